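"""Specificity Z-scores, gene-set calls, locus association and enrichment.

Brute-force oracles: the Mann-Whitney U is re-counted pair by pair and the
Welch statistic recomputed from its textbook formula on tiny inputs.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chromdyn.intervals import GeneModel, GenomeInterval, interval_gene_distance
from chromdyn.specificity import (associate_loci, category_enrichment,
                                  define_specific_genes, geneset_score,
                                  specificity_z)


def _expr_with_log2fc(fcs, episc_value=15.0, reps=2):
    """Expression table whose pseudocounted log2(ESC/EpiSC) equals ``fcs``."""
    rows = {}
    for i, fc in enumerate(fcs):
        esc = (episc_value + 1) * 2.0 ** fc - 1
        rows[f"g{i}"] = [esc] * reps + [episc_value] * reps
    cols = [f"ESC_{r}" for r in range(reps)] + [f"EpiSC_{r}" for r in range(reps)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols), \
        cols[:reps], cols[reps:]


class TestDefineSpecificGenes:
    def test_noise_free_recovery_equals_truth(self, noise_free_cfg):
        from chromdyn.simulate import simulate_study
        data = simulate_study(noise_free_cfg, with_tracks=False)
        ed = data.expression
        sets = define_specific_genes(ed.table, ed.esc_cols, ed.episc_cols)
        assert set(sets.naive) == set(data.truth.genes_with_label("naive"))
        assert set(sets.primed) == set(data.truth.genes_with_label("primed"))

    def test_identical_means_are_unchanged(self):
        expr, esc, episc = _expr_with_log2fc([0.0, 2.0, 2.0, -2.0])
        sets = define_specific_genes(expr, esc, episc)
        assert "g0" in sets.unchanged

    def test_requires_two_replicates(self):
        expr, esc, episc = _expr_with_log2fc([1.0, 0.0])
        with pytest.raises(ValueError, match="replicates"):
            define_specific_genes(expr, esc[:1], episc)

    def test_plain_welch_flag_matches_scipy(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.uniform(10, 1000, size=(20, 6)),
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(6)])
        esc, episc = [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)]
        sets = define_specific_genes(expr, esc, episc, moderated=False)
        _, p = sps.ttest_ind(np.log2(expr[esc] + 1), np.log2(expr[episc] + 1),
                             axis=1, equal_var=False)
        np.testing.assert_allclose(sets.stats["p"].to_numpy(), p)


class TestSpecificityZ:
    def test_hand_computed_population_z(self):
        expr, esc, episc = _expr_with_log2fc([2, 1, 0, -1, -2])
        z = specificity_z(expr, esc, episc)
        r2 = math.sqrt(2)
        np.testing.assert_allclose(z.to_numpy(),
                                   [r2, r2 / 2, 0, -r2 / 2, -r2], atol=1e-12)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.uniform(0, 500, size=(50, 4)),
                            index=[f"g{i}" for i in range(50)],
                            columns=["e1", "e2", "p1", "p2"])
        z = specificity_z(expr, ["e1", "e2"], ["p1", "p2"])
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=0) - 1) < 1e-12

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.uniform(0, 500, size=(30, 4)),
                            index=[f"g{i}" for i in range(30)],
                            columns=["e1", "e2", "p1", "p2"])
        z1 = specificity_z(expr, ["e1", "e2"], ["p1", "p2"])
        z2 = specificity_z(expr, ["p1", "p2"], ["e1", "e2"])
        np.testing.assert_allclose(z1.to_numpy(), -z2.to_numpy(), atol=1e-10)

    def test_degenerate_identical_fold_changes_error(self):
        expr, esc, episc = _expr_with_log2fc([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="zero SD"):
            specificity_z(expr, esc, episc)


class TestAssociateLoci:
    def _genes(self, tss_list):
        return [GeneModel(f"g{i}", GenomeInterval("c", t, t + 2000, "+"))
                for i, t in enumerate(tss_list)]

    def test_edge_distance_window(self):
        loci = [GenomeInterval("c", 0, 500)]
        # TSS at 2501: distance to end-1 edge = 2002 > 2000
        assert associate_loci(loci, self._genes([2501]))["locus_000000"] == []
        assert associate_loci(loci, self._genes([2499]))["locus_000000"] == ["g0"]

    def test_tss_inside_locus_and_all_genes_kept(self):
        loci = [GenomeInterval("c", 0, 500)]
        assoc = associate_loci(loci, self._genes([100, 600]))
        assert assoc["locus_000000"] == ["g0", "g1"]

    def test_matches_bruteforce_distance_scan(self):
        rng = np.random.default_rng(7)
        loci = [GenomeInterval("c", int(s), int(s) + 300)
                for s in sorted(rng.integers(0, 100_000, 40))]
        genes = self._genes(sorted(int(t) for t in rng.integers(0, 100_000, 60)))
        assoc = associate_loci(loci, genes, window=2000)
        for i, iv in enumerate(loci):
            expected = sorted(g.gene_id for g in genes
                              if interval_gene_distance(iv, g) <= 2000)
            assert assoc[f"locus_{i:06d}"] == expected


def _brute_u(x, y):
    """Textbook U: count wins plus half-ties for sample x."""
    return sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in x for b in y)


class TestCategoryEnrichment:
    def _inputs(self, cat_z):
        """Build categories/assoc/z where each category sees fixed z-values."""
        z = {}
        categories, assoc = {}, {}
        for cat, values in cat_z.items():
            gids = []
            for j, v in enumerate(values):
                gid = f"{cat}_g{j}"
                z[gid] = v
                gids.append(gid)
            lid = f"L_{cat}"
            categories[lid] = cat
            assoc[lid] = gids
        return categories, assoc, pd.Series(z)

    def test_reference_vs_itself_is_one(self):
        cats, assoc, z = self._inputs({"permanently_open": [1.0, 2.0, 3.0]})
        res = category_enrichment(cats, assoc, z)
        assert res.loc["permanently_open", "p"] == 1.0
        assert res.loc["permanently_open", "U"] == pytest.approx(4.5)

    def test_u_statistic_matches_bruteforce(self):
        cats, assoc, z = self._inputs({
            "permanently_open": [0.1, -0.2, 0.05, 0.3],
            "kd_specific_open": [1.5, 2.0, 0.9, 2.4],
        })
        res = category_enrichment(cats, assoc, z)
        x = [1.5, 2.0, 0.9, 2.4]
        y = [0.1, -0.2, 0.05, 0.3]
        assert res.loc["kd_specific_open", "U"] == pytest.approx(_brute_u(x, y))
        # exact enumeration p: proportion of label permutations at least as
        # extreme (two-sided)
        pooled = x + y
        u_obs = _brute_u(x, y)
        mu = len(x) * len(y) / 2
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(8) if i not in idx]
            if abs(_brute_u(xs, ys) - mu) >= abs(u_obs - mu) - 1e-9:
                count += 1
            total += 1
        assert res.loc["kd_specific_open", "p"] == pytest.approx(count / total,
                                                                 abs=1e-9)

    def test_small_category_p_undefined(self):
        cats, assoc, z = self._inputs({
            "permanently_open": [0.1, 0.2, 0.3],
            "complex": [5.0],
        })
        res = category_enrichment(cats, assoc, z)
        assert np.isnan(res.loc["complex", "p"])

    def test_gene_deduplicated_within_category(self):
        z = pd.Series({"g0": 1.0, "r0": 0.0, "r1": 0.1, "r2": -0.1})
        categories = {"L1": "kd_specific_open", "L2": "kd_specific_open",
                      "LR": "permanently_open"}
        assoc = {"L1": ["g0"], "L2": ["g0"], "LR": ["r0", "r1", "r2"]}
        res = category_enrichment(categories, assoc, z)
        assert res.loc["kd_specific_open", "n_genes"] == 1

    def test_missing_reference_raises(self):
        cats, assoc, z = self._inputs({"complex": [1.0, 2.0]})
        with pytest.raises(ValueError, match="reference"):
            category_enrichment(cats, assoc, z)


class TestGeneSetScore:
    def test_constant_genes_score_zero_and_flagged(self):
        expr = pd.DataFrame({"s1": [5.0, 1.0], "s2": [5.0, 2.0],
                             "s3": [5.0, 3.0]}, index=["gc", "gu"])
        res = geneset_score(expr, ["gc"], ["gu"])
        assert (res.scores == 0).all()
        assert res.constant_genes == ["gc"]

    def test_hand_computed_z_row(self):
        expr = pd.DataFrame({"s1": [10.0, 1.0], "s2": [20.0, 2.0],
                             "s3": [30.0, 4.0]}, index=["g", "u"])
        res = geneset_score(expr, ["g"], ["u"])
        np.testing.assert_allclose(res.zmat.loc["g"].to_numpy(),
                                   [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_welch_p_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.uniform(1, 100, size=(8, 3)),
                            index=[f"g{i}" for i in range(8)],
                            columns=["s1", "s2", "s3"])
        gene_set, unchanged = ["g0", "g1", "g2"], ["g3", "g4", "g5", "g6", "g7"]
        res = geneset_score(expr, gene_set, unchanged)
        a = res.zmat.loc[gene_set, "s2"].to_numpy()
        b = res.zmat.loc[unchanged, "s2"].to_numpy()
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert res.pvalues["s2"] == pytest.approx(p)

    def test_empty_sets_rejected(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            geneset_score(expr, [], ["g"])
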