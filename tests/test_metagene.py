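
import numpy as np
import pandas as pd
import pytest

from chromdyn.intervals import GeneModel, GenomeInterval
from chromdyn.metagene import (SignalTrack, classify_expression, load_track,
                               normalize_cpm, scaled_metagene, summit_profile,
                               tss_body_ratio)


def _constant_df(value=2.0, length=100_000, chrom="c"):
    starts = np.arange(0, length, 1000)
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": np.minimum(starts + 1000, length),
                         "value": value})


def _genes(spans, chrom="c"):
    return [GeneModel(f"g{i}", GenomeInterval(chrom, s, e, strand))
            for i, (s, e, strand) in enumerate(spans)]


class TestLoadTrack:
    def test_constant_track_bins(self):
        t = load_track(_constant_df(2.0), bin_size=50)
        np.testing.assert_array_equal(t.bins["c"], 2.0)

    def test_straddling_interval_split_by_overlap(self):
        # value 10 over [30, 120): bin0 gets 20/50, bin1 full, bin2 20/50
        df = pd.DataFrame({"chrom": ["c"], "start": [30], "end": [120],
                           "value": [10.0]})
        t = load_track(df, bin_size=50, chrom_sizes={"c": 150})
        np.testing.assert_allclose(t.bins["c"], [10 * 20 / 50, 10.0, 10 * 20 / 50])

    def test_cpm_sums_to_one_million(self):
        rng = np.random.default_rng(3)
        df = _constant_df(1.0)
        df["value"] = rng.uniform(0, 10, len(df))
        t = normalize_cpm(load_track(df))
        assert sum(v.sum() for v in t.bins.values()) == pytest.approx(1e6)

    def test_zero_total_normalization_error(self):
        t = load_track(_constant_df(0.0))
        with pytest.raises(ValueError, match="zero-total"):
            normalize_cpm(t)


class TestClassifyExpression:
    def test_threshold_is_strict(self):
        vals = pd.Series({"g0": 100.0, "g1": 100.1})
        cls = classify_expression(vals)
        assert cls["g0"] == "not_expressed"
        assert cls["g1"] == "Q1"

    def test_eight_genes_two_per_quartile(self):
        vals = pd.Series({f"g{i}": 200.0 + i for i in range(8)})
        sizes = classify_expression(vals).value_counts()
        assert all(sizes[q] == 2 for q in ("Q1", "Q2", "Q3", "Q4"))

    def test_ten_genes_remainder_to_top_quartiles(self):
        vals = pd.Series({f"g{i}": 200.0 + i for i in range(10)})
        sizes = classify_expression(vals).value_counts()
        assert [sizes[q] for q in ("Q1", "Q2", "Q3", "Q4")] == [3, 3, 2, 2]

    def test_ties_broken_by_gene_id(self):
        vals = pd.Series({"b": 200.0, "a": 200.0, "d": 200.0, "c": 200.0})
        cls = classify_expression(vals)
        assert cls.to_dict() == {"a": "Q1", "b": "Q2", "c": "Q3", "d": "Q4"}


class TestScaledMetagene:
    def test_constant_track_profile_exact(self):
        t = load_track(_constant_df(3.5))
        genes = _genes([(10_000, 18_000, "+"), (40_000, 45_000, "-")])
        prof = scaled_metagene(t, genes)
        np.testing.assert_allclose(prof.values, 3.5, rtol=0, atol=1e-9)
        assert prof.n_genes == 2

    def test_tss_local_signal_peaks_at_body_start(self):
        length = 100_000
        genes = _genes([(20_000, 30_000, "+")])
        df = _constant_df(0.0, length)
        rows = [df]
        rows.append(pd.DataFrame({"chrom": ["c"], "start": [19_900],
                                  "end": [20_100], "value": [50.0]}))
        t = load_track(pd.concat(rows, ignore_index=True), bin_size=50,
                       chrom_sizes={"c": length})
        prof = scaled_metagene(t, genes)
        vals = prof.values
        n_up = len(prof.upstream)
        # signal confined to the bins flanking the TSS boundary
        assert n_up - 3 <= vals.argmax() <= n_up + 1
        mid = n_up + len(prof.body) // 2
        assert vals[mid] == 0.0
        assert vals[:n_up - 5].max() == 0.0

    def test_strand_mirror_invariance_exact(self):
        rng = np.random.default_rng(8)
        length = 60_000
        df = pd.DataFrame({"chrom": "c", "start": np.arange(0, length, 50),
                           "end": np.arange(50, length + 1, 50),
                           "value": rng.uniform(0, 10, length // 50)})
        t = load_track(df, bin_size=50)
        genes = _genes([(10_000, 16_000, "+"), (30_000, 37_000, "-")])
        prof = scaled_metagene(t, genes)
        # mirror track and flip strands
        mdf = df.copy()
        mdf["start"], mdf["end"] = length - df["end"], length - df["start"]
        mt = load_track(mdf.sort_values("start"), bin_size=50)
        mgenes = [GeneModel(g.gene_id,
                            GenomeInterval("c", length - g.end, length - g.start,
                                           "-" if g.strand == "+" else "+"))
                  for g in genes]
        mprof = scaled_metagene(mt, mgenes)
        np.testing.assert_allclose(prof.values, mprof.values, atol=1e-9)

    def test_short_or_clipped_genes_skipped_with_warning(self):
        t = load_track(_constant_df(1.0, 10_000))
        genes = _genes([(1000, 1060, "+"),     # shorter than 2 bins
                        (500, 4000, "+"),      # upstream flank clipped
                        (5000, 8000, "+")])    # usable? downstream 8000+3000>10000
        with pytest.warns(UserWarning, match="skipped"):
            prof = scaled_metagene(t, _genes([(1000, 1060, "+"),
                                              (4000, 6500, "+")]))
        assert prof.n_skipped == 1
        assert prof.n_genes == 1
        with pytest.raises(ValueError):
            scaled_metagene(t, genes[:1])


class TestTssBodyRatio:
    def test_constant_track_gives_unit_ratio(self):
        t = load_track(_constant_df(4.0))
        genes = _genes([(10_000, 15_000, "+"), (30_000, 36_000, "-")])
        res = tss_body_ratio(t, genes)
        np.testing.assert_allclose(res["ratio"].to_numpy(), 1.0, atol=1e-9)

    def test_constructed_two_to_one_ratio(self):
        length = 30_000
        gene = _genes([(10_000, 20_000, "+")])
        base = _constant_df(1.0, length)
        promoter = pd.DataFrame({"chrom": ["c"], "start": [9500],
                                 "end": [10_501], "value": [1.0]})
        # 1-bp bins keep the unaligned promoter window exact
        t = load_track(pd.concat([base, promoter], ignore_index=True),
                       bin_size=1, chrom_sizes={"c": length})
        res = tss_body_ratio(t, gene)
        assert res.loc["g0", "ratio"] == pytest.approx(2.0, abs=1e-9)

    def test_gene_length_1001_excluded(self):
        t = load_track(_constant_df(1.0))
        res = tss_body_ratio(t, _genes([(10_000, 11_001, "+")]))
        assert res.loc["g0", "status"] == "body_empty"
        assert np.isnan(res.loc["g0", "ratio"])

    def test_invariant_under_global_scaling(self):
        rng = np.random.default_rng(12)
        df = _constant_df(1.0)
        df["value"] = rng.uniform(0.5, 5, len(df))
        genes = _genes([(10_000, 15_000, "+"), (40_000, 46_000, "-")])
        r1 = tss_body_ratio(load_track(df), genes)["ratio"]
        df2 = df.copy()
        df2["value"] *= 7.5
        r2 = tss_body_ratio(load_track(df2), genes)["ratio"]
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), rtol=1e-12)

    def test_zero_body_flagged_undefined(self):
        length = 30_000
        promoter_only = pd.DataFrame({"chrom": ["c"], "start": [9000],
                                      "end": [10_500], "value": [5.0]})
        base = _constant_df(0.0, length)
        t = load_track(pd.concat([base, promoter_only], ignore_index=True),
                       bin_size=50, chrom_sizes={"c": length})
        res = tss_body_ratio(t, _genes([(10_000, 20_000, "+")]))
        assert res.loc["g0", "status"] == "zero_body"


class TestSummitProfile:
    def test_constant_track_rows_constant(self):
        t = load_track(_constant_df(2.5))
        sp = summit_profile(t, [("c", 10_000), ("c", 50_000)])
        np.testing.assert_allclose(sp.matrix, 2.5, atol=1e-9)

    def test_delta_signal_maximal_at_center(self):
        length = 40_000
        base = _constant_df(0.0, length)
        spike = pd.DataFrame({"chrom": ["c"], "start": [19_975],
                              "end": [20_025], "value": [100.0]})
        t = load_track(pd.concat([base, spike], ignore_index=True),
                       bin_size=50, chrom_sizes={"c": length})
        sp = summit_profile(t, [("c", 20_000)], half_window=2000, n_bins=100)
        center = sp.mean.argmax()
        assert center in (49, 50)

    def test_row_means_match_per_base_bruteforce(self):
        rng = np.random.default_rng(21)
        length = 20_000
        values = rng.uniform(0, 10, length // 50)
        df = pd.DataFrame({"chrom": "c", "start": np.arange(0, length, 50),
                           "end": np.arange(50, length + 1, 50),
                           "value": values})
        t = load_track(df, bin_size=50)
        per_base = np.repeat(values, 50)
        summits = [("c", 5000), ("c", 9000), ("c", 13_000)]
        sp = summit_profile(t, summits, half_window=2000, n_bins=80)
        for row, (_, pos) in zip(sp.matrix, summits):
            assert row.mean() == pytest.approx(
                per_base[pos - 2000:pos + 2000].mean(), rel=1e-9)

    def test_clipped_windows_dropped(self):
        t = load_track(_constant_df(1.0, 10_000))
        sp = summit_profile(t, [("c", 100), ("c", 5000), ("c", 9990)])
        assert sp.n_dropped == 2
        assert sp.kept == [1]
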