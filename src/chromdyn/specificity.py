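"""Cell-type specificity scoring and category enrichment.

Covers four linked analyses:

* a simplified differential-expression call (Welch t on log2 pseudocounted
  values + Benjamini-Hochberg) defining naive-, primed-specific and
  unchanged gene sets at a 2-fold / q < 0.01 threshold;
* a per-gene specificity Z-score: the log2 naive/primed fold change
  standardized across genes (positive = higher in naive ESCs);
* association of atlas loci to genes whose TSS lies within a window of the
  locus (all qualifying genes, not nearest-only);
* per-category enrichment of associated genes' Z-scores (Mann-Whitney U
  versus a reference category) and gene-set time-course scoring (sum of
  per-gene Z with Welch tests versus unchanged genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GeneModel, GenomeInterval, interval_gene_distance


@dataclass
class GeneSets:
    """Naive/primed-specific and unchanged gene sets with per-gene statistics."""

    naive: list[str]
    primed: list[str]
    unchanged: list[str]
    stats: pd.DataFrame  # log2fc, p, q per gene


def _log2_fc(expr: pd.DataFrame, esc_cols: Sequence[str], episc_cols: Sequence[str],
             pseudocount: float = 1.0) -> pd.Series:
    """log2 fold change naive(ESC)/primed(EpiSC) on pseudocounted replicate means."""
    esc = expr[list(esc_cols)].mean(axis=1)
    episc = expr[list(episc_cols)].mean(axis=1)
    return np.log2((esc + pseudocount) / (episc + pseudocount))


def _inv_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    from scipy.special import polygamma
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        step = -tri * (tri - x) / float(polygamma(2, y))
        y += step
        if abs(step) < 1e-10 * y:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for per-gene variances.

    Method-of-moments fit on log variances: the spread of log(s2) beyond
    the chi-square sampling component trigamma(df/2) estimates the prior
    degrees of freedom d0; no excess spread means a common variance
    (d0 = inf).
    """
    from scipy.special import digamma, polygamma
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 0.0
    evar = float(polygamma(1, df / 2))
    excess = float(z.var(ddof=1)) - evar
    e_mean = float(z.mean()) - float(digamma(df / 2)) + np.log(df / 2)
    if excess <= 1e-8:
        return np.inf, float(np.exp(e_mean))
    d0 = 2 * _inv_trigamma(excess)
    s02 = float(np.exp(e_mean + digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s02


def _moderated_t(log_a: np.ndarray, log_b: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene moderated two-sample t: pooled within-gene variance shrunk
    toward an empirical-Bayes prior estimated across genes (limma-style).

    With few replicates a per-gene variance estimate is so unstable that a
    plain t-test has little power at stringent FDR; borrowing variance
    information across genes restores it.
    """
    n1, n2 = log_a.shape[1], log_b.shape[1]
    df = n1 + n2 - 2
    v1 = log_a.var(axis=1, ddof=1)
    v2 = log_b.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    d0, s02 = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s02 + df * s2) / (d0 + df)
        df_total = df + d0
    delta = log_a.mean(axis=1) - log_b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)  # 0/0: no change and no variance
    return t, p


def define_specific_genes(expr: pd.DataFrame, esc_cols: Sequence[str],
                          episc_cols: Sequence[str], fc_threshold: float = 2.0,
                          q_threshold: float = 0.01,
                          pseudocount: float = 1.0,
                          moderated: bool = True) -> GeneSets:
    """Call naive- and primed-specific genes between the two cell types.

    A gene is naive-specific when its ESC/EpiSC fold change is at least
    ``fc_threshold`` with BH-adjusted p < ``q_threshold``; primed-specific
    is the symmetric call; everything else is unchanged.  The test on
    log2(pseudocounted) replicate values is a moderated t by default
    (``moderated=False`` gives a plain Welch t).  Requires >= 2 replicates
    per cell type.
    """
    if len(esc_cols) < 2 or len(episc_cols) < 2:
        raise ValueError("need >= 2 replicates per cell type for the t-test")
    if (expr[list(esc_cols) + list(episc_cols)].to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    log_esc = np.log2(expr[list(esc_cols)].to_numpy() + pseudocount)
    log_episc = np.log2(expr[list(episc_cols)].to_numpy() + pseudocount)
    if moderated:
        _, p = _moderated_t(log_esc, log_episc)
    else:
        _, p = stats.ttest_ind(log_esc, log_episc, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    _, q, _, _ = multipletests(p, method="fdr_bh")
    l2fc = _log2_fc(expr, esc_cols, episc_cols, pseudocount)
    table = pd.DataFrame({"log2fc": l2fc, "p": p, "q": q}, index=expr.index)
    lfc_thr = np.log2(fc_threshold)
    naive = table.index[(table["log2fc"] >= lfc_thr) & (table["q"] < q_threshold)]
    primed = table.index[(table["log2fc"] <= -lfc_thr) & (table["q"] < q_threshold)]
    unchanged = table.index.difference(naive.union(primed), sort=False)
    return GeneSets(list(naive), list(primed), list(unchanged), table)


def specificity_z(expr: pd.DataFrame, esc_cols: Sequence[str],
                  episc_cols: Sequence[str], pseudocount: float = 1.0,
                  ddof: int = 0) -> pd.Series:
    """Per-gene specificity Z-score (positive = naive/ESC-high).

    The log2 ESC/EpiSC fold change is standardized across genes using the
    population SD by default (``ddof=0``).  Output has mean 0 and SD 1 by
    construction.  Raises when all genes share one fold change.
    """
    l2fc = _log2_fc(expr, esc_cols, episc_cols, pseudocount)
    sd = l2fc.std(ddof=ddof)
    if sd == 0 or np.isnan(sd):
        raise ValueError("degenerate input: zero SD of log2 fold changes across genes")
    z = (l2fc - l2fc.mean()) / sd
    z.name = "z"
    return z


def associate_loci(loci: Sequence[GenomeInterval], genes: Sequence[GeneModel],
                   window: int = 2000, locus_ids: Sequence[str] | None = None,
                   anchor: str = "edge",
                   summits: Sequence[int] | None = None) -> dict[str, list[str]]:
    """Map each locus to all genes whose TSS lies within ``window`` bp.

    ``anchor="edge"`` (default) measures to the nearer locus edge (0 inside
    the locus); ``anchor="summit"`` measures |TSS - summit| and requires
    ``summits``.  Loci with no qualifying gene map to an empty list.
    """
    if locus_ids is None:
        locus_ids = [f"locus_{i:06d}" for i in range(len(loci))]
    if anchor == "summit" and (summits is None or len(summits) != len(loci)):
        raise ValueError("summit anchoring requires one summit per locus")
    tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in sorted({g.chrom for g in genes}):
        sub = sorted((g.tss, g.gene_id) for g in genes if g.chrom == chrom)
        tss_by_chrom[chrom] = (np.array([t for t, _ in sub]),
                               [gid for _, gid in sub])
    out: dict[str, list[str]] = {}
    for i, iv in enumerate(loci):
        entry = tss_by_chrom.get(iv.chrom)
        if entry is None:
            out[locus_ids[i]] = []
            continue
        tss, gids = entry
        if anchor == "summit":
            lo, hi = summits[i] - window, summits[i] + window  # type: ignore[index]
        else:
            lo, hi = iv.start - window, iv.end - 1 + window
        a = int(np.searchsorted(tss, lo, side="left"))
        b = int(np.searchsorted(tss, hi, side="right"))
        out[locus_ids[i]] = sorted(gids[a:b])
    return out


def category_enrichment(categories: Mapping[str, str],
                        assoc: Mapping[str, Sequence[str]],
                        z: pd.Series,
                        log2fc: pd.Series | None = None,
                        reference: str = "permanently_open") -> pd.DataFrame:
    """Per-category Z-score enrichment versus a reference occupancy category.

    For each category the specificity Z-scores of all associated genes are
    pooled (genes deduplicated within the category to avoid counting one
    gene once per flanking locus) and compared with the reference
    category's pool by a two-sided Mann-Whitney U test.  Also reports the
    per-category sum of log2 fold changes.  P-values are raw and
    BH-adjusted across categories; categories with < 2 genes get NaN.
    """
    genes_by_cat: dict[str, list[str]] = {}
    n_loci: dict[str, int] = {}
    for locus_id, cat in categories.items():
        n_loci[cat] = n_loci.get(cat, 0) + 1
        genes_by_cat.setdefault(cat, [])
        genes_by_cat[cat].extend(assoc.get(locus_id, ()))
    for cat in genes_by_cat:
        genes_by_cat[cat] = sorted(set(genes_by_cat[cat]) & set(z.index))
    if reference not in genes_by_cat or not genes_by_cat[reference]:
        raise ValueError(f"reference category {reference!r} has no associated genes")
    ref_z = z.loc[genes_by_cat[reference]].to_numpy()
    rows = []
    for cat in sorted(genes_by_cat):
        gene_ids = genes_by_cat[cat]
        zs = z.loc[gene_ids].to_numpy()
        if len(zs) >= 2 and len(ref_z) >= 2:
            if cat == reference:
                p = 1.0
                u = len(zs) * len(ref_z) / 2.0
            else:
                u, p = stats.mannwhitneyu(zs, ref_z, alternative="two-sided")
        else:
            u, p = np.nan, np.nan
        fc_sum = (float(log2fc.loc[gene_ids].sum())
                  if log2fc is not None and gene_ids else np.nan)
        rows.append((cat, n_loci.get(cat, 0), len(gene_ids),
                     float(np.median(zs)) if len(zs) else np.nan,
                     u, p, fc_sum))
    df = pd.DataFrame(rows, columns=["category", "n_loci", "n_genes", "median_z",
                                     "U", "p", "sum_log2fc"]).set_index("category")
    q = np.full(len(df), np.nan)
    defined = df["p"].notna().to_numpy()
    if defined.any():
        _, q[defined], _, _ = multipletests(df["p"].to_numpy()[defined],
                                            method="fdr_bh")
    df["q"] = q
    return df


@dataclass
class GeneSetScore:
    """Sum-of-Z time-course score of a gene set, with per-sample Welch tests."""

    zmat: pd.DataFrame            # genes x samples, per-gene standardized
    scores: pd.Series             # per-sample sum of Z over the set
    pvalues: pd.Series            # per-sample Welch p, set vs unchanged genes
    constant_genes: list[str] = field(default_factory=list)


def geneset_score(expr: pd.DataFrame, gene_set: Sequence[str],
                  unchanged: Sequence[str], ddof: int = 0) -> GeneSetScore:
    """Score a gene set over a time course as the per-sample sum of Z-scores.

    Each gene's expression is standardized across the time-course samples
    (population SD by default); the set score at a sample is the sum of its
    member genes' Z there, and significance is a two-sided Welch t-test of
    the set's Z-values against the unchanged genes' Z-values at that
    sample.  Genes constant across samples get an all-zero Z row and are
    flagged, not dropped.
    """
    if len(gene_set) == 0 or len(unchanged) == 0:
        raise ValueError("gene_set and unchanged must be non-empty")
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = expr.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    zmat = pd.DataFrame((x - mean) / sd_safe, index=expr.index,
                        columns=expr.columns)
    zmat.loc[constant, :] = 0.0
    missing = [g for g in list(gene_set) + list(unchanged) if g not in zmat.index]
    if missing:
        raise KeyError(f"genes not in expression table: {missing[:5]}")
    set_z = zmat.loc[list(gene_set)]
    unch_z = zmat.loc[list(unchanged)]
    scores = set_z.sum(axis=0)
    scores.name = "sum_z"
    _, p = stats.ttest_ind(set_z.to_numpy(), unch_z.to_numpy(), axis=0,
                           equal_var=False)
    pvalues = pd.Series(p, index=expr.columns, name="welch_p")
    return GeneSetScore(zmat, scores, pvalues,
                        list(expr.index[constant]))
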