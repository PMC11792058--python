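"""Synthetic study generator with planted ground truth.

Emulates the full input set of an 8-sample chromatin time course (two shRNA
arms x four time points) during a primed-to-naive stem-cell conversion:

* a single synthetic chromosome tiled with non-overlapping genes labelled
  naive-specific, primed-specific, lineage-specific or unchanged;
* an expression table with ESC/EpiSC replicates (planted 2-fold effects)
  and an arm x time course in which the knockdown arm suppresses
  primed/lineage genes early and activates naive genes late (piecewise
  linear in log2 space);
* per-sample ATAC-like peak calls realizing deterministic ideal occupancy
  patterns per dynamic category, with boundary jitter and presence dropout;
  knockdown-specific open loci are planted within 2 kb of naive TSSs;
* bedGraph coverage (Poisson background, Gaussian peak enrichment, and a
  planted promoter/TSS enrichment factor);
* bait/control AP-MS tables per cell type with planted interactors,
  background proteins and named contaminants.

Every generator is deterministic for a fixed seed; downstream tests read
labels only from :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import PeakCall
from .intervals import GeneModel, GenomeInterval
from .interactome import CONTAMINANT_PREFIXES

#: Ideal (control, knockdown) occupancy patterns per planted category,
#: for a four-time-point design.  Monotone staircases; noise enters only
#: through dropout.
IDEAL_PATTERNS: dict[str, tuple[str, str]] = {
    "permanently_open": ("1111", "1111"),
    "accelerated_opening": ("0001", "0111"),
    "decelerated_opening": ("0111", "0001"),
    "accelerated_closing": ("1110", "1000"),
    "decelerated_closing": ("1000", "1110"),
    "kd_specific_open": ("0000", "0011"),
    "kd_specific_closed": ("1111", "1100"),
    "stable_other": ("0011", "0011"),
}

#: Time-course log2 offsets (units of effect_log2fc) at fractions 0, 1/3,
#: 2/3, 1 of the course, per gene label and arm.
_SCHEDULES: dict[str, dict[str, tuple[float, ...]]] = {
    "naive": {"control": (-0.5, -0.5, -0.5, -0.1),
              "knockdown": (-0.5, -0.5, 0.0, 0.5)},
    "primed": {"control": (0.5, 0.5, 0.3, 0.1),
               "knockdown": (0.0, -0.5, -0.5, -0.5)},
    "lineage": {"control": (0.3, 0.3, 0.2, 0.1),
                "knockdown": (-0.3, -0.5, -0.5, -0.5)},
    "unchanged": {"control": (0.0, 0.0, 0.0, 0.0),
                  "knockdown": (0.0, 0.0, 0.0, 0.0)},
}

#: Offsets (bp, relative to the host TSS) of the non-overlapping slots a
#: planted locus may occupy; spacing 700 bp keeps jittered peaks disjoint.
_SLOT_OFFSETS = (-1900, -1200, -500, 200, 900)


def _default_loci() -> dict[str, int]:
    return {
        "permanently_open": 200,
        "accelerated_opening": 100,
        "decelerated_opening": 100,
        "accelerated_closing": 100,
        "decelerated_closing": 100,
        "kd_specific_open": 200,
        "kd_specific_closed": 100,
        "stable_other": 100,
    }


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic study."""

    seed: int = 0
    chrom: str = "chrSim"
    chrom_length: int | None = None        # None -> sized to fit the genes
    n_genes: int = 300
    n_naive: int = 40
    n_primed: int = 40
    n_lineage: int = 60
    lineage_names: tuple[str, ...] = ("mesoderm", "ectoderm")
    arms: tuple[str, str] = ("shLuc", "shBrd8")
    timepoints: tuple[str, ...] = ("D0", "D2", "D4", "D6")
    n_reps_celltype: int = 3               # ESC / EpiSC replicates
    n_reps_timecourse: int = 2
    expr_noise_sd: float = 0.3             # log2-scale SD
    effect_log2fc: float = 2.0             # planted |log2FC| for specific genes
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    n_loci_per_category: dict[str, int] = field(default_factory=_default_loci)
    peak_dropout: float = 0.1
    peak_width: tuple[int, int] = (300, 420)
    peak_jitter: int = 50
    background_rate: float = 5.0           # mean coverage per bin
    peak_amplitude: float = 20.0
    peak_sigma: float = 200.0              # bp; Gaussian enrichment width
    tss_enrichment: float = 2.0            # promoter/body coverage factor
    track_bin_size: int = 50
    n_interactors: int = 20                # per cell type
    n_shared_interactors: int = 10
    n_background: int = 100
    n_contaminants: int = 5

    def __post_init__(self) -> None:
        counts = [self.n_genes, self.n_naive, self.n_primed, self.n_lineage,
                  self.n_interactors, self.n_shared_interactors,
                  self.n_background, self.n_contaminants,
                  *self.n_loci_per_category.values()]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0 <= self.peak_dropout < 0.5:
            raise ValueError("peak_dropout must be in [0, 0.5)")
        if self.effect_log2fc < 1:
            raise ValueError("effect_log2fc must be >= 1 so planted genes "
                             "pass the 2-fold rule")
        if self.n_naive + self.n_primed + self.n_lineage > self.n_genes:
            raise ValueError("labelled genes exceed n_genes")
        if self.n_shared_interactors > self.n_interactors:
            raise ValueError("n_shared_interactors exceeds n_interactors")
        bad = set(self.n_loci_per_category) - set(IDEAL_PATTERNS)
        if bad:
            raise ValueError(f"unknown locus categories {sorted(bad)}")

    @property
    def samples(self) -> list[tuple[str, str]]:
        """Arm-major, time-minor sample order."""
        return [(arm, tp) for arm in self.arms for tp in self.timepoints]


@dataclass
class GroundTruth:
    """Planted labels: the only source downstream tests may read."""

    gene_labels: dict[str, str] = field(default_factory=dict)
    locus_categories: dict[str, str] = field(default_factory=dict)
    locus_intervals: dict[str, GenomeInterval] = field(default_factory=dict)
    locus_patterns: dict[str, tuple[str, str]] = field(default_factory=dict)
    protein_labels: dict[str, dict[str, str]] = field(default_factory=dict)

    def genes_with_label(self, label: str) -> list[str]:
        return sorted(g for g, lab in self.gene_labels.items()
                      if lab == label or lab.startswith(label + ":"))

    def to_frames(self) -> dict[str, pd.DataFrame]:
        frames = {
            "genes": pd.DataFrame(sorted(self.gene_labels.items()),
                                  columns=["gene_id", "label"]),
            "loci": pd.DataFrame(
                [(lid, iv.chrom, iv.start, iv.end, self.locus_categories[lid],
                  *self.locus_patterns[lid])
                 for lid, iv in sorted(self.locus_intervals.items())],
                columns=["locus_id", "chrom", "start", "end", "category",
                         "control_pattern", "kd_pattern"]),
        }
        rows = [(ct, name, lab) for ct, d in sorted(self.protein_labels.items())
                for name, lab in sorted(d.items())]
        frames["proteins"] = pd.DataFrame(rows, columns=["cell_type", "name",
                                                         "label"])
        return frames


# -- annotation -------------------------------------------------------------

def generate_annotation(cfg: SimConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Tile non-overlapping labelled genes on one synthetic chromosome."""
    rng = np.random.default_rng([cfg.seed, 1])
    margin = 10_000
    n = cfg.n_genes
    truth = GroundTruth()
    if n == 0:
        return [], truth
    lengths = rng.integers(2000, 8001, size=n)
    gaps = rng.integers(5000, 15_001, size=n)
    strands = rng.choice(["+", "-"], size=n)
    genes: list[GeneModel] = []
    pos = margin
    for i in range(n):
        start, end = pos, pos + int(lengths[i])
        genes.append(GeneModel(f"g{i:04d}",
                               GenomeInterval(cfg.chrom, start, end, str(strands[i]))))
        pos = end + int(gaps[i])
    needed = pos - int(gaps[-1]) + margin
    if cfg.chrom_length is not None and cfg.chrom_length < needed:
        raise ValueError(f"chrom_length {cfg.chrom_length} too small; "
                         f"genes need {needed} bp")
    labels = ["unchanged"] * n
    order = rng.permutation(n)
    cursor = 0
    for gi in order[cursor:cursor + cfg.n_naive]:
        labels[gi] = "naive"
    cursor += cfg.n_naive
    for gi in order[cursor:cursor + cfg.n_primed]:
        labels[gi] = "primed"
    cursor += cfg.n_primed
    lineage_names = cfg.lineage_names or ("lineage",)
    for j, gi in enumerate(order[cursor:cursor + cfg.n_lineage]):
        labels[gi] = f"lineage:{lineage_names[j % len(lineage_names)]}"
    truth.gene_labels = {g.gene_id: lab for g, lab in zip(genes, labels)}
    return genes, truth


def chrom_length_for(cfg: SimConfig, genes: Sequence[GeneModel]) -> int:
    if cfg.chrom_length is not None:
        return cfg.chrom_length
    if not genes:
        return 100_000
    return max(g.end for g in genes) + 10_000


# -- expression -------------------------------------------------------------

def _schedule(label: str, arm_role: str, n_timepoints: int) -> np.ndarray:
    key = label.split(":")[0]
    anchors = np.array(_SCHEDULES[key][arm_role])
    frac = np.linspace(0, 1, n_timepoints)
    return np.interp(frac, np.linspace(0, 1, len(anchors)), anchors)


@dataclass
class ExpressionData:
    table: pd.DataFrame
    esc_cols: list[str]
    episc_cols: list[str]
    timecourse_cols: list[str]
    sample_of_col: dict[str, tuple[str, str]]   # timecourse col -> (arm, tp)


def generate_expression(cfg: SimConfig, genes: Sequence[GeneModel],
                        truth: GroundTruth) -> ExpressionData:
    """Expression table: ESC/EpiSC replicates plus the arm x time course.

    Values are log-normal around per-gene baselines.  Naive-specific genes
    are ``effect_log2fc`` higher in ESCs (primed-specific the mirror);
    lineage and unchanged genes do not differ between the cell types.  The
    time course follows the piecewise-linear log2 schedules in
    ``_SCHEDULES`` (knockdown arm: early primed/lineage suppression, late
    naive activation).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    fc = cfg.effect_log2fc
    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    labels = [truth.gene_labels[g] for g in gene_ids]
    esc_off = np.array([fc / 2 if lab == "naive" else -fc / 2 if lab == "primed"
                        else 0.0 for lab in labels])
    columns: dict[str, np.ndarray] = {}
    esc_cols, episc_cols, tc_cols = [], [], []
    sample_of_col: dict[str, tuple[str, str]] = {}

    def noisy(log2_mean: np.ndarray) -> np.ndarray:
        return 2.0 ** (log2_mean + rng.normal(0, cfg.expr_noise_sd, size=n))

    for r in range(cfg.n_reps_celltype):
        col = f"ESC_rep{r + 1}"
        columns[col] = noisy(base + esc_off)
        esc_cols.append(col)
    for r in range(cfg.n_reps_celltype):
        col = f"EpiSC_rep{r + 1}"
        columns[col] = noisy(base - esc_off)
        episc_cols.append(col)
    n_tp = len(cfg.timepoints)
    sched = {lab: {role: _schedule(lab, role, n_tp)
                   for role in ("control", "knockdown")}
             for lab in sorted(set(labels))}
    for arm, role in zip(cfg.arms, ("control", "knockdown")):
        for t, tp in enumerate(cfg.timepoints):
            offsets = np.array([sched[lab][role][t] * fc for lab in labels])
            for r in range(cfg.n_reps_timecourse):
                col = f"{arm}_{tp}_rep{r + 1}"
                columns[col] = noisy(base + offsets)
                tc_cols.append(col)
                sample_of_col[col] = (arm, tp)
    table = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionData(table, esc_cols, episc_cols, tc_cols, sample_of_col)


# -- peaks ------------------------------------------------------------------

def generate_peaks(cfg: SimConfig, genes: Sequence[GeneModel],
                   truth: GroundTruth
                   ) -> dict[tuple[str, str], list[PeakCall]]:
    """Per-sample peak calls realizing the planted occupancy patterns.

    Loci occupy fixed slots around host-gene TSSs: knockdown-specific open
    loci around naive-specific TSSs (so their enrichment is recoverable),
    all other categories around unchanged-gene TSSs.  Peaks are emitted
    where the pattern bit is 1, with +-``peak_jitter`` boundary jitter and
    dropout at ``peak_dropout``.  Requires the four-time-point design.
    """
    if len(cfg.timepoints) != len(next(iter(IDEAL_PATTERNS.values()))[0]):
        raise ValueError("ideal occupancy patterns require the "
                         f"{len(IDEAL_PATTERNS['permanently_open'][0])}"
                         "-time-point design")
    rng = np.random.default_rng([cfg.seed, 3])
    naive_hosts = [g for g in genes if truth.gene_labels[g.gene_id] == "naive"]
    unch_hosts = [g for g in genes if truth.gene_labels[g.gene_id] == "unchanged"]
    chrom_len = chrom_length_for(cfg, genes)

    placements: list[tuple[str, GeneModel, int]] = []  # (category, host, slot)
    n_kd_open = cfg.n_loci_per_category.get("kd_specific_open", 0)
    if n_kd_open and not naive_hosts:
        raise ValueError("kd_specific_open loci need naive-specific host genes")
    if n_kd_open > len(naive_hosts) * len(_SLOT_OFFSETS):
        raise ValueError("too many kd_specific_open loci for the naive genes")
    for i in range(n_kd_open):
        placements.append(("kd_specific_open", naive_hosts[i % len(naive_hosts)],
                           _SLOT_OFFSETS[i // len(naive_hosts)]))
    other = [(cat, count) for cat, count in sorted(cfg.n_loci_per_category.items())
             if cat != "kd_specific_open"]
    n_other = sum(c for _, c in other)
    if n_other and not unch_hosts:
        raise ValueError("planted loci need unchanged host genes")
    if n_other > len(unch_hosts) * len(_SLOT_OFFSETS):
        raise ValueError("too many loci for the unchanged genes")
    idx = 0
    for cat, count in other:
        for _ in range(count):
            placements.append((cat, unch_hosts[idx % len(unch_hosts)],
                               _SLOT_OFFSETS[idx // len(unch_hosts)]))
            idx += 1

    # deterministic locus order by genomic position
    records = []
    for cat, host, offset in placements:
        width = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
        start = host.tss + offset
        records.append((start, start + width, cat))
    records.sort()
    peak_sets: dict[tuple[str, str], list[PeakCall]] = {s: [] for s in cfg.samples}
    for li, (start, end, cat) in enumerate(records):
        lid = f"site_{li:06d}"
        truth.locus_categories[lid] = cat
        truth.locus_intervals[lid] = GenomeInterval(cfg.chrom, start, end)
        ctrl_bits, kd_bits = IDEAL_PATTERNS[cat]
        truth.locus_patterns[lid] = (ctrl_bits, kd_bits)
        for arm, bits in zip(cfg.arms, (ctrl_bits, kd_bits)):
            for tp, bit in zip(cfg.timepoints, bits):
                if bit == "0" or rng.random() < cfg.peak_dropout:
                    continue
                j = cfg.peak_jitter
                s = max(0, start + int(rng.integers(-j, j + 1)))
                e = min(chrom_len, end + int(rng.integers(-j, j + 1)))
                if e <= s:
                    s, e = start, end
                summit = (s + e) // 2 + int(rng.integers(-20, 21))
                summit = min(max(summit, s), e - 1)
                peak_sets[(arm, tp)].append(
                    PeakCall(GenomeInterval(cfg.chrom, s, e), summit,
                             score=float(rng.integers(100, 1000)),
                             sample_id=(arm, tp)))
    return peak_sets


def match_atlas_to_truth(atlas: Sequence[GenomeInterval],
                         truth: GroundTruth) -> list[str | None]:
    """Match each atlas locus to the overlapping planted locus id (or None).

    Planted loci are mutually disjoint with gaps larger than the boundary
    jitter, so each atlas locus overlaps at most one planted locus.
    """
    planted = sorted(truth.locus_intervals.items(), key=lambda kv: kv[1].start)
    starts = np.array([iv.start for _, iv in planted])
    ends = np.array([iv.end for _, iv in planted])
    out: list[str | None] = []
    for iv in atlas:
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        if lo < len(planted) and starts[lo] < iv.end and \
                planted[lo][1].chrom == iv.chrom:
            out.append(planted[lo][0])
        else:
            out.append(None)
    return out


# -- coverage tracks --------------------------------------------------------

def generate_tracks(cfg: SimConfig, peak_sets: Mapping[tuple[str, str], Sequence[PeakCall]],
                    genes: Sequence[GeneModel],
                    samples: Sequence[tuple[str, str]] | None = None,
                    ) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-sample bedGraph coverage (one row per track bin).

    Per bin the expected coverage is ``background_rate``, multiplied by
    ``tss_enrichment`` over +-500 bp promoter windows (fractional bin
    overlap) and incremented by Gaussian bumps (amplitude
    ``peak_amplitude``, width ``peak_sigma``) over each sample's peaks;
    observed values are Poisson draws.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    chrom_len = chrom_length_for(cfg, genes)
    bs = cfg.track_bin_size
    n_bins = -(-chrom_len // bs)
    edges = np.arange(n_bins + 1) * bs
    centers = edges[:-1] + bs / 2.0

    promoter_factor = np.ones(n_bins)
    if cfg.tss_enrichment != 1.0:
        for g in genes:
            lo, hi = g.tss - 500, g.tss + 501
            overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo),
                              0, bs)
            promoter_factor += (cfg.tss_enrichment - 1.0) * overlap / bs
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for sid in (samples if samples is not None else list(peak_sets)):
        lam = cfg.background_rate * promoter_factor.copy()
        for p in peak_sets.get(sid, ()):  # type: ignore[call-overload]
            s = p.summit
            span = int(4 * cfg.peak_sigma)
            b0 = max(0, (s - span) // bs)
            b1 = min(n_bins, (s + span) // bs + 1)
            lam[b0:b1] += cfg.peak_amplitude * np.exp(
                -((centers[b0:b1] - s) ** 2) / (2 * cfg.peak_sigma ** 2))
        values = rng.poisson(lam)
        out[sid] = pd.DataFrame({
            "chrom": cfg.chrom,
            "start": edges[:-1],
            "end": np.minimum(edges[1:], chrom_len),
            "value": values,
        })
    return out


# -- proteomics -------------------------------------------------------------

def generate_proteomics(cfg: SimConfig, truth: GroundTruth,
                        cell_types: Sequence[str] = ("ESC", "EpiSC"),
                        ) -> dict[str, pd.DataFrame]:
    """Bait/control AP-MS tables with planted interactors and contaminants.

    True interactors have bait/control ratio >= 4 and bait intensity
    >= 4e6 so they pass every filter rule by construction; background
    proteins have ratio around 1; contaminants carry names beginning with
    known contaminant prefixes but otherwise strong signals.  The first
    ``n_shared_interactors`` interactors are shared across cell types.
    """
    rng = np.random.default_rng([cfg.seed, 5])
    tables: dict[str, pd.DataFrame] = {}
    shared = [f"IntS{i:03d}" for i in range(cfg.n_shared_interactors)]
    for ct_i, ct in enumerate(cell_types):
        names, peptides, bait, control, labels = [], [], [], [], []
        n_specific = cfg.n_interactors - cfg.n_shared_interactors
        specific = [f"Int{ct[:1]}{ct_i}{i:03d}" for i in range(n_specific)]
        for name in shared + specific:
            names.append(name)
            peptides.append(2 + int(rng.poisson(4)))
            b = 4e6 * 2.0 ** rng.uniform(0, 3)
            ratio = 4.0 * 2.0 ** rng.uniform(0, 2)
            bait.append(b)
            control.append(b / ratio)
            labels.append("interactor")
        for i in range(cfg.n_background):
            names.append(f"Bkg{ct_i}{i:03d}")
            peptides.append(int(rng.poisson(2)))
            b = 2.0 ** rng.normal(np.log2(5e5), 1.0)
            ratio = 2.0 ** rng.normal(0, 0.4)
            bait.append(b)
            control.append(b / ratio)
            labels.append("background")
        for i in range(cfg.n_contaminants):
            prefix = CONTAMINANT_PREFIXES[i % len(CONTAMINANT_PREFIXES)]
            names.append(f"{prefix}{i + 1}")
            peptides.append(3 + int(rng.poisson(3)))
            b = 5e6 * 2.0 ** rng.uniform(0, 2)
            bait.append(b)
            control.append(b / 8.0)
            labels.append("contaminant")
        tables[ct] = pd.DataFrame({
            "name": names,
            "unique_peptides": peptides,
            "bait_intensity": bait,
            "control_intensity": control,
        })
        truth.protein_labels[ct] = dict(zip(names, labels))
    return tables


# -- convenience ------------------------------------------------------------

@dataclass
class SimData:
    cfg: SimConfig
    genes: list[GeneModel]
    truth: GroundTruth
    expression: ExpressionData
    peak_sets: dict[tuple[str, str], list[PeakCall]]
    proteomics: dict[str, pd.DataFrame]
    tracks: dict[tuple[str, str], pd.DataFrame] | None = None


def simulate_study(cfg: SimConfig, with_tracks: bool = True) -> SimData:
    """Generate the complete synthetic study (annotation, expression, peaks,
    optionally coverage tracks, proteomics) under one seed."""
    genes, truth = generate_annotation(cfg)
    expr = generate_expression(cfg, genes, truth)
    peaks = generate_peaks(cfg, genes, truth)
    proteomics = generate_proteomics(cfg, truth)
    tracks = generate_tracks(cfg, peaks, genes, cfg.samples) if with_tracks else None
    return SimData(cfg, genes, truth, expr, peaks, proteomics, tracks)
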