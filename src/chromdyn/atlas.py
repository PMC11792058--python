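"""Unified peak atlas, binary presence matrix, and occupancy-pattern taxonomy.

A time-course ATAC experiment with a control arm and a knockdown arm yields,
per unified locus, a binary occupancy string across the ordered samples
(arm-major, time-minor).  Splitting that string into the two arms gives a
(control, knockdown) pair of time-ordered bit vectors that is classified into
one of nine dynamic categories (permanently open, accelerated/decelerated
opening/closing, knockdown-specific open/closed, stable-other, complex).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeInterval

PATTERN_CATEGORIES = (
    "permanently_open",
    "stable_other",
    "accelerated_opening",
    "decelerated_opening",
    "accelerated_closing",
    "decelerated_closing",
    "kd_specific_open",
    "kd_specific_closed",
    "complex",
)


@dataclass(frozen=True)
class PeakCall:
    """One called peak in one sample; ``sample_id`` is an (arm, timepoint) pair."""

    interval: GenomeInterval
    summit: int
    score: float = 0.0
    sample_id: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )


def peaks_from_narrowpeak(df: pd.DataFrame, sample_id: tuple[str, str] | None = None
                          ) -> list[PeakCall]:
    """Convert a narrowPeak DataFrame (see :func:`chromdyn.io.read_narrowpeak`)."""
    return [
        PeakCall(GenomeInterval(r.chrom, int(r.start), int(r.end)),
                 int(r.summit), float(r.score), sample_id)
        for r in df.itertuples(index=False)
    ]


def unify_peaks(peak_sets: Iterable[Sequence[PeakCall]],
                min_overlap: int = 1) -> list[GenomeInterval]:
    """Merge all peaks across samples into a unified locus atlas.

    Loci are the connected components of the overlap graph (single-linkage:
    two peaks link when they share >= ``min_overlap`` bp); each atlas
    interval spans the union of its members.  Returned sorted by
    (chrom, start).  Idempotent: unifying the atlas returns the atlas.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ivs = sorted(
        (p.interval for peaks in peak_sets for p in peaks),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    atlas: list[GenomeInterval] = []
    cur = None
    for iv in ivs:
        if cur is not None and iv.chrom == cur.chrom and \
                min(cur.end, iv.end) - iv.start >= min_overlap:
            if iv.end > cur.end:
                cur = GenomeInterval(cur.chrom, cur.start, iv.end)
        else:
            if cur is not None:
                atlas.append(cur)
            cur = GenomeInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        atlas.append(cur)
    return atlas


@dataclass
class PresenceMatrix:
    """Binary occupancy of atlas loci (rows) across ordered samples (columns)."""

    loci: list[GenomeInterval]
    samples: list[tuple[str, str]]
    cells: np.ndarray  # shape (n_loci, n_samples), dtype int8
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.loci), len(self.samples)):
            raise ValueError("cells shape does not match loci x samples")
        if not self.locus_ids:
            self.locus_ids = [f"locus_{i:06d}" for i in range(len(self.loci))]

    def pattern(self, i: int) -> str:
        return "".join(str(b) for b in self.cells[i])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{arm}_{tp}" for arm, tp in self.samples]
        df = pd.DataFrame(self.cells, columns=cols, index=self.locus_ids)
        df.insert(0, "chrom", [iv.chrom for iv in self.loci])
        df.insert(1, "start", [iv.start for iv in self.loci])
        df.insert(2, "end", [iv.end for iv in self.loci])
        return df


def _overlap_hits(atlas_starts: np.ndarray, atlas_ends: np.ndarray,
                  start: int, end: int) -> range:
    """Indices of disjoint sorted atlas intervals overlapping [start, end)."""
    lo = int(np.searchsorted(atlas_ends, start, side="right"))
    hi = int(np.searchsorted(atlas_starts, end, side="left"))
    return range(lo, hi)


def presence_matrix(atlas: Sequence[GenomeInterval],
                    peak_sets: Mapping[tuple[str, str], Sequence[PeakCall]],
                    sample_order: Sequence[tuple[str, str]] | None = None,
                    ) -> PresenceMatrix:
    """Build the loci x samples 0/1 matrix (cell = 1 iff >= 1 bp overlap).

    ``sample_order`` fixes column order (arm-major, time-minor is the
    convention used by the pipeline); by default insertion order is kept.
    A sample with zero peaks yields an all-zero column.
    """
    samples = list(sample_order) if sample_order is not None else list(peak_sets)
    loci = list(atlas)
    # atlas intervals are disjoint within a chromosome; index them per chrom
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in sorted({iv.chrom for iv in loci}):
        idx = np.array([i for i, iv in enumerate(loci) if iv.chrom == chrom])
        starts = np.array([loci[i].start for i in idx])
        srt = np.argsort(starts, kind="stable")
        idx = idx[srt]
        by_chrom[chrom] = (
            np.array([loci[i].start for i in idx]),
            np.array([loci[i].end for i in idx]),
            idx,
        )
    cells = np.zeros((len(loci), len(samples)), dtype=np.int8)
    for j, sid in enumerate(samples):
        for p in peak_sets.get(sid, ()):  # type: ignore[call-overload]
            entry = by_chrom.get(p.interval.chrom)
            if entry is None:
                continue
            starts, ends, idx = entry
            for k in _overlap_hits(starts, ends, p.interval.start, p.interval.end):
                cells[idx[k], j] = 1
    return PresenceMatrix(loci, samples, cells)


def select_dynamic(matrix: PresenceMatrix) -> np.ndarray:
    """Boolean mask of loci whose pattern changes (drops constant-1 rows).

    Constant-0 rows cannot occur when the atlas was built from the same
    peak sets (a locus exists only because some sample had a peak).
    """
    return ~(matrix.cells == 1).all(axis=1)


# -- pattern taxonomy -------------------------------------------------------

def _as_bits(bits) -> tuple[int, ...]:
    if isinstance(bits, str):
        bits = bits.replace(" ", "")
        if not set(bits) <= {"0", "1"}:
            raise ValueError(f"invalid pattern string {bits!r}")
        return tuple(int(c) for c in bits)
    out = tuple(int(b) for b in bits)
    if not set(out) <= {0, 1}:
        raise ValueError(f"invalid bit values in {out!r}")
    return out


def is_monotone(bits: Sequence[int]) -> bool:
    """True when the pattern is a staircase: at most one 0->1 or 1->0 step."""
    transitions = sum(a != b for a, b in zip(bits, bits[1:]))
    return transitions <= 1


def repair_pattern(bits) -> tuple[int, ...]:
    """Deletion-aware smoothing of a non-monotone occupancy pattern.

    Peak dropout only deletes presence calls, so the maximum-likelihood
    correction of a non-monotone pattern is the monotone *superset*
    reachable with the fewest 0->1 additions.  Ties break toward the
    latest first-open index (the conservative reading: open late rather
    than early).  Already-monotone patterns are returned unchanged.
    """
    bits = _as_bits(bits)
    if is_monotone(bits):
        return bits
    n = len(bits)
    zero_pos = [i for i in range(n) if bits[i] == 0]
    best: tuple[int, ...] | None = None
    best_key: tuple[int, int] | None = None
    for mask in range(1, 1 << len(zero_pos)):
        cand = list(bits)
        additions = 0
        for bit_i, pos in enumerate(zero_pos):
            if mask >> bit_i & 1:
                cand[pos] = 1
                additions += 1
        cand_t = tuple(cand)
        if not is_monotone(cand_t):
            continue
        first_open = next(i for i, b in enumerate(cand_t) if b == 1)
        key = (additions, -first_open)
        if best_key is None or key < best_key:
            best, best_key = cand_t, key
    assert best is not None  # all-ones superset is always monotone
    return best


def _settle_index(bits: Sequence[int], target: int) -> int:
    """Index after which the arm stays in ``target`` state (len if never)."""
    n = len(bits)
    k = n
    while k > 0 and bits[k - 1] == target:
        k -= 1
    return k


def classify_pattern(control_bits, kd_bits, smooth: bool = False) -> str:
    """Assign a (control, knockdown) occupancy-pattern pair to a category.

    Rules, applied in order:

    1. control all-0 (knockdown has a peak somewhere) -> ``kd_specific_open``
    2. control all-1: knockdown all-1 -> ``permanently_open``,
       else -> ``kd_specific_closed``
    3. any non-monotone arm -> ``complex``
    4. identical non-constant arms -> ``stable_other``
    5. otherwise the control arm is a non-constant staircase; its direction
       (opening 0->1 or closing 1->0) is read off, and each arm's settling
       index into the control's final state is compared: knockdown settles
       earlier -> accelerated, later -> decelerated, same -> ``stable_other``.

    With ``smooth=True`` each arm is first passed through
    :func:`repair_pattern`.  The all-zero pair is inadmissible (no locus
    would exist) and raises ``ValueError``.
    """
    c = _as_bits(control_bits)
    k = _as_bits(kd_bits)
    if len(c) != len(k):
        raise ValueError(f"arm length mismatch: {len(c)} vs {len(k)}")
    if len(c) < 2:
        raise ValueError("need >= 2 time points per arm")
    if not any(c) and not any(k):
        raise ValueError("all-zero pattern pair is inadmissible")
    if smooth:
        c, k = repair_pattern(c), repair_pattern(k)
    if not any(c):
        return "kd_specific_open"
    if all(c):
        return "permanently_open" if all(k) else "kd_specific_closed"
    if not is_monotone(c) or not is_monotone(k):
        return "complex"
    if c == k:
        return "stable_other"
    direction = "opening" if c[0] == 0 else "closing"
    target = 1 if direction == "opening" else 0
    kc, kk = _settle_index(c, target), _settle_index(k, target)
    if kk < kc:
        return f"accelerated_{direction}"
    if kk > kc:
        return f"decelerated_{direction}"
    return "stable_other"


def classify_matrix(matrix: PresenceMatrix, arms: Sequence[str] | None = None,
                    smooth: bool = False) -> pd.DataFrame:
    """Classify every locus of a presence matrix.

    The sample order must be arm-major with two arms (control first); the
    row is split midway into the control and knockdown bit vectors.
    """
    sample_arms = [arm for arm, _ in matrix.samples]
    if arms is None:
        arms = list(dict.fromkeys(sample_arms))
    if len(arms) != 2:
        raise ValueError(f"expected exactly 2 arms, got {arms}")
    ctrl_cols = [j for j, a in enumerate(sample_arms) if a == arms[0]]
    kd_cols = [j for j, a in enumerate(sample_arms) if a == arms[1]]
    if len(ctrl_cols) != len(kd_cols) or not ctrl_cols:
        raise ValueError("arms must have equal numbers of time points")
    records = []
    for i, locus_id in enumerate(matrix.locus_ids):
        row = matrix.cells[i]
        cat = classify_pattern(row[ctrl_cols], row[kd_cols], smooth=smooth)
        iv = matrix.loci[i]
        records.append((locus_id, iv.chrom, iv.start, iv.end,
                        matrix.pattern(i), cat))
    return pd.DataFrame(
        records, columns=["locus_id", "chrom", "start", "end", "pattern", "category"]
    ).set_index("locus_id")
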