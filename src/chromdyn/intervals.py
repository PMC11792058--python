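"""Genomic interval and gene-model primitives.

All coordinates in this package are 0-based, half-open (BED convention).
GTF input (1-based, inclusive) is converted on read; see :mod:`chromdyn.io`.
Chromosome names are compared as exact strings ("chr1" != "1"); use
:func:`normalize_chrom` to strip or add the "chr" prefix beforehand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end}; "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        """True if the two intervals share >= 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start (TSS) and end (TTS).

    On the + strand the TSS is ``start`` and the TTS ``end - 1``; on the
    - strand the two are mirrored.  Genes must be stranded and at least
    2 bp long so that TSS != TTS.
    """

    gene_id: str
    interval: GenomeInterval

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if len(self.interval) < 2:
            raise ValueError(f"gene {self.gene_id}: length must be >= 2 bp")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


def interval_gene_distance(iv: GenomeInterval, gene: GeneModel) -> float:
    """Distance in bp between an interval and a gene's TSS.

    Returns 0 when the TSS lies inside ``[start, end)``, otherwise the
    distance to the nearer interval edge.  Different chromosomes are
    incomparable and return ``math.inf``.
    """
    if iv.chrom != gene.chrom:
        return math.inf
    tss = gene.tss
    if iv.start <= tss < iv.end:
        return 0
    return min(abs(tss - iv.start), abs(tss - (iv.end - 1)))


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Normalize a chromosome name to the "chr"-prefixed or bare style."""
    if style == "chr":
        return name if name.startswith("chr") else "chr" + name
    if style == "bare":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"unknown style {style!r}; use 'chr' or 'bare'")
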