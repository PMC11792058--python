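"""Readers and writers for the tab-separated genomic formats the pipeline uses.

BED family files are headerless TSV; expression, gene-set and proteomics
tables carry a header row.  GTF coordinates (1-based inclusive) are converted
to the package-wide 0-based half-open convention on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GeneModel, GenomeInterval

_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}, line {lineno}: {msg}")


def read_bed(path) -> list[GenomeInterval]:
    """Read a BED3/BED6 file into intervals (strand kept when present)."""
    out: list[GenomeInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, "expected >= 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise _parse_error(path, lineno, "non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                out.append(GenomeInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
    return out


def write_bed6(path, intervals: Iterable[GenomeInterval], names: Sequence[str] | None = None,
               scores: Sequence[float] | None = None) -> None:
    """Write intervals as BED6 (tab-separated, no header)."""
    intervals = list(intervals)
    names = names if names is not None else [f"region_{i}" for i in range(len(intervals))]
    scores = scores if scores is not None else [0] * len(intervals)
    with open(path, "w") as fh:
        for iv, name, score in zip(intervals, names, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def _finish_genes(genes: list[GeneModel], path) -> list[GeneModel]:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def read_bed12_genes(path) -> list[GeneModel]:
    """Read gene models from a BED6/BED12 file (first six columns used)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise _parse_error(path, lineno, "expected >= 6 BED columns for genes")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise _parse_error(path, lineno, "non-integer coordinates") from None
            name, strand = fields[3], fields[5]
            try:
                genes.append(GeneModel(name, GenomeInterval(chrom, start, end, strand)))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
    return _finish_genes(genes, path)


def read_gtf_genes(path) -> list[GeneModel]:
    """Read gene features from a GTF file.

    Only ``gene`` feature lines are used.  GTF start (1-based) becomes
    ``start - 1``; GTF end is already the half-open end.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise _parse_error(path, lineno, "expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            m = _GTF_GENE_ID.search(fields[8])
            if m is None:
                raise _parse_error(path, lineno, "missing gene_id attribute")
            try:
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError:
                raise _parse_error(path, lineno, "non-integer coordinates") from None
            try:
                genes.append(GeneModel(m.group(1), GenomeInterval(fields[0], start, end, fields[6])))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
    return _finish_genes(genes, path)


def read_annotation(path, format: str = "bed12") -> list[GeneModel]:
    """Read a gene annotation in the named dialect (``gtf`` or ``bed12``)."""
    if format == "bed12":
        return read_bed12_genes(path)
    if format == "gtf":
        return read_gtf_genes(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_genes_bed(path, genes: Iterable[GeneModel]) -> None:
    genes = list(genes)
    write_bed6(path, [g.interval for g in genes], names=[g.gene_id for g in genes])


# -- narrowPeak -------------------------------------------------------------

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "summit_offset",
]


def read_narrowpeak(path) -> pd.DataFrame:
    """Read a narrowPeak (BED6+4) file into a DataFrame with absolute summits."""
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS,
                     dtype={"chrom": str})
    if df.empty:
        df["summit"] = pd.Series(dtype=int)
        return df
    bad = ~(df["start"] < df["end"])
    if bad.any():
        raise ValueError(f"{path}: start >= end at line {int(bad.idxmax()) + 1}")
    df["summit"] = df["start"] + df["summit_offset"]
    off = ~((df["summit"] >= df["start"]) & (df["summit"] < df["end"]))
    if off.any():
        raise ValueError(f"{path}: summit outside peak at line {int(off.idxmax()) + 1}")
    return df


def write_narrowpeak(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=NARROWPEAK_COLUMNS)


# -- bedGraph ---------------------------------------------------------------

def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph into a (chrom, start, end, value) DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"], dtype={"chrom": str})
    if (df["value"] < 0).any():
        raise ValueError(f"{path}: negative coverage values")
    return df


def write_bedgraph(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


# -- tables -----------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def write_expression(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read a two-column (set, gene) TSV into named gene lists."""
    df = pd.read_csv(path, sep="\t", header=0, names=["set", "gene"])
    return {name: sub["gene"].tolist() for name, sub in df.groupby("set", sort=False)}


def write_gene_sets(path, sets: dict[str, Sequence[str]]) -> None:
    rows = [(name, g) for name, genes in sets.items() for g in genes]
    pd.DataFrame(rows, columns=["set", "gene"]).to_csv(path, sep="\t", index=False)


def read_proteomics(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a proteinGroups-style TSV.

    ``column_map`` renames source columns onto the canonical
    (name, unique_peptides, bait_intensity, control_intensity) schema.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    required = ["name", "unique_peptides", "bait_intensity", "control_intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in required[1:]:
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative values in {col}")
    return df[required]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
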