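"""AP-MS (Co-IP/mass-spec) interactor filtering and cell-type set comparison.

A protein pulled down with the bait counts as an interactor when it has at
least one unique peptide, a minimum bait intensity (default 1e6), bait
intensity at least 2-fold above the mock/control pulldown, and a name not
matching a list of common-contaminant prefixes (ribosomal, cytoskeletal,
immunoglobulin and housekeeping families).  A control intensity of zero
passes the ratio rule: absence from the control is the strongest evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

#: Common-contaminant protein-name prefixes (capitalized gene symbols).
CONTAMINANT_PREFIXES: tuple[str, ...] = (
    "Rpl", "Rps", "Tub", "Gapdh", "Act", "Myh", "Ighg", "Iglv", "Col",
    "Golga", "Kif", "Myl", "Krt", "Eif", "Vim", "Atp", "Igkv", "Ighv",
)

REJECTION_REASONS = ("peptides", "intensity", "ratio", "contaminant")


@dataclass(frozen=True)
class ProteinRecord:
    name: str
    unique_peptides: int
    bait_intensity: float
    control_intensity: float

    def __post_init__(self) -> None:
        if self.unique_peptides < 0:
            raise ValueError(f"{self.name}: negative peptide count")
        if self.bait_intensity < 0 or self.control_intensity < 0:
            raise ValueError(f"{self.name}: negative intensity")


@dataclass
class InteractorSet:
    """Filtered interactors for one cell type, with per-record rejection reasons."""

    cell_type: str
    passing: list[ProteinRecord]
    rejected: dict[str, str] = field(default_factory=dict)  # name -> first failing rule
    rejected_records: list[ProteinRecord] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return sorted(r.name for r in self.passing)


def records_from_frame(df: pd.DataFrame) -> list[ProteinRecord]:
    return [ProteinRecord(str(r.name), int(r.unique_peptides),
                          float(r.bait_intensity), float(r.control_intensity))
            for r in df.itertuples(index=False)]


def _first_failure(rec: ProteinRecord, min_peptides: int, min_intensity: float,
                   min_ratio: float, prefixes: Sequence[str],
                   case_sensitive: bool) -> str | None:
    if rec.unique_peptides < min_peptides:
        return "peptides"
    if rec.bait_intensity < min_intensity:
        return "intensity"
    # ratio rule as bait >= min_ratio * control; control 0 always passes
    if rec.bait_intensity < min_ratio * rec.control_intensity:
        return "ratio"
    name = rec.name if case_sensitive else rec.name.lower()
    for pref in prefixes:
        if name.startswith(pref if case_sensitive else pref.lower()):
            return "contaminant"
    return None


def filter_interactors(records: Iterable[ProteinRecord],
                       min_peptides: int = 1,
                       min_intensity: float = 1e6,
                       min_ratio: float = 2.0,
                       contaminant_prefixes: Sequence[str] = CONTAMINANT_PREFIXES,
                       case_sensitive: bool = True,
                       cell_type: str = "") -> InteractorSet:
    """Apply the four-rule interactor filter.

    Rules are tested in the order peptides -> intensity -> ratio ->
    contaminant and a rejected record carries the first failing reason.
    The filter is monotone (raising any threshold never adds a passing
    protein) and independent of record order.
    """
    passing: list[ProteinRecord] = []
    rejected: dict[str, str] = {}
    rejected_records: list[ProteinRecord] = []
    for rec in records:
        reason = _first_failure(rec, min_peptides, min_intensity, min_ratio,
                                contaminant_prefixes, case_sensitive)
        if reason is None:
            passing.append(rec)
        else:
            rejected[rec.name] = reason
            rejected_records.append(rec)
    return InteractorSet(cell_type, passing, rejected, rejected_records)


@dataclass
class SetComparison:
    common: list[str]
    a_only: list[str]
    b_only: list[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.common), len(self.a_only), len(self.b_only)


def compare_sets(a: InteractorSet, b: InteractorSet) -> SetComparison:
    """Name-keyed partition of two interactor sets (Venn-diagram counts)."""
    na, nb = set(a.names), set(b.names)
    return SetComparison(sorted(na & nb), sorted(na - nb), sorted(nb - na))


def annotate_regulators(iset: InteractorSet, tf_list: Sequence[str],
                        epi_list: Sequence[str]) -> pd.DataFrame:
    """Tag passing interactors as TF / epigenetic / both / other by exact symbol."""
    tfs, epis = set(tf_list), set(epi_list)
    rows = []
    for name in iset.names:
        is_tf, is_epi = name in tfs, name in epis
        tag = ("TF+epigenetic" if is_tf and is_epi else
               "TF" if is_tf else "epigenetic" if is_epi else "other")
        rows.append((name, is_tf, is_epi, tag))
    return pd.DataFrame(rows, columns=["name", "is_tf", "is_epigenetic",
                                       "tag"]).set_index("name")


def interactor_frame(iset: InteractorSet) -> pd.DataFrame:
    """Pass/fail table for export (one row per input record)."""
    rows = [(r.name, r.unique_peptides, r.bait_intensity, r.control_intensity,
             True, "") for r in iset.passing]
    rows += [(r.name, r.unique_peptides, r.bait_intensity, r.control_intensity,
              False, iset.rejected[r.name]) for r in iset.rejected_records]
    df = pd.DataFrame(rows, columns=["name", "unique_peptides", "bait_intensity",
                                     "control_intensity", "passed", "reason"])
    return df.sort_values("name").reset_index(drop=True)
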