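"""Detection and provenance classification of presence/absence conflicts.

A BOTH-valued cell means the aggregated literature simultaneously supports
presence and absence of one structure in one taxon.  Each such cell gets
exactly one category, assigned by a strongest-evidence precedence:

1. ``intra_source_polymorphism`` — a single source matrix directly asserts
   both values; treated as real published polymorphism and excluded from
   conflict totals rather than reviewed as a data conflict.
2. ``asserted_asserted`` — direct assertions on both sides, from different
   sources (authors genuinely disagree).
3. ``asserted_inferred`` — exactly one side has a direct assertion.
4. ``inferred_inferred`` — both sides rest on inference alone.

Conflicts are reported, never auto-resolved: determining the cause of a
conflict (new specimens, differing interpretations, annotation slips)
requires expert review, which the provenance in each record is meant to
support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .ontology import TermId
from .synthesis import (
    CellValue,
    SupportMode,
    SupportRecord,
    SyntheticMatrix,
)

__all__ = [
    "ConflictCategory",
    "ConflictRecord",
    "classify_conflict",
    "conflict_report",
    "conflict_report_json",
    "detect_conflicts",
]


class ConflictCategory(str, Enum):
    ASSERTED_ASSERTED = "asserted_asserted"
    ASSERTED_INFERRED = "asserted_inferred"
    INFERRED_INFERRED = "inferred_inferred"
    INTRA_SOURCE_POLYMORPHISM = "intra_source_polymorphism"


@dataclass(frozen=True)
class ConflictRecord:
    taxon: TermId
    entity: TermId
    category: ConflictCategory
    presence_supports: Tuple[SupportRecord, ...]
    absence_supports: Tuple[SupportRecord, ...]

    @property
    def excluded_from_conflict_counts(self) -> bool:
        return self.category is ConflictCategory.INTRA_SOURCE_POLYMORPHISM


def classify_conflict(
    presence_supports: Sequence[SupportRecord],
    absence_supports: Sequence[SupportRecord],
) -> ConflictCategory:
    """Assign the category of one BOTH cell from its two support lists."""
    if not presence_supports or not absence_supports:
        raise ValueError("a conflict cell needs supports on both sides")
    asserted_p_sources = {
        s.matrix_id for s in presence_supports if s.mode is SupportMode.ASSERTED
    }
    asserted_a_sources = {
        s.matrix_id for s in absence_supports if s.mode is SupportMode.ASSERTED
    }
    if asserted_p_sources & asserted_a_sources:
        return ConflictCategory.INTRA_SOURCE_POLYMORPHISM
    if asserted_p_sources and asserted_a_sources:
        return ConflictCategory.ASSERTED_ASSERTED
    if asserted_p_sources or asserted_a_sources:
        return ConflictCategory.ASSERTED_INFERRED
    return ConflictCategory.INFERRED_INFERRED


def detect_conflicts(m: SyntheticMatrix) -> List[ConflictRecord]:
    """One record per BOTH cell, in (taxon, entity) order.

    Intra-source polymorphism records are included in the returned list but
    flagged for exclusion from conflict counts.
    """
    records: List[ConflictRecord] = []
    for (taxon, entity), cell in sorted(m.cells.items()):
        if cell.value is not CellValue.BOTH:
            continue
        pres = tuple(s for s in cell.supports if s.value == "present")
        absn = tuple(s for s in cell.supports if s.value == "absent")
        records.append(
            ConflictRecord(
                taxon=taxon,
                entity=entity,
                category=classify_conflict(pres, absn),
                presence_supports=pres,
                absence_supports=absn,
            )
        )
    return records


def _side_provenance(supports: Sequence[SupportRecord]) -> str:
    return "; ".join(
        f"{s.matrix_id}:{s.char_id}:{s.state_id} ({s.mode.value})" for s in supports
    )


def conflict_report(records: Sequence[ConflictRecord]) -> pd.DataFrame:
    """Tabular conflict report (one row per BOTH cell).

    Columns: taxon, entity, category, excluded flag, and the provenance of
    each side (source:character:state with mode).  A conflict-free matrix
    yields a header-only table.
    """
    rows = [
        {
            "taxon": r.taxon,
            "entity": r.entity,
            "category": r.category.value,
            "excluded_from_conflict_counts": r.excluded_from_conflict_counts,
            "presence_provenance": _side_provenance(r.presence_supports),
            "absence_provenance": _side_provenance(r.absence_supports),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "taxon",
            "entity",
            "category",
            "excluded_from_conflict_counts",
            "presence_provenance",
            "absence_provenance",
        ],
    )


def conflict_report_json(records: Sequence[ConflictRecord]) -> str:
    """JSON report variant with embedded witness chains."""

    def support(s: SupportRecord) -> Dict:
        return {
            "matrix_id": s.matrix_id,
            "char_id": s.char_id,
            "state_id": s.state_id,
            "phenotype": s.phenotype.to_dict(),
            "mode": s.mode.value,
            "chain": [[a, rel.value, b] for a, rel, b in s.chain],
        }

    payload = [
        {
            "taxon": r.taxon,
            "entity": r.entity,
            "category": r.category.value,
            "excluded_from_conflict_counts": r.excluded_from_conflict_counts,
            "presence_supports": [support(s) for s in r.presence_supports],
            "absence_supports": [support(s) for s in r.absence_supports],
        }
        for r in records
    ]
    return json.dumps(payload, indent=1, sort_keys=True)


def conflict_counts(records: Sequence[ConflictRecord]) -> Dict[str, int]:
    """Category counts; intra-source polymorphism tallied separately."""
    counts = {c.value: 0 for c in ConflictCategory}
    for r in records:
        counts[r.category.value] += 1
    counts["total_both_cells"] = len(records)
    counts["total_conflicts"] = len(records) - counts[
        ConflictCategory.INTRA_SOURCE_POLYMORPHISM.value
    ]
    return counts
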