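"""Synthesis of entity-by-taxon presence/absence supermatrices.

Given anatomy and taxonomy ontologies, a set of EQ-annotated source
matrices, and two class expressions (one selecting anatomical entities, one
selecting a taxonomic group), build a synthetic supermatrix:

1. one synthetic character per anatomical class subsumed by the entity
   expression;
2. one row per source taxon falling inside the taxon expression;
3. each cell populated from every published state whose EQ annotations
   entail presence or absence of that character's entity for that taxon,
   carrying full provenance (source matrix, published character/state,
   phenotype, witness chain) per supporting record.

A cell's value is a pure function of its supports: PRESENT, ABSENT, BOTH
(polymorphism/conflict), or MISSING when no annotation path exists.  Each
support is flagged ``asserted`` when the published state directly asserts
presence/absence of the character's exact entity (quality PATO:0000467 or
PATO:0000462), and ``inferred`` otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .eq_model import (
    ABSENT_QUALITY,
    EQPhenotype,
    Polarity,
    PRESENT_QUALITY,
    SourceMatrix,
)
from .expression import ClassExpression, evaluate_expression, parse_expression
from .ontology import (
    CLOSURE_RELATIONS,
    Edge,
    Ontology,
    TermId,
    closure_path,
    downward_closure,
    upward_closure,
)

logger = logging.getLogger(__name__)

TOOL_VERSION = "phenosynth 0.1.0"


class CellValue(str, Enum):
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    BOTH = "BOTH"
    MISSING = "MISSING"


class SupportMode(str, Enum):
    ASSERTED = "asserted"
    INFERRED = "inferred"


class VariabilityBasis(str, Enum):
    """Why a variable character is variable (per-column provenance class)."""

    ASSERTED_ONLY = "asserted_only"  # asserted supports alone make it variable
    VARIABLE_ONLY_BY_INFERENCE = "variable_only_by_inference"
    INFERRED_ONLY = "inferred_only"  # no asserted support anywhere in column


@dataclass(frozen=True)
class SupportRecord:
    """Provenance for one supporting (source, character, state, phenotype)."""

    taxon: TermId
    matrix_id: str
    char_id: str
    state_id: str
    phenotype: EQPhenotype
    value: str  # "present" | "absent"
    mode: SupportMode
    chain: Tuple[Edge, ...] = ()

    def sort_key(self):
        return (self.matrix_id, self.char_id, self.state_id, self.value,
                self.phenotype.entity, self.phenotype.quality,
                self.phenotype.related_entity or "")


@dataclass(frozen=True)
class SyntheticCell:
    value: CellValue
    supports: Tuple[SupportRecord, ...] = ()


def cell_value_from_supports(supports: Sequence[SupportRecord]) -> CellValue:
    values = {s.value for s in supports}
    if not values:
        return CellValue.MISSING
    if values == {"present"}:
        return CellValue.PRESENT
    if values == {"absent"}:
        return CellValue.ABSENT
    return CellValue.BOTH


@dataclass
class SyntheticMatrix:
    """The synthesized supermatrix.

    ``cells`` stores populated cells only; :meth:`cell` returns a MISSING
    cell for any in-grid coordinate without supports.  Characters and taxa
    are kept lexicographically sorted so identical inputs serialize
    byte-identically.
    """

    characters: Tuple[TermId, ...]
    taxa: Tuple[TermId, ...]
    cells: Dict[Tuple[TermId, TermId], SyntheticCell] = field(default_factory=dict)
    entity_expression: str = ""
    taxon_expression: str = ""
    source_ids: Tuple[str, ...] = ()
    tool_version: str = TOOL_VERSION
    timestamp: Optional[str] = None
    variability_basis: Dict[TermId, VariabilityBasis] = field(default_factory=dict)

    def cell(self, taxon: TermId, entity: TermId) -> SyntheticCell:
        return self.cells.get((taxon, entity), SyntheticCell(CellValue.MISSING))

    def column(self, entity: TermId) -> Tuple[CellValue, ...]:
        return tuple(self.cell(t, entity).value for t in self.taxa)

    @property
    def n_cells(self) -> int:
        return len(self.characters) * len(self.taxa)


# ----------------------------------------------------------------------


def generate_characters(
    anatomy: Ontology, expr: Union[str, ClassExpression]
) -> List[TermId]:
    """One synthetic character per anatomy class subsumed by ``expr``.

    Lexicographically ordered; pruning to entities with support happens
    later in :func:`synthesize`.
    """
    if isinstance(expr, str):
        expr = parse_expression(expr)
    result = sorted(evaluate_expression(anatomy, expr))
    if not result:
        logger.warning("entity expression selected no anatomy classes")
    return result


def select_taxa(
    taxonomy: Ontology,
    taxon_expr: Union[str, ClassExpression],
    sources: Sequence[SourceMatrix],
) -> List[TermId]:
    """Source taxa subsumed by the taxon expression, sorted.

    Only taxa that actually appear in a source cell are candidates; a taxon
    outside the clade is excluded no matter how richly annotated.
    """
    if isinstance(taxon_expr, str):
        taxon_expr = parse_expression(taxon_expr)
    clade = evaluate_expression(taxonomy, taxon_expr)
    with_data: Set[TermId] = set()
    for m in sources:
        for (taxon, _char), _states in m.cells.items():
            with_data.add(taxon)
    return sorted(with_data & clade)


def _direct_assertion(p: EQPhenotype, entity: TermId) -> bool:
    """The published-state annotation directly asserts P/A of ``entity``.

    Requires the exact character entity (not a subclass or part) and one of
    the designated present/absent qualities.
    """
    if p.polarity is Polarity.PRESENCE_TYPE:
        return p.entity == entity and p.quality == PRESENT_QUALITY
    return p.negated_entity == entity and p.quality == ABSENT_QUALITY


def synthesize(
    anatomy: Ontology,
    taxonomy: Ontology,
    sources: Sequence[SourceMatrix],
    entity_expr: Union[str, ClassExpression],
    taxon_expr: Union[str, ClassExpression],
    prune: str = "populated",
    asserted_only: bool = False,
    timestamp: Optional[str] = None,
) -> SyntheticMatrix:
    """Build the supermatrix.

    Parameters
    ----------
    prune:
        ``"none"`` keeps every selected character and taxon; ``"populated"``
        (default) drops all-missing columns and rows; ``"variable"``
        additionally restricts to variable characters via
        :func:`variable_subset`.
    asserted_only:
        Restrict supports to direct assertions (inference disabled).  The
        populated cells of such a run are always a subset of the full
        run's.
    timestamp:
        Optional build timestamp recorded in matrix metadata; leave None
        for byte-reproducible output.

    Raises a hard error listing offenders if source annotations reference
    anatomy terms unknown to the ontology.
    """
    if prune not in ("none", "populated", "variable"):
        raise ValueError(f"unknown prune policy {prune!r}")
    entity_expr_text = entity_expr if isinstance(entity_expr, str) else repr(entity_expr)
    taxon_expr_text = taxon_expr if isinstance(taxon_expr, str) else repr(taxon_expr)

    characters = generate_characters(anatomy, entity_expr)
    charset = set(characters)
    taxa = select_taxa(taxonomy, taxon_expr, sources)
    taxa_set = set(taxa)

    dangling: Set[TermId] = set()
    supports: Dict[Tuple[TermId, TermId], List[SupportRecord]] = {}

    for m in sources:
        char_index = {c.char_id: c for c in m.characters}
        for (taxon, char_id), state_ids in sorted(m.cells.items()):
            if taxon not in taxa_set:
                continue
            pub_char = char_index[char_id]
            for state_id in sorted(state_ids):
                state = pub_char.state(state_id)
                for p in state.phenotypes:
                    anchor = (
                        p.entity
                        if p.polarity is Polarity.PRESENCE_TYPE
                        else p.negated_entity
                    )
                    if anchor not in anatomy.terms:
                        dangling.add(anchor)
                        continue
                    if p.polarity is Polarity.PRESENCE_TYPE:
                        targets = _affected_up(anatomy, anchor)
                        value = "present"
                    else:
                        targets = _affected_down(anatomy, anchor)
                        value = "absent"
                    for entity in targets & charset:
                        mode = (
                            SupportMode.ASSERTED
                            if _direct_assertion(p, entity)
                            else SupportMode.INFERRED
                        )
                        if asserted_only and mode is not SupportMode.ASSERTED:
                            continue
                        chain = closure_path(
                            anatomy,
                            anchor,
                            entity,
                            CLOSURE_RELATIONS,
                            reverse=(value == "absent"),
                        )
                        rec = SupportRecord(
                            taxon=taxon,
                            matrix_id=m.matrix_id,
                            char_id=char_id,
                            state_id=state_id,
                            phenotype=p,
                            value=value,
                            mode=mode,
                            chain=tuple(chain),
                        )
                        supports.setdefault((taxon, entity), []).append(rec)

    if dangling:
        raise ValueError(
            "source annotations reference anatomy terms unknown to the "
            f"ontology: {sorted(dangling)}"
        )

    cells = {
        key: SyntheticCell(
            value=cell_value_from_supports(recs),
            supports=tuple(sorted(recs, key=SupportRecord.sort_key)),
        )
        for key, recs in supports.items()
    }

    matrix = SyntheticMatrix(
        characters=tuple(characters),
        taxa=tuple(taxa),
        cells=cells,
        entity_expression=entity_expr_text,
        taxon_expression=taxon_expr_text,
        source_ids=tuple(sorted(m.matrix_id for m in sources)),
        timestamp=timestamp,
    )
    if prune in ("populated", "variable"):
        matrix = prune_empty(matrix)
    if prune == "variable":
        matrix = variable_subset(matrix)
    return matrix


def _affected_up(anatomy: Ontology, anchor: TermId) -> Set[TermId]:
    """Entities whose presence is entailed by presence of ``anchor``."""
    return upward_closure(anatomy, anchor, CLOSURE_RELATIONS)


def _affected_down(anatomy: Ontology, anchor: TermId) -> Set[TermId]:
    """Entities whose absence is entailed by absence of ``anchor``."""
    return downward_closure(anatomy, anchor, CLOSURE_RELATIONS)


def prune_empty(m: SyntheticMatrix) -> SyntheticMatrix:
    """Drop all-missing character columns and taxon rows."""
    populated_chars = sorted({e for (_t, e) in m.cells})
    populated_taxa = sorted({t for (t, _e) in m.cells})
    keep_chars = tuple(c for c in m.characters if c in set(populated_chars))
    keep_taxa = tuple(t for t in m.taxa if t in set(populated_taxa))
    return replace(m, characters=keep_chars, taxa=keep_taxa)


def variable_subset(m: SyntheticMatrix) -> SyntheticMatrix:
    """Restrict to variable characters (both values somewhere in column).

    A BOTH cell alone makes a column variable.  All-missing rows are
    dropped after subsetting, and each kept character is annotated with the
    provenance class of its variability: whether direct assertions alone
    make it variable, whether inference was required, or whether the column
    holds no direct assertion at all.
    """
    keep: List[TermId] = []
    basis: Dict[TermId, VariabilityBasis] = {}
    for entity in m.characters:
        col_values: Set[CellValue] = set()
        asserted_values: Set[str] = set()
        any_asserted = False
        for taxon in m.taxa:
            cell = m.cell(taxon, entity)
            if cell.value is CellValue.MISSING:
                continue
            col_values.add(cell.value)
            for s in cell.supports:
                if s.mode is SupportMode.ASSERTED:
                    any_asserted = True
                    asserted_values.add(s.value)
        variable = (CellValue.BOTH in col_values) or (
            CellValue.PRESENT in col_values and CellValue.ABSENT in col_values
        )
        if not variable:
            continue
        keep.append(entity)
        if not any_asserted:
            basis[entity] = VariabilityBasis.INFERRED_ONLY
        elif len(asserted_values) == 2:
            basis[entity] = VariabilityBasis.ASSERTED_ONLY
        else:
            basis[entity] = VariabilityBasis.VARIABLE_ONLY_BY_INFERENCE

    keep_set = set(keep)
    cells = {k: v for k, v in m.cells.items() if k[1] in keep_set}
    populated_taxa = {t for (t, _e) in cells}
    taxa = tuple(t for t in m.taxa if t in populated_taxa)
    return replace(
        m,
        characters=tuple(keep),
        taxa=taxa,
        cells=cells,
        variability_basis=basis,
    )


def cell_dump_rows(m: SyntheticMatrix) -> List[Dict[str, object]]:
    """Rows for a TSV dump: taxon, entity, value, n_asserted, n_inferred."""
    rows: List[Dict[str, object]] = []
    for taxon in m.taxa:
        for entity in m.characters:
            cell = m.cell(taxon, entity)
            if cell.value is CellValue.MISSING:
                continue
            n_asserted = sum(
                1 for s in cell.supports if s.mode is SupportMode.ASSERTED
            )
            rows.append(
                {
                    "taxon": taxon,
                    "entity": entity,
                    "value": cell.value.value,
                    "n_asserted": n_asserted,
                    "n_inferred": len(cell.supports) - n_asserted,
                }
            )
    return rows
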