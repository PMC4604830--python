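"""Quantification queries over sources and synthesized matrices.

Three reports, mirroring the questions a supermatrix curator asks:

* how much of the grid is populated, and how much of that rests on direct
  assertion versus inference (:func:`missing_data_stats`);
* how many published character states entail presence or absence of each
  entity for each taxon — the data behind anatomical-sampling heat maps
  (:func:`entailing_state_counts`);
* how many source matrices sampled each taxon
  (:func:`taxon_source_counts`).

All reports are pure functions of their inputs; rerunning them is
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple, Union

import pandas as pd

from .eq_model import Polarity, SourceMatrix
from .expression import ClassExpression, evaluate_expression, parse_expression
from .ontology import CLOSURE_RELATIONS, Ontology, TermId, downward_closure, upward_closure
from .synthesis import (
    CellValue,
    SupportMode,
    SyntheticMatrix,
    cell_value_from_supports,
)

__all__ = [
    "MissingDataStats",
    "entailing_state_counts",
    "missing_data_stats",
    "taxon_source_counts",
]


@dataclass(frozen=True)
class MissingDataStats:
    """Cell-grid bookkeeping for one synthesized matrix.

    ``n_populated = n_asserted_cells + n_inferred_only_cells``; fractions
    lie in [0, 1] and are defined as 1.0 missing for an empty grid.
    ``frac_missing_asserted_only`` re-derives every cell from its asserted
    supports alone, i.e. it reports the missing-data fraction the matrix
    would have had without inference.
    """

    n_cells: int
    n_populated: int
    n_asserted_cells: int
    n_inferred_only_cells: int
    frac_missing_with_inference: float
    frac_missing_asserted_only: float


def missing_data_stats(m: SyntheticMatrix) -> MissingDataStats:
    """Count populated/asserted/inferred-only cells and missing fractions."""
    n_cells = m.n_cells
    n_populated = 0
    n_asserted = 0
    n_asserted_only_populated = 0
    for cell in m.cells.values():
        if cell.value is CellValue.MISSING:  # not stored in practice
            continue
        n_populated += 1
        if any(s.mode is SupportMode.ASSERTED for s in cell.supports):
            n_asserted += 1
        asserted_supports = [
            s for s in cell.supports if s.mode is SupportMode.ASSERTED
        ]
        if cell_value_from_supports(asserted_supports) is not CellValue.MISSING:
            n_asserted_only_populated += 1
    if n_cells == 0:
        return MissingDataStats(0, 0, 0, 0, 1.0, 1.0)
    return MissingDataStats(
        n_cells=n_cells,
        n_populated=n_populated,
        n_asserted_cells=n_asserted,
        n_inferred_only_cells=n_populated - n_asserted,
        frac_missing_with_inference=1.0 - n_populated / n_cells,
        frac_missing_asserted_only=1.0 - n_asserted_only_populated / n_cells,
    )


def entailing_state_counts(
    sources: Sequence[SourceMatrix],
    anatomy: Ontology,
    taxonomy: Ontology,
    entities: Sequence[TermId],
    taxa: Sequence[TermId],
) -> pd.DataFrame:
    """Taxon-by-entity counts of entailing published states.

    ``count[t][e]`` is the number of distinct (source, character, state)
    triples assigned to taxon ``t`` carrying at least one phenotype that
    entails presence *or* absence of ``e``.  States are the counting unit:
    a state with several entailing phenotypes for the same entity counts
    once; each assigned state of a polymorphic cell counts once.  Row and
    column order follow the input lists.
    """
    for e in entities:
        anatomy._require(e)
    entity_set = set(entities)
    taxon_set = set(taxa)
    # triples[taxon][entity] -> set of (matrix, char, state)
    hits: Dict[Tuple[TermId, TermId], Set[Tuple[str, str, str]]] = {}
    for m in sources:
        char_index = {c.char_id: c for c in m.characters}
        for (taxon, char_id), state_ids in m.cells.items():
            if taxon not in taxon_set:
                continue
            for state_id in state_ids:
                state = char_index[char_id].state(state_id)
                affected: Set[TermId] = set()
                for p in state.phenotypes:
                    if p.polarity is Polarity.PRESENCE_TYPE:
                        anchor = p.entity
                        if anchor in anatomy.terms:
                            affected |= upward_closure(
                                anatomy, anchor, CLOSURE_RELATIONS
                            )
                    else:
                        anchor = p.negated_entity
                        if anchor in anatomy.terms:
                            affected |= downward_closure(
                                anatomy, anchor, CLOSURE_RELATIONS
                            )
                for entity in affected & entity_set:
                    hits.setdefault((taxon, entity), set()).add(
                        (m.matrix_id, char_id, state_id)
                    )
    data = [
        [len(hits.get((taxon, entity), ())) for entity in entities]
        for taxon in taxa
    ]
    return pd.DataFrame(data, index=list(taxa), columns=list(entities))


def taxon_source_counts(
    sources: Sequence[SourceMatrix],
    taxonomy: Ontology,
    taxon_expr: Union[str, ClassExpression],
) -> pd.DataFrame:
    """Per selected taxon: number of distinct source matrices and rank.

    A taxon counts toward a matrix if it has at least one cell there;
    duplicating states within one source never changes the count.
    """
    if isinstance(taxon_expr, str):
        taxon_expr = parse_expression(taxon_expr)
    clade = evaluate_expression(taxonomy, taxon_expr)
    matrices: Dict[TermId, Set[str]] = {}
    for m in sources:
        for (taxon, _char) in m.cells:
            if taxon in clade:
                matrices.setdefault(taxon, set()).add(m.matrix_id)
    rows = [
        {
            "taxon": taxon,
            "n_matrices": len(mids),
            "rank": taxonomy.ranks.get(taxon, ""),
        }
        for taxon, mids in sorted(matrices.items())
    ]
    return pd.DataFrame(rows, columns=["taxon", "n_matrices", "rank"])
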