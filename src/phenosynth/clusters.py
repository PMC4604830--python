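"""Isomorphic synthetic characters: detection and cause classification.

Ontology-driven synthesis necessarily produces groups of characters with
identical value columns — e.g. a presence assertion on "femur bone" induces
the same state for "hindlimb", "limb", and every other containing class.
Characters whose columns are identical across all taxa (including the
missing-data pattern) are collected into *isomorphic clusters*, and each
cluster is assigned an ontological cause by a deterministic cascade:

1. ``presence_equivalence`` — every member pair carries identical
   presence/absence information (equal supporter closures); such members
   are *guaranteed* isomorphic in any synthesized matrix.
2. ``co_assertion`` — the members' supports all trace to shared published
   states that annotate several cluster members at once (one state, many
   EQ annotations: "pedal digits 6, 7, and 8 present").
3. ``part_containment`` — members form a containment chain (each pair
   comparable under the closure relations) with supports anchored on a
   single member.
4. ``inference_chain`` — the residual: identical columns arising from
   unrelated chains of inference.

The cascade order resolves overlap between categories that are descriptive
in origin; equivalence is checked first because it is the only cause that
is a theorem rather than a diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .eq_model import Polarity, SourceMatrix
from .ontology import CLOSURE_RELATIONS, Ontology, TermId, downward_closure
from .reasoner import presence_class_equivalent
from .synthesis import CellValue, SupportMode, SyntheticMatrix

__all__ = [
    "ClusterCause",
    "IsoCluster",
    "classify_cluster",
    "cluster_report",
    "find_isomorphic_clusters",
]


class ClusterCause(str, Enum):
    PRESENCE_EQUIVALENCE = "presence_equivalence"
    CO_ASSERTION = "co_assertion"
    PART_CONTAINMENT = "part_containment"
    INFERENCE_CHAIN = "inference_chain"


@dataclass(frozen=True)
class IsoCluster:
    """A maximal set (>= 2) of characters with identical columns."""

    members: Tuple[TermId, ...]
    signature: Tuple[CellValue, ...]
    cause: Optional[ClusterCause] = None
    inferred_only: bool = False


def find_isomorphic_clusters(m: SyntheticMatrix) -> List[IsoCluster]:
    """Partition characters by exact column equality; drop singletons.

    Column equality is strict: PRESENT/ABSENT/BOTH values and the MISSING
    pattern must all coincide.  Clusters are ordered by their first member;
    members are sorted.
    """
    by_signature: Dict[Tuple[CellValue, ...], List[TermId]] = {}
    for entity in m.characters:
        by_signature.setdefault(m.column(entity), []).append(entity)
    clusters = [
        IsoCluster(
            members=tuple(sorted(members)),
            signature=sig,
            inferred_only=_inferred_only(m, members),
        )
        for sig, members in by_signature.items()
        if len(members) >= 2
    ]
    clusters.sort(key=lambda c: c.members)
    return clusters


def _inferred_only(m: SyntheticMatrix, members: Sequence[TermId]) -> bool:
    for entity in members:
        for taxon in m.taxa:
            for s in m.cell(taxon, entity).supports:
                if s.mode is SupportMode.ASSERTED:
                    return False
    return True


# ----------------------------------------------------------------------
# cause classification


def _member_support_triples(
    m: SyntheticMatrix, entity: TermId
) -> Set[Tuple[str, str, str]]:
    triples: Set[Tuple[str, str, str]] = set()
    for taxon in m.taxa:
        for s in m.cell(taxon, entity).supports:
            triples.add((s.matrix_id, s.char_id, s.state_id))
    return triples


def _directly_annotated_members(
    m: SyntheticMatrix, members: Sequence[TermId]
) -> Set[TermId]:
    """Cluster members that some supporting phenotype names as its target."""
    member_set = set(members)
    hit: Set[TermId] = set()
    for entity in members:
        for taxon in m.taxa:
            for s in m.cell(taxon, entity).supports:
                p = s.phenotype
                target = (
                    p.entity if p.polarity is Polarity.PRESENCE_TYPE else p.negated_entity
                )
                if target in member_set:
                    hit.add(target)
    return hit


def classify_cluster(
    c: IsoCluster,
    anatomy: Ontology,
    m: SyntheticMatrix,
    sources: Sequence[SourceMatrix] = (),
    presence_only: bool = False,
) -> ClusterCause:
    """Assign the ontological cause of one cluster (see module docstring).

    ``presence_only`` selects the weaker presence-supporters-only
    equivalence test in step 1.
    """
    members = c.members
    # (1) inferred equivalence of presence/absence information
    first = members[0]
    if all(
        presence_class_equivalent(anatomy, first, other, presence_only=presence_only)
        for other in members[1:]
    ):
        return ClusterCause.PRESENCE_EQUIVALENCE
    # (2) shared multi-entity states: identical support triples across
    # members, with at least one state directly annotating >= 2 members
    triple_sets = [_member_support_triples(m, e) for e in members]
    if triple_sets[0] and all(t == triple_sets[0] for t in triple_sets[1:]):
        if len(_directly_annotated_members(m, members)) >= 2:
            return ClusterCause.CO_ASSERTION
    # (3) containment chain with supports anchored on one member
    closures = {e: downward_closure(anatomy, e, CLOSURE_RELATIONS) for e in members}
    chain = all(
        (x in closures[y]) or (y in closures[x])
        for i, x in enumerate(members)
        for y in members[i + 1 :]
    )
    if chain and len(_directly_annotated_members(m, members)) <= 1:
        return ClusterCause.PART_CONTAINMENT
    return ClusterCause.INFERENCE_CHAIN


def classify_clusters(
    clusters: Sequence[IsoCluster],
    anatomy: Ontology,
    m: SyntheticMatrix,
    sources: Sequence[SourceMatrix] = (),
    presence_only: bool = False,
) -> List[IsoCluster]:
    """Return clusters with their ``cause`` field filled in."""
    from dataclasses import replace

    return [
        replace(
            c,
            cause=classify_cluster(
                c, anatomy, m, sources, presence_only=presence_only
            ),
        )
        for c in clusters
    ]


def cluster_report(
    clusters: Sequence[IsoCluster], m: SyntheticMatrix
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Per-cluster table plus a summary.

    The table has one row per cluster: members, size, cause, inferred-only
    flag, and the number of populated cells the cluster's columns cover.
    The summary counts clusters by cause and totals the covered cells.
    """
    rows = []
    total_cells = 0
    for c in clusters:
        n_cells = sum(
            1
            for entity in c.members
            for taxon in m.taxa
            if m.cell(taxon, entity).value is not CellValue.MISSING
        )
        total_cells += n_cells
        rows.append(
            {
                "members": "|".join(c.members),
                "size": len(c.members),
                "cause": c.cause.value if c.cause else "",
                "inferred_only": c.inferred_only,
                "n_populated_cells": n_cells,
            }
        )
    table = pd.DataFrame(
        rows, columns=["members", "size", "cause", "inferred_only", "n_populated_cells"]
    )
    summary: Dict[str, int] = {f"clusters_{cause.value}": 0 for cause in ClusterCause}
    for c in clusters:
        if c.cause:
            summary[f"clusters_{c.cause.value}"] += 1
    summary["n_clusters"] = len(clusters)
    summary["n_cells_in_clusters"] = total_cells
    return table, summary
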