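"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's BFS/product-construction
code paths: reachability is computed with dense boolean adjacency matrices
closed by repeated squaring (numpy), synthesis by naive enumeration of
every (state, entity) pair, and clustering by all-pairs column comparison.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from phenosynth.eq_model import Polarity, SourceMatrix
from phenosynth.expression import ClassExpression, NamedClass, SomeValuesFrom
from phenosynth.ontology import CLOSURE_RELATIONS, Ontology, Relation, TermId
from phenosynth.synthesis import SyntheticMatrix


def _index(o: Ontology) -> Tuple[List[TermId], Dict[TermId, int]]:
    terms = sorted(o.terms)
    return terms, {t: i for i, t in enumerate(terms)}


def adjacency(o: Ontology, relations) -> np.ndarray:
    """Boolean matrix A[i, j] = True iff edge (term_i, rel, term_j)."""
    terms, idx = _index(o)
    rels = set(relations)
    a = np.zeros((len(terms), len(terms)), dtype=bool)
    for s, rel, t in o.edges:
        if rel in rels:
            a[idx[s], idx[t]] = True
    return a


def reflexive_transitive_closure(a: np.ndarray) -> np.ndarray:
    """Closure by repeated boolean squaring (paths of any length)."""
    r = a | np.eye(a.shape[0], dtype=bool)
    while True:
        r2 = r | (r @ r)
        if (r2 == r).all():
            return r
        r = r2


def oracle_upward(o: Ontology, start: TermId, relations) -> Set[TermId]:
    terms, idx = _index(o)
    r = reflexive_transitive_closure(adjacency(o, relations))
    return {terms[j] for j in np.nonzero(r[idx[start]])[0]}


def oracle_downward(o: Ontology, start: TermId, relations) -> Set[TermId]:
    terms, idx = _index(o)
    r = reflexive_transitive_closure(adjacency(o, relations))
    return {terms[i] for i in np.nonzero(r[:, idx[start]])[0]}


def oracle_all_closures(
    o: Ontology, relations
) -> Tuple[List[TermId], np.ndarray]:
    """Sorted terms plus the full reachability matrix over ``relations``."""
    terms, _ = _index(o)
    return terms, reflexive_transitive_closure(adjacency(o, relations))


def oracle_presence_supporters(o: Ontology, entity: TermId) -> Set[TermId]:
    return oracle_downward(o, entity, CLOSURE_RELATIONS)


def oracle_absence_supporters(o: Ontology, entity: TermId) -> Set[TermId]:
    return oracle_upward(o, entity, CLOSURE_RELATIONS)


# ----------------------------------------------------------------------
# expression evaluation oracle


def oracle_evaluate(o: Ontology, e: ClassExpression) -> Set[TermId]:
    """Matrix-algebra evaluator: is_a* rel (is_a|rel)* chains into the filler."""
    terms, idx = _index(o)
    out: Set[TermId] = set()
    for atom in e.atoms:
        if isinstance(atom, NamedClass):
            ref = atom.ref
            if atom.is_label:
                hits = [t for t, lab in o.terms.items() if lab == ref]
                assert len(hits) == 1, f"label {ref!r} not uniquely resolvable"
                ref = hits[0]
            out |= oracle_downward(o, ref, {Relation.IS_A})
        else:
            assert isinstance(atom, SomeValuesFrom)
            filler = oracle_evaluate(o, atom.filler)
            fvec = np.zeros(len(terms), dtype=bool)
            for t in filler:
                fvec[idx[t]] = True
            t_isa = reflexive_transitive_closure(adjacency(o, {Relation.IS_A}))
            m_rel = adjacency(o, {atom.relation})
            t_both = reflexive_transitive_closure(
                adjacency(o, {Relation.IS_A, atom.relation})
            )
            # chains shaped  is_a* . rel . (is_a|rel)*  (>= 1 rel edge)
            reach = t_isa @ m_rel @ t_both
            hits = reach @ fvec
            out |= {terms[i] for i in np.nonzero(hits)[0]}
    return out


# ----------------------------------------------------------------------
# synthesis oracle


def oracle_synthesize_values(
    anatomy: Ontology,
    sources: Sequence[SourceMatrix],
    entities: Sequence[TermId],
    taxa: Sequence[TermId],
) -> Dict[Tuple[TermId, TermId], str]:
    """Naive cell values: loop every (source, cell, state, phenotype, entity).

    Returns only populated cells, each mapped to PRESENT/ABSENT/BOTH.
    """
    terms, r = oracle_all_closures(anatomy, CLOSURE_RELATIONS)
    idx = {t: i for i, t in enumerate(terms)}
    taxa_set = set(taxa)
    votes: Dict[Tuple[TermId, TermId], Set[str]] = {}
    for m in sources:
        chars = {c.char_id: c for c in m.characters}
        for (taxon, char_id), state_ids in m.cells.items():
            if taxon not in taxa_set:
                continue
            for sid in state_ids:
                state = chars[char_id].state(sid)
                for p in state.phenotypes:
                    for entity in entities:
                        if p.polarity is Polarity.PRESENCE_TYPE:
                            if p.entity in idx and r[idx[p.entity], idx[entity]]:
                                votes.setdefault((taxon, entity), set()).add("present")
                        else:
                            neg = p.negated_entity
                            if neg in idx and r[idx[entity], idx[neg]]:
                                votes.setdefault((taxon, entity), set()).add("absent")
    out: Dict[Tuple[TermId, TermId], str] = {}
    for key, vals in votes.items():
        out[key] = "BOTH" if len(vals) == 2 else vals.pop().upper()
    return out


# ----------------------------------------------------------------------
# cluster oracle


def oracle_clusters(m: SyntheticMatrix) -> List[Tuple[TermId, ...]]:
    """All-pairs O(n^2) column comparison; sorted member tuples, sorted."""
    cols = {e: m.column(e) for e in m.characters}
    chars = list(m.characters)
    assigned: Set[TermId] = set()
    clusters: List[Tuple[TermId, ...]] = []
    for i, x in enumerate(chars):
        if x in assigned:
            continue
        group = [x]
        for y in chars[i + 1 :]:
            if y not in assigned and cols[x] == cols[y]:
                group.append(y)
        if len(group) >= 2:
            clusters.append(tuple(sorted(group)))
            assigned.update(group)
    clusters.sort()
    return clusters
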