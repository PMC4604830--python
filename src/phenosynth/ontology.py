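"""Term graphs (anatomy, taxonomy, quality) and reachability closures.

An :class:`Ontology` is a typed directed multigraph: terms (CURIE-style
identifiers with labels) connected by a closed set of relationship types.
An edge ``(s, part_of, o)`` reads "s is part of o"; following edges in the
subject-to-object direction therefore moves *upward*, toward wholes,
superclasses, and developmental precursors.  All presence/absence reasoning
in this package reduces to reflexive–transitive closures over subsets of
these relations.

Acyclicity is enforced per relation (``is_a``, ``part_of``,
``develops_from`` must each be acyclic); cycles that arise only when
relations are mixed are tolerated with a warning, because closure
computation is a visited-set BFS and terminates regardless.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

TermId = str
Edge = Tuple[TermId, "Relation", TermId]


class Relation(str, Enum):
    """The closed set of relationship types that participate in reasoning."""

    IS_A = "is_a"
    PART_OF = "part_of"
    DEVELOPS_FROM = "develops_from"
    CONNECTED_TO = "connected_to"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Relations over which presence/absence propagates (Fig.-3-style chains).
#: ``connected_to`` is loaded and queryable but never used in closures; it
#: only participates in class-expression evaluation.
CLOSURE_RELATIONS: FrozenSet[Relation] = frozenset(
    {Relation.IS_A, Relation.PART_OF, Relation.DEVELOPS_FROM}
)

#: Relations that must individually form acyclic subgraphs.
ACYCLIC_RELATIONS: FrozenSet[Relation] = CLOSURE_RELATIONS


class OntologyError(Exception):
    """Base class for ontology loading/validation problems."""


class FormatError(OntologyError):
    """The file is not parsable under the restricted OBO dialect."""


class ValidationError(OntologyError):
    """The parsed graph violates an ontology invariant (e.g. a cycle)."""


class LookupError_(OntologyError):
    """A term id or label could not be resolved."""


@dataclass
class Ontology:
    """A validated term graph.

    Parameters
    ----------
    namespace:
        One of ``"anatomy"``, ``"taxonomy"``, ``"quality"``.  Taxonomy
        ontologies may only contain ``is_a`` edges.
    terms:
        Mapping of term id to human-readable label.
    edges:
        Deduplicated set of ``(subject, relation, object)`` triples; every
        endpoint must be a declared term.
    ranks:
        Optional taxonomic rank per term (read from ``property_value:
        has_rank`` lines), used only by reporting.
    """

    namespace: str
    terms: Dict[TermId, str]
    edges: Set[Edge] = field(default_factory=set)
    ranks: Dict[TermId, str] = field(default_factory=dict)

    # adjacency caches, built lazily
    _out: Optional[Dict[TermId, List[Tuple[Relation, TermId]]]] = field(
        default=None, repr=False, compare=False
    )
    _in: Optional[Dict[TermId, List[Tuple[Relation, TermId]]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise :class:`ValidationError`."""
        if self.namespace not in ("anatomy", "taxonomy", "quality"):
            raise ValidationError(f"unknown namespace {self.namespace!r}")
        for s, rel, o in self.edges:
            if s not in self.terms or o not in self.terms:
                raise ValidationError(
                    f"edge ({s}, {rel.value}, {o}) references undeclared term"
                )
            if self.namespace == "taxonomy" and rel is not Relation.IS_A:
                raise ValidationError(
                    f"taxonomy ontology may only contain is_a edges, found {rel.value}"
                )
        for rel in sorted(ACYCLIC_RELATIONS, key=lambda r: r.value):
            g = nx.DiGraph()
            g.add_nodes_from(self.terms)
            g.add_edges_from((s, o) for s, r, o in self.edges if r is rel)
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                continue
            path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise ValidationError(f"cycle in {rel.value} subgraph: {path}")
        # mixed-relation cycles are benign but worth surfacing once
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (s, o) for s, r, o in self.edges if r in CLOSURE_RELATIONS
        )
        if not nx.is_directed_acyclic_graph(g):
            logger.warning(
                "ontology %r contains mixed-relation cycles; closures still "
                "terminate (visited-set BFS)",
                self.namespace,
            )
        self._out = None
        self._in = None

    # ------------------------------------------------------------------
    def _adjacency(self, reverse: bool) -> Dict[TermId, List[Tuple[Relation, TermId]]]:
        cache = self._in if reverse else self._out
        if cache is None:
            cache = {t: [] for t in self.terms}
            for s, rel, o in self.edges:
                if reverse:
                    cache[o].append((rel, s))
                else:
                    cache[s].append((rel, o))
            for lst in cache.values():
                lst.sort(key=lambda e: (e[1], e[0].value))
            if reverse:
                self._in = cache
            else:
                self._out = cache
        return cache

    def out_edges(self, term: TermId) -> List[Tuple[Relation, TermId]]:
        """Edges with ``term`` as subject, as ``(relation, object)`` pairs."""
        self._require(term)
        return list(self._adjacency(reverse=False)[term])

    def in_edges(self, term: TermId) -> List[Tuple[Relation, TermId]]:
        """Edges with ``term`` as object, as ``(relation, subject)`` pairs."""
        self._require(term)
        return list(self._adjacency(reverse=True)[term])

    def _require(self, term: TermId) -> None:
        if term not in self.terms:
            raise LookupError_(f"unknown term {term!r} in {self.namespace} ontology")

    def sorted_terms(self) -> List[TermId]:
        return sorted(self.terms)

    def label(self, term: TermId) -> str:
        self._require(term)
        return self.terms[term]


# ----------------------------------------------------------------------
# closures


def _closure(
    o: Ontology,
    start: TermId,
    relations: Iterable[Relation],
    reverse: bool,
) -> Set[TermId]:
    rels = frozenset(relations)
    if not rels:
        raise ValueError("relations must be non-empty")
    o._require(start)
    adj = o._adjacency(reverse=reverse)
    seen: Set[TermId] = {start}
    queue: deque = deque([start])
    while queue:
        cur = queue.popleft()
        for rel, nxt in adj[cur]:
            if rel in rels and nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return seen


def upward_closure(
    o: Ontology, start: TermId, relations: Iterable[Relation]
) -> Set[TermId]:
    """Reflexive–transitive closure following edges subject→object.

    Moves toward wholes, superclasses and developmental precursors: for the
    fin-to-limb toy graph, the upward closure of *humerus* over all three
    closure relations is {humerus, forelimb skeleton, forelimb, forelimb
    bud}.  Mixed-relation interleavings are permitted.
    """
    return _closure(o, start, relations, reverse=False)


def downward_closure(
    o: Ontology, start: TermId, relations: Iterable[Relation]
) -> Set[TermId]:
    """Reflexive–transitive closure following edges object→subject.

    The adjoint of :func:`upward_closure`: ``y in downward_closure(o, x, R)``
    iff ``x in upward_closure(o, y, R)``.
    """
    return _closure(o, start, relations, reverse=True)


def closure_path(
    o: Ontology,
    start: TermId,
    goal: TermId,
    relations: Iterable[Relation],
    reverse: bool = False,
) -> List[Edge]:
    """A shortest witness path of ontology edges from ``start`` to ``goal``.

    With ``reverse=False`` the path runs upward (each step is an ontology
    edge ``(subject, rel, object)`` traversed subject→object); with
    ``reverse=True`` it runs downward.  Returns ``[]`` for the reflexive
    case; raises :class:`LookupError_` if ``goal`` is unreachable.
    """
    rels = frozenset(relations)
    o._require(start)
    o._require(goal)
    if start == goal:
        return []
    adj = o._adjacency(reverse=reverse)
    parent: Dict[TermId, Tuple[TermId, Relation]] = {}
    queue: deque = deque([start])
    seen = {start}
    while queue:
        cur = queue.popleft()
        for rel, nxt in adj[cur]:
            if rel in rels and nxt not in seen:
                seen.add(nxt)
                parent[nxt] = (cur, rel)
                if nxt == goal:
                    queue.clear()
                    break
                queue.append(nxt)
    if goal not in parent:
        raise LookupError_(
            f"no {'downward' if reverse else 'upward'} path {start} -> {goal}"
        )
    path: List[Edge] = []
    cur = goal
    while cur != start:
        prev, rel = parent[cur]
        if reverse:
            path.append((cur, rel, prev))  # ontology triple: subject is below
        else:
            path.append((prev, rel, cur))
        cur = prev
    path.reverse()
    return path


# ----------------------------------------------------------------------
# restricted OBO dialect I/O

_RELATION_VALUES = {r.value for r in Relation}


def load_obo(path: str, namespace: str) -> Ontology:
    """Load an ontology from a restricted OBO 1.4 file.

    Recognised tags: ``[Term]`` stanzas with ``id``, ``name``, ``is_a``,
    ``relationship: part_of|develops_from|connected_to`` and
    ``property_value: has_rank``.  Unknown relationship types are dropped
    with a logged warning; all other tags are ignored.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc

    terms: Dict[TermId, str] = {}
    ranks: Dict[TermId, str] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = data.get("name", node)
        for pv in data.get("property_value", []):
            parts = pv.split()
            if len(parts) >= 2 and parts[0] == "has_rank":
                ranks[node] = parts[1].strip('"')

    edges: Set[Edge] = set()
    for s, o, key in graph.edges(keys=True):
        if key in _RELATION_VALUES:
            edges.add((s, Relation(key), o))
        else:
            logger.warning("ignoring unknown relationship %r (%s -> %s)", key, s, o)
    return Ontology(namespace=namespace, terms=terms, edges=edges, ranks=ranks)


def write_obo(o: Ontology, path: str) -> None:
    """Write the same restricted OBO dialect that :func:`load_obo` reads."""
    lines: List[str] = ["format-version: 1.4", f"ontology: phenosynth/{o.namespace}", ""]
    out: Dict[TermId, List[Edge]] = {t: [] for t in o.terms}
    for e in o.edges:
        out[e[0]].append(e)
    for term in sorted(o.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {o.terms[term]}")
        for s, rel, obj in sorted(out[term], key=lambda e: (e[1].value, e[2])):
            if rel is Relation.IS_A:
                lines.append(f"is_a: {obj} ! {o.terms[obj]}")
            else:
                lines.append(f"relationship: {rel.value} {obj} ! {o.terms[obj]}")
        if term in o.ranks:
            lines.append(f"property_value: has_rank {o.ranks[term]}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
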