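"""OWL-style class expressions that select anatomical entities and taxa.

The grammar is exactly the fragment needed for supermatrix synthesis: named
classes (CURIEs or single-quoted labels) combined by ``or``, and existential
restrictions ``<relation> some (<expr>)``.  A typical input::

    part_of some ('paired limb/fin' or 'girdle skeleton')
        or connected_to some ('paired limb/fin' or 'girdle skeleton')

Evaluation semantics
--------------------
* ``NamedClass(c)`` denotes ``c`` together with everything subsumed by it:
  the downward ``is_a`` closure of ``c``.
* ``SomeValuesFrom(rel, filler)`` denotes every term ``t`` from which some
  chain of ``is_a`` and ``rel`` edges, containing at least one ``rel`` edge,
  reaches the filler set.  The "at least one ``rel`` edge" requirement is
  what makes a humerus ``part_of some forelimb`` while the forelimb itself
  is not.
* ``a or b`` denotes the set union.

Intersection and negation are deliberately rejected: the synthesis inputs
only ever use unions of existential restrictions and named classes.
"""

from __future__ import annotations

import difflib
import re
from collections import deque
from dataclasses import dataclass
from typing import List, Set, Tuple, Union

from .ontology import LookupError_, Ontology, Relation, TermId, downward_closure

__all__ = [
    "Atom",
    "ClassExpression",
    "ExpressionSyntaxError",
    "NamedClass",
    "SomeValuesFrom",
    "evaluate_expression",
    "parse_expression",
]


class ExpressionSyntaxError(ValueError):
    """Raised with a character position when expression text is malformed."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class NamedClass:
    """A class named by CURIE (``is_label=False``) or quoted label."""

    ref: str
    is_label: bool = False


@dataclass(frozen=True)
class SomeValuesFrom:
    """Existential restriction ``relation some (filler)``."""

    relation: Relation
    filler: "ClassExpression"


Atom = Union[NamedClass, SomeValuesFrom]


@dataclass(frozen=True)
class ClassExpression:
    """A union of one or more atoms."""

    atoms: Tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a class expression needs at least one atom")


# ----------------------------------------------------------------------
# parsing

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<quoted>'[^']*')
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<word>[^\s()']+)
    """,
    re.VERBOSE,
)

_RELATION_KEYWORDS = {r.value: r for r in Relation}
# words that terminate a name token stream
_RESERVED = {"or", "some", "and", "not"}


def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    # curly/straight quote normalization before tokenizing
    text = text.replace("‘", "'").replace("’", "'")
    tokens: List[Tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:  # pragma: no cover - regex matches any char
            raise ExpressionSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group(), pos))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> Tuple[str, str, int]:
        return self.tokens[self.i]

    def advance(self) -> Tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, what: str) -> Tuple[str, str, int]:
        tok = self.advance()
        if tok[0] != kind:
            raise ExpressionSyntaxError(f"expected {what}, found {tok[1]!r}", tok[2])
        return tok

    def parse(self) -> ClassExpression:
        expr = self.expr()
        tok = self.peek()
        if tok[0] != "eof":
            raise ExpressionSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return expr

    def expr(self) -> ClassExpression:
        atoms: List[Atom] = list(self.atom())
        while self.peek()[0] == "word" and self.peek()[1] == "or":
            self.advance()
            atoms.extend(self.atom())
        return ClassExpression(tuple(atoms))

    def atom(self) -> Tuple[Atom, ...]:
        kind, value, pos = self.peek()
        if kind == "lparen":
            self.advance()
            inner = self.expr()
            self.expect("rparen", "')'")
            return inner.atoms
        if kind == "quoted":
            self.advance()
            return (NamedClass(value[1:-1], is_label=True),)
        if kind == "word":
            if value in ("and", "not"):
                raise ExpressionSyntaxError(
                    f"{value!r} is not supported; only unions and existential "
                    "restrictions are allowed",
                    pos,
                )
            if value in _RELATION_KEYWORDS:
                self.advance()
                self.expect_word("some")
                self.expect("lparen", "'(' after 'some'")
                filler = self.expr()
                self.expect("rparen", "')'")
                return (SomeValuesFrom(_RELATION_KEYWORDS[value], filler),)
            if value == "some":
                raise ExpressionSyntaxError("'some' without a relation keyword", pos)
            self.advance()
            return (NamedClass(value, is_label=False),)
        raise ExpressionSyntaxError(f"expected a class atom, found {value!r}", pos)

    def expect_word(self, word: str) -> None:
        kind, value, pos = self.advance()
        if kind != "word" or value != word:
            raise ExpressionSyntaxError(f"expected {word!r}, found {value!r}", pos)


def parse_expression(text: str) -> ClassExpression:
    """Parse expression text into a :class:`ClassExpression` parse tree.

    Whitespace-insensitive; straight and curly single quotes are accepted.
    Raises :class:`ExpressionSyntaxError` (with position) on malformed
    input, including the unsupported ``and``/``not`` connectives.
    """
    if not text or not text.strip():
        raise ExpressionSyntaxError("empty expression", 0)
    return _Parser(text).parse()


# ----------------------------------------------------------------------
# evaluation


def resolve_name(o: Ontology, atom: NamedClass) -> TermId:
    """Resolve a named class to exactly one term id.

    CURIEs must be declared terms; labels are matched exactly against term
    names after quote normalization.  Ambiguity is an error, not a guess;
    unresolvable names raise :class:`LookupError_` listing near-miss
    candidates.
    """
    if not atom.is_label:
        if atom.ref in o.terms:
            return atom.ref
        candidates = difflib.get_close_matches(atom.ref, list(o.terms), n=5)
        raise LookupError_(
            f"unknown term id {atom.ref!r}; close matches: {candidates}"
        )
    hits = sorted(t for t, label in o.terms.items() if label == atom.ref)
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        raise LookupError_(f"label {atom.ref!r} is ambiguous: {hits}")
    candidates = difflib.get_close_matches(atom.ref, list(o.terms.values()), n=5)
    raise LookupError_(f"unknown label {atom.ref!r}; close matches: {candidates}")


def _eval_some(o: Ontology, rel: Relation, filler_set: Set[TermId]) -> Set[TermId]:
    """All terms with an is_a/rel chain (>=1 rel edge) into ``filler_set``.

    Product construction over states ``(term, seen_rel_edge)`` explored by
    reverse BFS from the filler set, so each edge is touched at most twice.
    """
    adj_in = o._adjacency(reverse=True)
    result: Set[TermId] = set()
    # state False: reaches filler via is_a only so far (no rel edge yet seen
    # on the path suffix); state True: suffix contains >=1 rel edge.
    seen0: Set[TermId] = set(filler_set)
    seen1: Set[TermId] = set()
    queue: deque = deque((t, False) for t in sorted(filler_set))
    while queue:
        cur, flagged = queue.popleft()
        for r, sub in adj_in[cur]:
            if r is rel:
                if sub not in seen1:
                    seen1.add(sub)
                    queue.append((sub, True))
            elif r is Relation.IS_A and rel is not Relation.IS_A:
                if flagged:
                    if sub not in seen1:
                        seen1.add(sub)
                        queue.append((sub, True))
                else:
                    if sub not in seen0:
                        seen0.add(sub)
                        queue.append((sub, False))
    result = seen1
    return result


def evaluate_atom(o: Ontology, atom: Atom) -> Set[TermId]:
    if isinstance(atom, NamedClass):
        term = resolve_name(o, atom)
        return downward_closure(o, term, {Relation.IS_A})
    filler = evaluate_expression(o, atom.filler)
    return _eval_some(o, atom.relation, filler)


def evaluate_expression(o: Ontology, e: ClassExpression) -> Set[TermId]:
    """Evaluate a class expression to the set of subsumed terms.

    The result is a plain set; callers that serialize sort it
    lexicographically for deterministic output.
    """
    out: Set[TermId] = set()
    for atom in e.atoms:
        out |= evaluate_atom(o, atom)
    return out
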