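"""Presence/absence entailment over anatomy ontologies.

The computational heart of the package.  Given an EQ phenotype and a target
anatomical entity, decide whether the phenotype entails the entity's
presence, its absence, or nothing — with an auditable witness chain of
ontology edges.

The semantics mirror partonomy/developmental reasoning over anatomy
ontologies:

* **Presence propagates upward.**  Any quality inhering in a structure
  implies that structure is present, and presence of a part, subclass, or
  developmental derivative implies presence of the whole, superclass, or
  precursor.  A present humerus implies a present forelimb skeleton,
  forelimb, and forelimb bud.
* **Absence propagates downward.**  Absence of a whole, superclass, or
  precursor implies absence of its parts, subclasses, and derivatives.  An
  absent forelimb bud implies an absent humerus — but an absent humerus
  says nothing about the forelimb.

Both directions use the mixed relation set {is_a, part_of, develops_from};
``connected_to`` never participates.  The two closures are exact duals:
``e0 in presence_supporters(e)`` iff ``e in absence_supporters(e0)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Set, Tuple

from .eq_model import EQPhenotype, Polarity
from .ontology import (
    CLOSURE_RELATIONS,
    Edge,
    Ontology,
    TermId,
    closure_path,
    downward_closure,
    upward_closure,
)

__all__ = [
    "EntailmentVerdict",
    "Verdict",
    "absence_supporters",
    "entails",
    "presence_class_equivalent",
    "presence_supporters",
]


class Verdict(str, Enum):
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    NONE = "NONE"


@dataclass(frozen=True)
class EntailmentVerdict:
    """A verdict plus the ontology-edge path witnessing it.

    The chain is empty for NONE and for the reflexive case (a phenotype on
    the entity itself).  PRESENT chains run upward from the annotated
    entity to the target; ABSENT chains run downward from the negated
    entity to the target.
    """

    value: Verdict
    chain: Tuple[Edge, ...] = ()


def presence_supporters(o: Ontology, entity: TermId) -> Set[TermId]:
    """Entities whose asserted presence entails presence of ``entity``.

    This is the downward closure of ``entity`` over {is_a, part_of,
    develops_from}: presence of a part, subclass, or derivative propagates
    up to ``entity``.  Always contains ``entity`` itself (a present humerus
    is a present humerus), which is what lets direct assertions be found by
    the same query path as inferred ones.
    """
    return downward_closure(o, entity, CLOSURE_RELATIONS)


def absence_supporters(o: Ontology, entity: TermId) -> Set[TermId]:
    """Entities whose asserted absence entails absence of ``entity``.

    The dual of :func:`presence_supporters`: the upward closure of
    ``entity`` — absence of a whole, superclass, or precursor propagates
    down to ``entity``.
    """
    return upward_closure(o, entity, CLOSURE_RELATIONS)


def entails(o: Ontology, p: EQPhenotype, entity: TermId) -> EntailmentVerdict:
    """Decide what phenotype ``p`` says about ``entity``.

    PRESENT iff ``p`` is presence-type and its entity lies in the presence
    supporters of ``entity``; ABSENT iff ``p`` is absence-type and its
    negated entity lies in the absence supporters; otherwise NONE.  The
    returned chain replays the inference edge by edge.
    """
    o._require(entity)
    if p.polarity is Polarity.PRESENCE_TYPE:
        if p.entity in o.terms and p.entity in presence_supporters(o, entity):
            chain = closure_path(
                o, p.entity, entity, CLOSURE_RELATIONS, reverse=False
            )
            return EntailmentVerdict(Verdict.PRESENT, tuple(chain))
        return EntailmentVerdict(Verdict.NONE)
    negated = p.negated_entity
    if negated in o.terms and negated in absence_supporters(o, entity):
        chain = closure_path(o, negated, entity, CLOSURE_RELATIONS, reverse=True)
        return EntailmentVerdict(Verdict.ABSENT, tuple(chain))
    return EntailmentVerdict(Verdict.NONE)


def presence_class_equivalent(
    o: Ontology, x: TermId, y: TermId, presence_only: bool = False
) -> bool:
    """Do ``x`` and ``y`` carry identical presence/absence information?

    With the default both-closure test this holds iff every possible
    annotation entails the same verdict for ``x`` and ``y``; two characters
    on such entities are guaranteed to be isomorphic columns in any
    synthesized matrix.  ``presence_only=True`` compares presence
    supporters alone — the weaker DL-query-style variant, exposed for
    reproducing cluster taxonomies built from implied-presence equivalence
    only.
    """
    if presence_supporters(o, x) != presence_supporters(o, y):
        return False
    if presence_only:
        return True
    return absence_supporters(o, x) == absence_supporters(o, y)
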