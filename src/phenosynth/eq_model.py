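"""Entity–Quality phenotype annotations and published source matrices.

A published study is a taxa × characters matrix whose character states are
free text, each state optionally annotated with Entity–Quality (EQ)
phenotypes.  A phenotype pairs an anatomical entity with a quality term
(e.g. humerus + "L-shaped"); any quality inhering in an entity implies that
entity's presence.  Absence is expressible two ways and both normalize to
the same internal form:

* quality ``PATO:0000462`` ("absent") directly on the entity, or
* the lacks-all-parts pattern: quality ``PATO:0002000`` on an organism-level
  entity with the negated anatomical class in the ``related_entity``
  ("towards") slot.

Studies are interchanged as "study bundle" JSON documents::

    {"matrix_id": ..., "citation": ...,
     "taxa": ["VTO:..."],
     "characters": [{"char_id": ..., "label": ...,
                     "states": [{"state_id": ..., "label": ...,
                                 "phenotypes": [{"entity": ..., "quality": ...,
                                                 "related_entity": ...?}]}]}],
     "cells": [{"taxon": ..., "char_id": ..., "state_ids": [...]}]}

A cell assigning more than one state is a published polymorphism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Tuple

from .ontology import TermId

logger = logging.getLogger(__name__)

#: PATO terms with hard-coded meaning.
PRESENT_QUALITY: TermId = "PATO:0000467"
ABSENT_QUALITY: TermId = "PATO:0000462"
LACKS_ALL_PARTS_QUALITY: TermId = "PATO:0002000"

#: Qualities that make a phenotype absence-type.
ABSENCE_QUALITIES: FrozenSet[TermId] = frozenset(
    {ABSENT_QUALITY, LACKS_ALL_PARTS_QUALITY}
)


class Polarity(str, Enum):
    PRESENCE_TYPE = "presence_type"
    ABSENCE_TYPE = "absence_type"


class BundleError(ValueError):
    """Study bundle violates the schema; message names a JSON pointer."""


@dataclass(frozen=True)
class EQPhenotype:
    """One EQ annotation: entity + quality (+ optional ``towards`` entity)."""

    entity: TermId
    quality: TermId
    related_entity: Optional[TermId] = None

    @property
    def polarity(self) -> Polarity:
        return classify_phenotype(self)

    @property
    def negated_entity(self) -> Optional[TermId]:
        """The anatomical class asserted absent, or None for presence-type."""
        if self.polarity is Polarity.PRESENCE_TYPE:
            return None
        return self.related_entity if self.related_entity else self.entity

    def to_dict(self) -> Dict[str, str]:
        d = {"entity": self.entity, "quality": self.quality}
        if self.related_entity:
            d["related_entity"] = self.related_entity
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, str]) -> "EQPhenotype":
        return cls(
            entity=d["entity"],
            quality=d["quality"],
            related_entity=d.get("related_entity"),
        )


def classify_phenotype(p: EQPhenotype) -> Polarity:
    """Classify a phenotype as presence-type or absence-type.

    Deterministic and total: absence-type iff the quality is the designated
    "absent" or lacks-all-parts quality; every other quality inheres in the
    entity and therefore implies its presence.
    """
    if p.quality in ABSENCE_QUALITIES:
        return Polarity.ABSENCE_TYPE
    return Polarity.PRESENCE_TYPE


@dataclass(frozen=True)
class CharacterState:
    """One published state; ``phenotypes`` may be empty (unannotated)."""

    state_id: str
    label: str
    phenotypes: Tuple[EQPhenotype, ...] = ()


@dataclass(frozen=True)
class PublishedCharacter:
    char_id: str
    label: str
    states: Tuple[CharacterState, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError(f"character {self.char_id!r} has no states")
        ids = [s.state_id for s in self.states]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate state_id in character {self.char_id!r}")

    def state(self, state_id: str) -> CharacterState:
        for s in self.states:
            if s.state_id == state_id:
                return s
        raise KeyError(state_id)


@dataclass
class SourceMatrix:
    """One publication's matrix: taxa × characters with state assignments.

    ``cells`` maps ``(taxon, char_id)`` to the set of assigned state ids;
    a set of size > 1 is a published polymorphism.  Taxa may be missing for
    any character.
    """

    matrix_id: str
    citation: str
    taxa: Tuple[TermId, ...]
    characters: Tuple[PublishedCharacter, ...]
    cells: Dict[Tuple[TermId, str], FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        taxa = set(self.taxa)
        chars = {c.char_id: c for c in self.characters}
        if len(chars) != len(self.characters):
            raise ValueError(f"duplicate char_id in matrix {self.matrix_id!r}")
        for (taxon, char_id), state_ids in self.cells.items():
            if taxon not in taxa:
                raise ValueError(
                    f"matrix {self.matrix_id!r}: cell references unknown taxon {taxon!r}"
                )
            if char_id not in chars:
                raise ValueError(
                    f"matrix {self.matrix_id!r}: cell references unknown character "
                    f"{char_id!r}"
                )
            if not state_ids:
                raise ValueError(
                    f"matrix {self.matrix_id!r}: empty state set for ({taxon}, {char_id})"
                )
            known = {s.state_id for s in chars[char_id].states}
            for sid in state_ids:
                if sid not in known:
                    raise ValueError(
                        f"matrix {self.matrix_id!r}: cell ({taxon}, {char_id}) "
                        f"references unknown state {sid!r}"
                    )

    def character(self, char_id: str) -> PublishedCharacter:
        for c in self.characters:
            if c.char_id == char_id:
                return c
        raise KeyError(char_id)


# ----------------------------------------------------------------------
# bundle I/O


def _require(d: Dict, key: str, pointer: str, typ) -> object:
    if key not in d:
        raise BundleError(f"missing {pointer}/{key}")
    v = d[key]
    if not isinstance(v, typ):
        raise BundleError(f"{pointer}/{key}: expected {typ.__name__}")
    return v


def source_matrix_from_dict(data: Dict) -> SourceMatrix:
    """Build and validate a :class:`SourceMatrix` from bundle JSON data."""
    if not isinstance(data, dict):
        raise BundleError("/: bundle must be a JSON object")
    matrix_id = _require(data, "matrix_id", "", str)
    citation = str(data.get("citation", ""))
    taxa = tuple(_require(data, "taxa", "", list))
    characters: List[PublishedCharacter] = []
    for i, cd in enumerate(_require(data, "characters", "", list)):
        cp = f"/characters/{i}"
        if not isinstance(cd, dict):
            raise BundleError(f"{cp}: expected object")
        states: List[CharacterState] = []
        for j, sd in enumerate(_require(cd, "states", cp, list)):
            sp = f"{cp}/states/{j}"
            if not isinstance(sd, dict):
                raise BundleError(f"{sp}: expected object")
            phenotypes: List[EQPhenotype] = []
            for k, pd in enumerate(sd.get("phenotypes", [])):
                pp = f"{sp}/phenotypes/{k}"
                if not isinstance(pd, dict) or "entity" not in pd or "quality" not in pd:
                    raise BundleError(f"{pp}: needs entity and quality")
                phenotypes.append(EQPhenotype.from_dict(pd))
            if not phenotypes:
                logger.info(
                    "state %s/%s/%s is unannotated; it will carry provenance "
                    "but never entail anything",
                    matrix_id,
                    cd.get("char_id"),
                    sd.get("state_id"),
                )
            states.append(
                CharacterState(
                    state_id=str(_require(sd, "state_id", sp, str)),
                    label=str(sd.get("label", "")),
                    phenotypes=tuple(phenotypes),
                )
            )
        characters.append(
            PublishedCharacter(
                char_id=str(_require(cd, "char_id", cp, str)),
                label=str(cd.get("label", "")),
                states=tuple(states),
            )
        )
    cells: Dict[Tuple[TermId, str], FrozenSet[str]] = {}
    for i, celld in enumerate(_require(data, "cells", "", list)):
        cp = f"/cells/{i}"
        if not isinstance(celld, dict):
            raise BundleError(f"{cp}: expected object")
        taxon = str(_require(celld, "taxon", cp, str))
        char_id = str(_require(celld, "char_id", cp, str))
        state_ids = frozenset(str(s) for s in _require(celld, "state_ids", cp, list))
        key = (taxon, char_id)
        if key in cells:
            raise BundleError(f"{cp}: duplicate cell for ({taxon}, {char_id})")
        cells[key] = state_ids
    try:
        return SourceMatrix(
            matrix_id=matrix_id,
            citation=citation,
            taxa=taxa,
            characters=tuple(characters),
            cells=cells,
        )
    except ValueError as exc:
        raise BundleError(str(exc)) from exc


def source_matrix_to_dict(m: SourceMatrix) -> Dict:
    return {
        "matrix_id": m.matrix_id,
        "citation": m.citation,
        "taxa": list(m.taxa),
        "characters": [
            {
                "char_id": c.char_id,
                "label": c.label,
                "states": [
                    {
                        "state_id": s.state_id,
                        "label": s.label,
                        "phenotypes": [p.to_dict() for p in s.phenotypes],
                    }
                    for s in c.states
                ],
            }
            for c in m.characters
        ],
        "cells": [
            {"taxon": taxon, "char_id": char_id, "state_ids": sorted(state_ids)}
            for (taxon, char_id), state_ids in sorted(m.cells.items())
        ],
    }


def load_study_bundle(path: str) -> SourceMatrix:
    """Load and validate one study-bundle JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BundleError(f"{path}: not valid JSON: {exc}") from exc
    return source_matrix_from_dict(data)


def write_study_bundle(m: SourceMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(source_matrix_to_dict(m), fh, indent=1, sort_keys=True)
        fh.write("\n")
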