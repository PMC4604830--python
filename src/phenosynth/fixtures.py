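"""Synthetic fixtures: random ontologies, taxonomies, and annotated studies.

Everything the synthesis pipeline consumes can be generated here from a
seed, with a ground-truth ledger recording what was planted — so every
other module is testable end-to-end with no external ontology or data
download.

What the generator emulates
---------------------------
* **Anatomy ontology**: a layered random DAG (edges only cross toward
  lower layers, so each relation is acyclic by construction) rooted in a
  single whole-body term, every term connected to the root through
  ``part_of``.  Optional cluster-inducing motifs mirror the structures
  that make real synthesized matrices redundant: a mutual-closure pair
  (two terms carrying identical presence/absence information), a
  three-term containment chain, and a "digits" fan for co-asserted states.
* **Taxonomy**: a three-level tree (clade / genera / species) with ranks.
* **Latent truth**: per taxon, a presence/absence assignment over all
  entities that is closure-consistent by construction — absence seeds are
  drawn first and propagated downward (whole before part), never
  rejection-sampled.
* **Studies**: each source matrix scores a random subset of taxa against
  characters focused on random entities.  Presence is annotated either
  with the designated "present" quality (a direct assertion) or with a
  shape-type quality that entails presence without asserting it — the
  mechanism behind characters that are variable only through inference.
  Absence uses the direct "absent" quality or the lacks-all-parts/towards
  pattern.  Annotations are always consistent with the latent truth.
* **Injected disagreements**: because natural annotations are
  truth-consistent, every BOTH cell in a synthesized matrix traces to an
  explicit injection.  Conflicts of each category and intra-source
  polymorphisms are planted at closure-leaf entities (so a counter-truth
  assertion affects exactly one cell), and the ledger records each site
  with its affected cells.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .eq_model import (
    ABSENT_QUALITY,
    CharacterState,
    EQPhenotype,
    LACKS_ALL_PARTS_QUALITY,
    PRESENT_QUALITY,
    PublishedCharacter,
    SourceMatrix,
    write_study_bundle,
)
from .ontology import (
    CLOSURE_RELATIONS,
    Ontology,
    Relation,
    TermId,
    downward_closure,
    upward_closure,
    write_obo,
)

ROOT_ANATOMY: TermId = "ANAT:0000000"
ROOT_TAXON: TermId = "TAXON:0000000"

#: Qualities used for non-presence/absence annotations (shape, size, length).
SHAPE_QUALITIES: Tuple[TermId, ...] = ("PATO:0000052", "PATO:0000117", "PATO:0000122")
_QUALITY_LABELS = {
    "PATO:0000052": "shape",
    "PATO:0000117": "size",
    "PATO:0000122": "length",
    PRESENT_QUALITY: "present",
    ABSENT_QUALITY: "absent",
    LACKS_ALL_PARTS_QUALITY: "lacks all parts of type",
}

CONFLICT_CATEGORIES = ("asserted_asserted", "asserted_inferred", "inferred_inferred")

#: Number of extra terms appended for cluster motifs:
#: equivalence pair (2) + containment chain (3) + digit fan (3 + holder).
_N_MOTIF_TERMS = 9


def default_entity_expression() -> str:
    """Expression selecting every generated anatomy term except the root."""
    return f"part_of some ({ROOT_ANATOMY})"


def default_taxon_expression() -> str:
    return ROOT_TAXON


@dataclass
class FixtureConfig:
    """Knobs of the generator; same seed implies byte-identical outputs.

    Defaults describe the standard study conditions used throughout the
    test-suite and acceptance measurements: a ~60-entity anatomy, 50
    species scored by 6 sources, with two injected disagreements of each
    category.
    """

    seed: int
    n_anatomy_terms: int = 60
    n_taxa: int = 50
    n_sources: int = 6
    density_is_a: float = 0.04
    density_part_of: float = 0.03
    density_develops_from: float = 0.015
    density_connected_to: float = 0.02
    annotation_rate: float = 0.35
    absence_rate: float = 0.10
    shape_quality_rate: float = 0.40
    part_annotation_rate: float = 0.30
    lacks_pattern_rate: float = 0.50
    higher_rank_row_rate: float = 0.05
    n_chars_per_source: int = 8
    injected_conflicts: Dict[str, int] = field(
        default_factory=lambda: {c: 2 for c in CONFLICT_CATEGORIES}
    )
    intra_source_polymorphism_count: int = 2
    include_cluster_motifs: bool = True

    def __post_init__(self) -> None:
        for name in (
            "density_is_a",
            "density_part_of",
            "density_develops_from",
            "density_connected_to",
            "annotation_rate",
            "absence_rate",
            "shape_quality_rate",
            "part_annotation_rate",
            "lacks_pattern_rate",
            "higher_rank_row_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_anatomy_terms < 3 or self.n_taxa < 1 or self.n_sources < 1:
            raise ValueError("fixture sizes too small")
        for cat, count in self.injected_conflicts.items():
            if cat not in CONFLICT_CATEGORIES or count < 0:
                raise ValueError(f"bad injected_conflicts entry {cat}={count}")
        if self.intra_source_polymorphism_count < 0:
            raise ValueError("intra_source_polymorphism_count must be >= 0")


# ----------------------------------------------------------------------
# ledger


@dataclass(frozen=True)
class Injection:
    category: str  # conflict category or "intra_source_polymorphism"
    taxon: TermId
    entity: TermId
    matrix_ids: Tuple[str, ...]
    affected: Tuple[Tuple[TermId, TermId], ...]


@dataclass(frozen=True)
class MotifRecord:
    kind: str  # presence_equivalence | part_containment | co_assertion
    members: Tuple[TermId, ...]
    matrix_id: str
    char_id: str
    taxa: Tuple[TermId, ...]


@dataclass
class GroundTruthLedger:
    """Everything the generator planted, for parameter-recovery tests."""

    absent: Dict[TermId, FrozenSet[TermId]]  # taxon -> absent entities
    injections: List[Injection] = field(default_factory=list)
    motifs: List[MotifRecord] = field(default_factory=list)
    n_annotation_trials: int = 0
    n_annotated: int = 0

    def truth(self, taxon: TermId, entity: TermId) -> str:
        return "absent" if entity in self.absent[taxon] else "present"

    def affected_cells(self) -> Set[Tuple[TermId, TermId]]:
        out: Set[Tuple[TermId, TermId]] = set()
        for inj in self.injections:
            out.update(inj.affected)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "absent": {t: sorted(es) for t, es in sorted(self.absent.items())},
                "injections": [
                    {
                        "category": i.category,
                        "taxon": i.taxon,
                        "entity": i.entity,
                        "matrix_ids": list(i.matrix_ids),
                        "affected": [list(c) for c in i.affected],
                    }
                    for i in self.injections
                ],
                "motifs": [
                    {
                        "kind": mo.kind,
                        "members": list(mo.members),
                        "matrix_id": mo.matrix_id,
                        "char_id": mo.char_id,
                        "taxa": list(mo.taxa),
                    }
                    for mo in self.motifs
                ],
                "n_annotation_trials": self.n_annotation_trials,
                "n_annotated": self.n_annotated,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLedger":
        d = json.loads(text)
        return cls(
            absent={t: frozenset(es) for t, es in d["absent"].items()},
            injections=[
                Injection(
                    category=i["category"],
                    taxon=i["taxon"],
                    entity=i["entity"],
                    matrix_ids=tuple(i["matrix_ids"]),
                    affected=tuple((a, b) for a, b in i["affected"]),
                )
                for i in d["injections"]
            ],
            motifs=[
                MotifRecord(
                    kind=mo["kind"],
                    members=tuple(mo["members"]),
                    matrix_id=mo["matrix_id"],
                    char_id=mo["char_id"],
                    taxa=tuple(mo["taxa"]),
                )
                for mo in d["motifs"]
            ],
            n_annotation_trials=d["n_annotation_trials"],
            n_annotated=d["n_annotated"],
        )


# ----------------------------------------------------------------------
# ontology generation


def _anat_id(i: int) -> TermId:
    return f"ANAT:{i:07d}"


def _motif_terms(cfg: FixtureConfig) -> Dict[str, Tuple[TermId, ...]]:
    """Deterministic ids of the motif terms appended after the base terms."""
    n = cfg.n_anatomy_terms
    ids = [_anat_id(n + k) for k in range(_N_MOTIF_TERMS)]
    return {
        "presence_equivalence": (ids[0], ids[1]),  # x, y
        "part_containment": (ids[2], ids[3], ids[4]),  # a part_of b part_of c
        "co_assertion": (ids[5], ids[6], ids[7]),  # digits
        "co_assertion_holder": (ids[8],),
    }


def generate_ontology(cfg: FixtureConfig) -> Ontology:
    """Layered random anatomy DAG, acyclic per relation by construction.

    Every non-root term has a ``part_of`` path to the root, so the
    standard entity expression ``part_of some (root)`` selects all of
    them.  With ``include_cluster_motifs`` the last nine term ids form the
    three cluster motifs (see :func:`_motif_terms`); the equivalence pair
    is a two-relation mixed 2-cycle, which per-relation acyclicity
    permits.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    n = cfg.n_anatomy_terms
    terms: Dict[TermId, str] = {ROOT_ANATOMY: "whole organism body"}
    layer: Dict[int, int] = {0: 0}
    n_layers = max(2, int(round(n ** 0.5)))
    for i in range(1, n):
        terms[_anat_id(i)] = f"anatomical structure {i}"
        layer[i] = 1 + (i - 1) * (n_layers - 1) // max(1, n - 1)

    by_layer: Dict[int, List[int]] = {}
    for i, lay in layer.items():
        by_layer.setdefault(lay, []).append(i)

    edges: Set[Tuple[TermId, Relation, TermId]] = set()
    # connectivity: each non-root term part_of one term in a strictly lower layer
    for i in range(1, n):
        candidates = [j for j in range(n) if layer[j] < layer[i]]
        parent = candidates[int(rng.integers(len(candidates)))]
        edges.add((_anat_id(i), Relation.PART_OF, _anat_id(parent)))
    # extra random edges, always toward lower layers (acyclicity per relation)
    densities = {
        Relation.IS_A: cfg.density_is_a,
        Relation.PART_OF: cfg.density_part_of,
        Relation.DEVELOPS_FROM: cfg.density_develops_from,
        Relation.CONNECTED_TO: cfg.density_connected_to,
    }
    for i in range(1, n):
        for j in range(n):
            if layer[j] >= layer[i]:
                continue
            for rel in (
                Relation.IS_A,
                Relation.PART_OF,
                Relation.DEVELOPS_FROM,
                Relation.CONNECTED_TO,
            ):
                if rng.random() < densities[rel]:
                    edges.add((_anat_id(i), rel, _anat_id(j)))

    if cfg.include_cluster_motifs:
        motifs = _motif_terms(cfg)
        layer1 = [j for j in range(1, n) if layer[j] == 1] or [0]
        anchor = lambda: _anat_id(layer1[int(rng.integers(len(layer1)))])  # noqa: E731
        x, y = motifs["presence_equivalence"]
        terms[x] = "pedal digit motif"
        terms[y] = "pedal digit skeleton motif"
        edges.add((x, Relation.IS_A, y))
        edges.add((y, Relation.PART_OF, x))  # mixed 2-cycle: equal closures
        edges.add((y, Relation.PART_OF, anchor()))
        a, b, c = motifs["part_containment"]
        terms[a] = "chain part motif"
        terms[b] = "chain middle motif"
        terms[c] = "chain whole motif"
        edges.add((a, Relation.PART_OF, b))
        edges.add((b, Relation.PART_OF, c))
        edges.add((c, Relation.PART_OF, anchor()))
        d1, d2, d3 = motifs["co_assertion"]
        (q,) = motifs["co_assertion_holder"]
        terms[q] = "digit row motif"
        for k, d in enumerate((d1, d2, d3), start=1):
            terms[d] = f"motif digit {k}"
            edges.add((d, Relation.PART_OF, q))
        edges.add((q, Relation.PART_OF, anchor()))

    return Ontology(namespace="anatomy", terms=terms, edges=edges)


def generate_taxonomy(cfg: FixtureConfig) -> Ontology:
    """Three-level taxonomy tree (clade / genus / species) with ranks."""
    n_genera = max(1, cfg.n_taxa // 5)
    terms: Dict[TermId, str] = {ROOT_TAXON: "fixture clade"}
    ranks: Dict[TermId, str] = {ROOT_TAXON: "class"}
    edges: Set[Tuple[TermId, Relation, TermId]] = set()
    for g in range(n_genera):
        gid = f"TAXON:{1000 + g:07d}"
        terms[gid] = f"Genus{g}"
        ranks[gid] = "genus"
        edges.add((gid, Relation.IS_A, ROOT_TAXON))
    for i in range(cfg.n_taxa):
        sid = f"TAXON:{2000 + i:07d}"
        gid = f"TAXON:{1000 + (i % n_genera):07d}"
        terms[sid] = f"Genus{i % n_genera} species{i}"
        ranks[sid] = "species"
        edges.add((sid, Relation.IS_A, gid))
    return Ontology(namespace="taxonomy", terms=terms, edges=edges, ranks=ranks)


# ----------------------------------------------------------------------
# knowledge-base generation


class _SourceBuilder:
    def __init__(self, matrix_id: str, citation: str) -> None:
        self.matrix_id = matrix_id
        self.citation = citation
        self.taxa: List[TermId] = []
        self.characters: List[Dict] = []  # {char_id, label, states: [CharacterState]}
        self.cells: Dict[Tuple[TermId, str], Set[str]] = {}

    def ensure_taxon(self, taxon: TermId) -> None:
        if taxon not in self.taxa:
            self.taxa.append(taxon)

    def new_char(self, label: str) -> Dict:
        char = {"char_id": f"ch{len(self.characters) + 1}", "label": label, "states": []}
        self.characters.append(char)
        return char

    @staticmethod
    def add_state(char: Dict, label: str, phenotypes: Sequence[EQPhenotype]) -> str:
        sid = f"s{len(char['states']) + 1}"
        char["states"].append(
            CharacterState(state_id=sid, label=label, phenotypes=tuple(phenotypes))
        )
        return sid

    def assign(self, taxon: TermId, char: Dict, state_id: str) -> None:
        self.ensure_taxon(taxon)
        self.cells.setdefault((taxon, char["char_id"]), set()).add(state_id)

    def build(self) -> SourceMatrix:
        # a published character always has states; characters for which no
        # taxon happened to be annotated are simply never published
        return SourceMatrix(
            matrix_id=self.matrix_id,
            citation=self.citation,
            taxa=tuple(sorted(self.taxa)),
            characters=tuple(
                PublishedCharacter(
                    char_id=c["char_id"], label=c["label"], states=tuple(c["states"])
                )
                for c in self.characters
                if c["states"]
            ),
            cells={k: frozenset(v) for k, v in self.cells.items()},
        )


def generate_kb(
    cfg: FixtureConfig, anatomy: Ontology, taxonomy: Ontology
) -> Tuple[List[SourceMatrix], GroundTruthLedger]:
    """Generate source matrices plus the ground-truth ledger.

    Natural annotations are consistent with the latent truth, so every
    BOTH cell in a synthesis over the result traces to an injection.
    Raises ``ValueError`` if an injection request cannot be satisfied
    (e.g. not enough present leaf sites).
    """
    rng = np.random.default_rng([cfg.seed, 33])
    n = cfg.n_anatomy_terms
    base_nonroot = [_anat_id(i) for i in range(1, n)]
    motifs = _motif_terms(cfg) if cfg.include_cluster_motifs else {}
    # keep natural annotations off motif terms so motif columns are driven
    # solely by their dedicated characters (plus uniform ancestor absences)
    motif_term_set: Set[TermId] = {t for ids in motifs.values() for t in ids}

    down: Dict[TermId, Set[TermId]] = {
        t: downward_closure(anatomy, t, CLOSURE_RELATIONS) for t in anatomy.terms
    }
    up: Dict[TermId, Set[TermId]] = {
        t: upward_closure(anatomy, t, CLOSURE_RELATIONS) for t in anatomy.terms
    }

    species = sorted(t for t, r in taxonomy.ranks.items() if r == "species")
    genera = sorted(t for t, r in taxonomy.ranks.items() if r == "genus")

    # latent truth: absence seeds propagated downward; constructive, never
    # rejection-sampled, hence closure-consistent
    absent: Dict[TermId, FrozenSet[TermId]] = {}
    for taxon in species + genera:
        absent_set: Set[TermId] = set()
        for entity in base_nonroot:
            if rng.random() < cfg.absence_rate:
                absent_set |= down[entity]
        absent[taxon] = frozenset(absent_set)

    ledger = GroundTruthLedger(absent=absent)
    direct_asserted: Set[Tuple[TermId, TermId]] = set()

    builders: List[_SourceBuilder] = []
    for m_idx in range(cfg.n_sources):
        sb = _SourceBuilder(
            matrix_id=f"study{m_idx + 1:02d}",
            citation=f"Synthetic Study {m_idx + 1} ({2005 + m_idx})",
        )
        frac = rng.uniform(0.4, 0.8)
        k = max(2, min(len(species), int(round(frac * len(species)))))
        taxa_m = sorted(
            str(t) for t in rng.choice(species, size=k, replace=False)
        )
        for g in genera:
            if rng.random() < cfg.higher_rank_row_rate:
                taxa_m.append(g)
        n_chars = min(cfg.n_chars_per_source, len(base_nonroot))
        focals = sorted(
            str(f) for f in rng.choice(base_nonroot, size=n_chars, replace=False)
        )
        for focal in focals:
            char = sb.new_char(f"{anatomy.label(focal)} character")
            state_registry: Dict[Tuple, str] = {}
            for taxon in taxa_m:
                ledger.n_annotation_trials += 1
                if rng.random() >= cfg.annotation_rate:
                    continue
                ledger.n_annotated += 1
                is_absent = focal in absent[taxon]
                anchor = focal
                if rng.random() < cfg.part_annotation_rate:
                    if is_absent:
                        cands = sorted(
                            e
                            for e in up[focal] - {focal}
                            if e in absent[taxon]
                            and e != ROOT_ANATOMY
                            and e not in motif_term_set
                        )
                    else:
                        cands = sorted(
                            e
                            for e in down[focal] - {focal}
                            if e not in absent[taxon] and e not in motif_term_set
                        )
                    if cands:
                        anchor = cands[int(rng.integers(len(cands)))]
                if is_absent:
                    if rng.random() < cfg.lacks_pattern_rate:
                        ph = EQPhenotype(
                            entity=ROOT_ANATOMY,
                            quality=LACKS_ALL_PARTS_QUALITY,
                            related_entity=anchor,
                        )
                        key = ("lacks", anchor)
                        label = f"{anatomy.label(anchor)} lacking"
                    else:
                        ph = EQPhenotype(entity=anchor, quality=ABSENT_QUALITY)
                        key = ("absent", anchor)
                        label = f"{anatomy.label(anchor)} absent"
                        direct_asserted.add((taxon, anchor))
                else:
                    if rng.random() < cfg.shape_quality_rate:
                        quality = SHAPE_QUALITIES[
                            int(rng.integers(len(SHAPE_QUALITIES)))
                        ]
                    else:
                        quality = PRESENT_QUALITY
                        direct_asserted.add((taxon, anchor))
                    ph = EQPhenotype(entity=anchor, quality=quality)
                    key = (quality, anchor)
                    label = f"{anatomy.label(anchor)} {_QUALITY_LABELS[quality]}"
                sid = state_registry.get(key)
                if sid is None:
                    sid = sb.add_state(char, label, [ph])
                    state_registry[key] = sid
                sb.assign(taxon, char, sid)
        builders.append(sb)

    if cfg.include_cluster_motifs:
        _add_motif_characters(cfg, anatomy, species, absent, builders, ledger, motifs)

    _add_injections(cfg, anatomy, species, absent, builders, ledger,
                    direct_asserted, down, rng)

    return [sb.build() for sb in builders], ledger


def _add_motif_characters(
    cfg: FixtureConfig,
    anatomy: Ontology,
    species: List[TermId],
    absent: Dict[TermId, FrozenSet[TermId]],
    builders: List[_SourceBuilder],
    ledger: GroundTruthLedger,
    motifs: Dict[str, Tuple[TermId, ...]],
) -> None:
    # deterministic, disjoint-ish taxon patterns keep motif columns distinct
    patterns = {
        "presence_equivalence": lambda i: i % 2 == 0,
        "part_containment": lambda i: i % 2 == 1,
        "co_assertion": lambda i: i % 3 == 0,
    }
    for k, kind in enumerate(
        ("presence_equivalence", "part_containment", "co_assertion")
    ):
        members = motifs[kind]
        sb = builders[k % len(builders)]
        required = members if kind == "co_assertion" else members[:1]
        taxa = [
            t
            for i, t in enumerate(species)
            if patterns[kind](i) and all(m not in absent[t] for m in required)
        ]
        if not taxa:
            taxa = [t for t in species if all(m not in absent[t] for m in required)]
        if not taxa:
            continue  # all-absent everywhere: motif not expressible
        if kind == "co_assertion":
            char = sb.new_char("motif digits character")
            sid = sb.add_state(
                char,
                "motif digits 1, 2 and 3 present",
                [EQPhenotype(entity=d, quality=PRESENT_QUALITY) for d in members],
            )
        else:
            target = members[0]
            char = sb.new_char(f"{anatomy.label(target)} character")
            sid = sb.add_state(
                char,
                f"{anatomy.label(target)} shape",
                [EQPhenotype(entity=target, quality=SHAPE_QUALITIES[0])],
            )
        for t in taxa:
            sb.assign(t, char, sid)
        # the digit holder receives identical inferred supports from every
        # digit phenotype, so it is genuinely part of the cluster
        if kind == "co_assertion":
            members = members + motifs["co_assertion_holder"]
        ledger.motifs.append(
            MotifRecord(
                kind=kind,
                members=tuple(sorted(members)),
                matrix_id=sb.matrix_id,
                char_id=char["char_id"],
                taxa=tuple(taxa),
            )
        )


def _add_injections(
    cfg: FixtureConfig,
    anatomy: Ontology,
    species: List[TermId],
    absent: Dict[TermId, FrozenSet[TermId]],
    builders: List[_SourceBuilder],
    ledger: GroundTruthLedger,
    direct_asserted: Set[Tuple[TermId, TermId]],
    down: Dict[TermId, Set[TermId]],
    rng: np.random.Generator,
) -> None:
    wanted = [
        (cat, cfg.injected_conflicts.get(cat, 0)) for cat in CONFLICT_CATEGORIES
    ] + [("intra_source_polymorphism", cfg.intra_source_polymorphism_count)]
    total = sum(c for _cat, c in wanted)
    if total == 0:
        return
    cross_source = any(
        c > 0 for cat, c in wanted if cat != "intra_source_polymorphism"
    )
    if cross_source and len(builders) < 2:
        raise ValueError("cross-source conflict injection needs >= 2 sources")

    leaves = sorted(
        e
        for e in (_anat_id(i) for i in range(1, cfg.n_anatomy_terms))
        if down[e] == {e}
    )
    sites = [(t, e) for e in leaves for t in species if e not in absent[t]]
    order = rng.permutation(len(sites))
    used: Set[Tuple[TermId, TermId]] = set()
    cursor = 0

    def next_site(need_no_direct: bool) -> Tuple[TermId, TermId]:
        nonlocal cursor
        while cursor < len(order):
            t, e = sites[int(order[cursor])]
            cursor += 1
            if (t, e) in used:
                continue
            if need_no_direct and (t, e) in direct_asserted:
                continue
            used.add((t, e))
            return t, e
        raise ValueError(
            "unsatisfiable injection request: not enough present leaf sites"
        )

    idx = 0
    for category, count in wanted:
        for _ in range(count):
            # cross-source categories must not coincide with a natural direct
            # assertion: one in the absence-side source would collapse the
            # cell into intra-source polymorphism by precedence
            taxon, entity = next_site(
                need_no_direct=(category != "intra_source_polymorphism")
            )
            label = anatomy.label(entity)
            if category == "intra_source_polymorphism":
                sb = builders[idx % len(builders)]
                char = sb.new_char(f"{label} polymorphism character")
                sid_p = sb.add_state(
                    char, f"{label} present",
                    [EQPhenotype(entity=entity, quality=PRESENT_QUALITY)],
                )
                sid_a = sb.add_state(
                    char, f"{label} absent",
                    [EQPhenotype(entity=entity, quality=ABSENT_QUALITY)],
                )
                sb.assign(taxon, char, sid_p)
                sb.assign(taxon, char, sid_a)
                matrix_ids = (sb.matrix_id,)
            else:
                sb_p = builders[idx % len(builders)]
                sb_a = builders[(idx + 1) % len(builders)]
                if category == "asserted_asserted":
                    p_ph = EQPhenotype(entity=entity, quality=PRESENT_QUALITY)
                    a_ph = EQPhenotype(entity=entity, quality=ABSENT_QUALITY)
                elif category == "asserted_inferred":
                    p_ph = EQPhenotype(entity=entity, quality=PRESENT_QUALITY)
                    a_ph = EQPhenotype(
                        entity=ROOT_ANATOMY,
                        quality=LACKS_ALL_PARTS_QUALITY,
                        related_entity=entity,
                    )
                else:  # inferred_inferred
                    p_ph = EQPhenotype(entity=entity, quality=SHAPE_QUALITIES[0])
                    a_ph = EQPhenotype(
                        entity=ROOT_ANATOMY,
                        quality=LACKS_ALL_PARTS_QUALITY,
                        related_entity=entity,
                    )
                char_p = sb_p.new_char(f"{label} conflict character")
                sid_p = sb_p.add_state(char_p, f"{label} observation", [p_ph])
                sb_p.assign(taxon, char_p, sid_p)
                char_a = sb_a.new_char(f"{label} conflict character")
                sid_a = sb_a.add_state(char_a, f"{label} negation", [a_ph])
                sb_a.assign(taxon, char_a, sid_a)
                matrix_ids = (sb_p.matrix_id, sb_a.matrix_id)
            ledger.injections.append(
                Injection(
                    category=category,
                    taxon=taxon,
                    entity=entity,
                    matrix_ids=matrix_ids,
                    affected=tuple(sorted((taxon, e) for e in down[entity])),
                )
            )
            idx += 1


# ----------------------------------------------------------------------
# hand-built fin-to-limb toy fixture


def fig3_ontology() -> Ontology:
    """The five-term fin-to-limb toy partonomy used throughout the docs.

    entepicondyle part_of humerus part_of forelimb skeleton part_of
    forelimb develops_from forelimb bud.
    """
    terms = {
        "TOY:entepicondyle": "entepicondyle",
        "TOY:humerus": "humerus",
        "TOY:forelimb_skeleton": "forelimb skeleton",
        "TOY:forelimb": "forelimb",
        "TOY:forelimb_bud": "forelimb bud",
    }
    edges = {
        ("TOY:entepicondyle", Relation.PART_OF, "TOY:humerus"),
        ("TOY:humerus", Relation.PART_OF, "TOY:forelimb_skeleton"),
        ("TOY:forelimb_skeleton", Relation.PART_OF, "TOY:forelimb"),
        ("TOY:forelimb", Relation.DEVELOPS_FROM, "TOY:forelimb_bud"),
    }
    return Ontology(namespace="anatomy", terms=terms, edges=edges)


def fig3_taxonomy() -> Ontology:
    terms = {
        "TOY:clade": "toy clade",
        "TOY:taxonA": "Toyus alpha",
        "TOY:taxonB": "Toyus beta",
        "TOY:taxonC": "Toyus gamma",
    }
    edges = {
        ("TOY:taxonA", Relation.IS_A, "TOY:clade"),
        ("TOY:taxonB", Relation.IS_A, "TOY:clade"),
        ("TOY:taxonC", Relation.IS_A, "TOY:clade"),
    }
    ranks = {
        "TOY:clade": "class",
        "TOY:taxonA": "species",
        "TOY:taxonB": "species",
        "TOY:taxonC": "species",
    }
    return Ontology(namespace="taxonomy", terms=terms, edges=edges, ranks=ranks)


def fig3_sources() -> List[SourceMatrix]:
    """Two tiny studies over the toy clade.

    Study 1 describes humerus shape in taxon A (presence only by
    inference) and asserts the entepicondyle present in taxon B; study 2
    asserts the forelimb bud absent in taxon C, which cascades absence
    down the whole partonomy.
    """
    s1 = _SourceBuilder("toy01", "Toy Study 1 (2001)")
    ch1 = s1.new_char("humerus shape")
    sid = s1.add_state(
        ch1, "humerus L-shaped",
        [EQPhenotype(entity="TOY:humerus", quality=SHAPE_QUALITIES[0])],
    )
    s1.assign("TOY:taxonA", ch1, sid)
    ch2 = s1.new_char("entepicondyle")
    sid = s1.add_state(
        ch2, "entepicondyle present",
        [EQPhenotype(entity="TOY:entepicondyle", quality=PRESENT_QUALITY)],
    )
    s1.assign("TOY:taxonB", ch2, sid)

    s2 = _SourceBuilder("toy02", "Toy Study 2 (2003)")
    ch3 = s2.new_char("forelimb bud")
    sid = s2.add_state(
        ch3, "forelimb bud absent",
        [EQPhenotype(entity="TOY:forelimb_bud", quality=ABSENT_QUALITY)],
    )
    s2.assign("TOY:taxonC", ch3, sid)
    return [s1.build(), s2.build()]


# ----------------------------------------------------------------------
# presets & file output

PRESETS = ("fig3", "small", "medium")


def preset_config(preset: str, seed: int) -> FixtureConfig:
    if preset == "small":
        return FixtureConfig(
            seed=seed, n_anatomy_terms=20, n_taxa=12, n_sources=3,
            n_chars_per_source=5,
            injected_conflicts={c: 1 for c in CONFLICT_CATEGORIES},
            intra_source_polymorphism_count=1,
        )
    if preset == "medium":
        return FixtureConfig(seed=seed)
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def write_fixture_dir(outdir: str, preset: str = "medium", seed: int = 1) -> None:
    """Write ontology/taxonomy OBO files, study bundles, and the ledger.

    The ``fig3`` preset writes the deterministic hand-built toy fixture;
    the others run the random generator.  Same seed, same bytes.
    """
    os.makedirs(os.path.join(outdir, "bundles"), exist_ok=True)
    if preset == "fig3":
        anatomy, taxonomy = fig3_ontology(), fig3_taxonomy()
        sources = fig3_sources()
        ledger = GroundTruthLedger(
            absent={
                "TOY:taxonA": frozenset(),
                "TOY:taxonB": frozenset(),
                "TOY:taxonC": frozenset(
                    {
                        "TOY:forelimb_bud", "TOY:forelimb",
                        "TOY:forelimb_skeleton", "TOY:humerus",
                        "TOY:entepicondyle",
                    }
                ),
            }
        )
    else:
        cfg = preset_config(preset, seed)
        anatomy = generate_ontology(cfg)
        taxonomy = generate_taxonomy(cfg)
        sources, ledger = generate_kb(cfg, anatomy, taxonomy)
    write_obo(anatomy, os.path.join(outdir, "anatomy.obo"))
    write_obo(taxonomy, os.path.join(outdir, "taxonomy.obo"))
    for m in sources:
        write_study_bundle(m, os.path.join(outdir, "bundles", f"{m.matrix_id}.json"))
    with open(os.path.join(outdir, "ledger.json"), "w", encoding="utf-8") as fh:
        fh.write(ledger.to_json())
        fh.write("\n")
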