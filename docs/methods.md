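# Methods

This note documents the model implemented by `phenosynth`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the problem sizes used by the test-suite and the
acceptance script.

## Ontology model and closures

An ontology is a typed directed multigraph: terms with labels, and edges
drawn from the closed relation set {`is_a`, `part_of`, `develops_from`,
`connected_to`}. An edge `(s, part_of, o)` reads "s is part of o"; the
subject→object direction therefore points *upward*, toward wholes,
superclasses, and developmental precursors (this matches OBO relationship
syntax). Acyclicity is enforced **per relation** for `is_a`, `part_of`, and
`develops_from`; a cycle that exists only in the mixed graph is tolerated
with a warning, because closure computation is a visited-set BFS and
terminates on any input. This tolerance is deliberate: a mixed two-relation
cycle (x `is_a` y together with y `part_of` x) is exactly the graph-level
shape of two entities that carry identical presence/absence information,
and real anatomy ontologies produce such equivalences through richer OWL
axioms that a reachability reasoner cannot represent any other way.

Closures are reflexive and transitive and may interleave relations freely:
`upward_closure(e)` is everything reachable by following edges
subject→object, `downward_closure(e)` the converse. The two are exact
adjoints (`y ∈ down(x)` iff `x ∈ up(y)`), a property the tests check
exhaustively on fixture graphs.

`connected_to` is loaded and queryable but excluded from presence/absence
closures; it participates only in class-expression evaluation. Connection
is not containment: a sternum connected to the girdle skeleton is a
sensible *character* to generate, but the absence of the girdle does not
entail the absence of the sternum.

## Entailment semantics

A phenotype is presence-type unless its quality is "absent" (PATO:0000462)
or "lacks all parts of type" (PATO:0002000); both absence spellings
normalize to a single negated entity (the `towards` filler when present,
else the phenotype's own entity). The rules are:

* presence-type phenotype on e₀ entails PRESENT for every e with
  e₀ ∈ down(e) over {is_a, part_of, develops_from};
* absence-type phenotype negating e₀ entails ABSENT for every e with
  e₀ ∈ up(e) over the same relations;
* otherwise NONE.

Open design points resolved here: absence propagation mirrors presence
exactly over the full mixed relation set, including `is_a` (absence of
"digit" entails absence of "digit 2" — the lacks-all-parts reading) and
mixed chains through `develops_from` (absence of a precursor of a whole
entails absence of the whole's parts). The symmetric rule is the only one
under which the presence/absence closures remain exact duals, which in turn
is what makes the equivalence-implies-isomorphism theorem (below) hold.

Every non-reflexive verdict carries a shortest witness chain of ontology
edges; replaying the chain edge by edge reproduces the verdict, and the
chains are serialized into report and NeXML provenance.

`presence_class_equivalent(x, y)` is true when x and y have identical
presence *and* absence supporter sets — i.e. no possible annotation can
distinguish them. A presence-only variant (identical presence supporters
only) is exposed behind a flag: it is the weaker test a DL query over
implied-presence class definitions performs, and is useful for reproducing
cluster taxonomies built that way, but only the both-closure test
guarantees isomorphic columns, so the both-closure test is the default.

## Class expressions

The grammar supports exactly what matrix synthesis needs: named classes
(CURIEs or single-quoted labels, curly quotes accepted), unions, and
existential restrictions `rel some (...)`. Intersection and negation are
rejected with a clear error. A named class denotes its `is_a` downward
closure. `rel some (F)` denotes every term with a chain of `is_a` and
`rel` edges containing **at least one** `rel` edge that ends in F — a
humerus is `part_of some` forelimb, the forelimb itself is not. Chains of
arbitrary length are allowed for every relation, including `connected_to`
(consistent with transitive closure; entities connected through an
intermediate are still selected). Label resolution is exact match after
quote normalization; ambiguity is an error, never a guess.

## Synthesis

One synthetic character per anatomy class subsumed by the entity
expression, lexicographically ordered; rows are the source taxa inside the
`is_a` closure of the taxon expression. For each (taxon, entity) the
builder collects one support record per (source, character, state,
phenotype) whose annotation entails a verdict for that entity, and the
cell value (PRESENT / ABSENT / BOTH / MISSING) is a pure function of the
supports. Mode is `asserted` only when the phenotype names the character's
*exact* entity with quality present/absent — a "present" on "femur bone"
is inferred, not asserted, support for "hindlimb" — and the
lacks-all-parts pattern is always inferred, since direct assertion is
defined by the two designated quality terms.

Published polymorphism (one taxon assigned several states of one character
in one source) contributes every state's supports independently. Taxa of
higher rank are distinct rows from their species; no state is ever
propagated down the taxonomy. Default pruning drops all-missing rows and
columns; the variable subset (characters whose column contains both
values, a BOTH cell alone sufficing) is a separate call that additionally
drops rows left all-missing and labels each kept character with the
provenance class of its variability: variable from assertions alone,
variable only through inference, or composed of inferred data entirely.

Disabling inference (`asserted_only=True`) restricts supports to direct
assertions; its populated cells are always a subset of the full run's, so
the missing-data fraction can only fall when inference is enabled. This
monotonicity is checked on every fixture corpus.

## Conflicts

Every BOTH cell receives exactly one category by strongest-evidence
precedence: `intra_source_polymorphism` (some single source directly
asserts both values — treated as real polymorphism and excluded from
conflict totals) > `asserted_asserted` > `asserted_inferred` >
`inferred_inferred`. The precedence rule is this package's resolution of
what is otherwise only a three-way tabulation; it is deterministic for
cells with mixed support types on one side. Conflicts are counted per
cell, not per conflicting support pair, and are reported (TSV, and JSON
with witness chains) but never auto-resolved — distinguishing a
digitization slip from a genuine re-interpretation of specimens needs an
expert looking at the provenance.

## Isomorphic clusters

Characters are partitioned by exact column equality, including the MISSING
pattern; singletons are dropped. Causes are assigned by a deterministic
cascade: (1) `presence_equivalence` when all member pairs pass the
both-closure equivalence test — the only cause that is a theorem: such
members *cannot* differ in any synthesized matrix; (2) `co_assertion` when
all members draw on the same supporting states and at least one state
directly annotates two or more members (one published state, several EQ
annotations); (3) `part_containment` when members form a chain under the
closure relations with annotations anchored on a single member; (4)
`inference_chain` as the residual. The cascade order resolves the overlap
among categories that are descriptive in origin; borderline clusters may
legitimately be split differently by other conventions.

## Reports

`missing_data_stats` counts populated, asserted, and inferred-only cells
and two missing fractions on the same grid — with all supports, and with
cell values re-derived from asserted supports alone. Entailing-state
counts (the sampling heat-map table) count distinct (source, character,
state) triples per (taxon, entity); states are the unit, so a state with
several entailing phenotypes for one entity counts once, and each assigned
state of a polymorphic cell counts once. Source counts per taxon count
distinct source matrices. All reports are pure functions of their inputs.

## Serialization

NeXML 0.9, one `otus` block and one standard-characters block with states
0 = absent, 1 = present and a polymorphic state set {0, 1} for BOTH;
MISSING cells are not written. Each written cell carries `ps:support` meta
elements (a small dedicated vocabulary, `https://phenosynth.dev/terms#`)
embedding the full support record including the witness chain, so the
matrix round-trips losslessly. Polymorphism, not uncertainty, is the
meaning of BOTH, hence `polymorphic_state_set` rather than
`uncertain_state_set`. Output is deterministic — stable ordering, no
timestamp unless the caller passes one — so fixture outputs are
byte-identical across runs. Offline structural validation
(`validate_nexml`) checks namespace/version, global id uniqueness, and
that every otu/char/state reference resolves and every symbol is legal;
it is a subset of full schema validation chosen to be runnable with no
network and no schema files on disk.

## The synthetic-data generator

The generator emulates an annotated comparative-morphology corpus at desk
scale. Anatomy ontologies are layered random DAGs (edges only cross toward
lower layers, so each relation is acyclic by construction) with a single
body root reachable from every term through `part_of`; taxonomies are
clade/genus/species trees with ranks. The latent truth — presence or
absence of every entity in every taxon — is drawn constructively:
per-taxon absence seeds are sampled and propagated downward (whole before
part), so the assignment is closure-consistent by construction rather
than by rejection. Studies then sample taxa and focal entities and emit
truth-consistent annotations: presence either as a direct "present"
assertion or as a shape/size quality (entailing presence without
asserting it — the mechanism behind characters that are variable only
through inference), absence either as a direct "absent" assertion or the
lacks-all-parts pattern, and annotations sometimes anchored on a part or
subclass of the focal entity to exercise cross-character inference.

Because natural annotations never contradict the latent truth, every BOTH
cell in a synthesized fixture matrix traces to an explicit injection. The
generator plants a requested number of conflicts of each category, and of
intra-source polymorphisms, at closure-leaf entities (empty strict
downward closure) so a counter-truth absence touches exactly one cell;
the ledger records every site with its affected cells, and recovery tests
require exact category recovery everywhere else. Cluster motifs — a
mixed-cycle equivalence pair, a three-term containment chain, and a
co-asserted digit fan — are appended to the ontology and annotated
through dedicated characters on distinct taxon patterns; natural
annotations are kept off the motif terms so the planted cause is
recoverable.

Default generator parameters (the standard study conditions): 60 anatomy
terms (+9 motif terms), 50 species in 10 genera, 6 sources of 8
characters each, annotation rate 0.35 per (taxon, character), absence
seed rate 0.10 per entity, shape-quality rate 0.40 among presence
annotations, part-anchoring rate 0.30, lacks-pattern rate 0.50 among
absence annotations, and two injections of each conflict category plus
two intra-source polymorphisms. These sizes give grids of ~3,500 cells
with roughly 40–45% missing data with inference and ~90% without — dense
enough that every behaviour (conflicts, clusters, higher-rank rows,
polymorphism) occurs, small enough that the whole suite runs in well
under a minute per corpus. Statistical knobs are verified to ±3 standard
errors over pooled seeds.

What the generator does **not** emulate: realistic anatomical
nomenclature, fossil preservation and specimen availability, correlated
character selection across studies, post-composed entities (e.g.
"part_of some X" used as an entity), and annotation error. Passing tests
therefore demonstrate the correctness of the reasoning, bookkeeping, and
recovery machinery under controlled conditions, not the curation quality
of any real corpus.

## Problem sizes used by tests and the acceptance script

* Reasoner/oracle equivalence: 100 random ontologies of 15–40 base terms
  (≤49 with motifs), every term pair, against a dense boolean-matrix
  reachability oracle, plus exhaustive duality. (~10 s)
* Synthesis recovery, conflict recovery, inference monotonicity: 20
  standard-size corpora as above. (~10 s)
* Equivalence-implies-isomorphism: 100 corpora at 30 terms / 20 taxa / 4
  sources; cluster detection cross-checked against an O(n²) column oracle
  on 20 of them. (~15 s)
* Serialization: the deterministic toy demo (golden file committed at
  `tests/data/golden_fig3.nexml`) plus generated corpora, round-tripped
  and byte-compared. (seconds)

## Known limitations

* The reasoner is reachability over four hard-coded relations; it has no
  logical definitions, disjointness, or property characteristics, so
  equivalences that real ontologies express through OWL axioms appear here
  only when they leave a mixed-cycle footprint in the graph.
* Entities are named classes (plus the `towards` slot); post-composed
  entity expressions in annotations are out of scope.
* The NeXML validator is structural, not schema-complete.
* Conflict counting is per cell; a cell supported by several independent
  disagreeing pairs is still one conflict record.
* No character weighting or merging is attempted for downstream
  phylogenetics; isomorphic clusters are reported precisely so a user can
  decide.
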