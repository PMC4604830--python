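"""Synthesize a presence/absence supermatrix from two toy studies.

Study 1 describes humerus shape in one taxon and asserts an entepicondyle
in another; study 2 asserts the forelimb bud absent in a third.  The
synthesized matrix shows how sparse published statements fan out into a
populated entity-by-taxon grid, with per-cell provenance separating
direct assertions from inference.
"""

from phenosynth import missing_data_stats, synthesize
from phenosynth.fixtures import fig3_ontology, fig3_sources, fig3_taxonomy
from phenosynth.synthesis import SupportMode

matrix = synthesize(
    fig3_ontology(),
    fig3_taxonomy(),
    fig3_sources(),
    entity_expr="part_of some ('forelimb')",
    taxon_expr="TOY:clade",
)

print("characters:", list(matrix.characters))
print("taxa:      ", list(matrix.taxa))
print()
for taxon in matrix.taxa:
    row = []
    for entity in matrix.characters:
        cell = matrix.cell(taxon, entity)
        asserted = sum(1 for s in cell.supports if s.mode is SupportMode.ASSERTED)
        row.append(f"{cell.value.value:8s}(a={asserted},i={len(cell.supports)-asserted})")
    print(taxon, " ".join(row))

stats = missing_data_stats(matrix)
print(
    f"\npopulated {stats.n_populated}/{stats.n_cells} cells; "
    f"missing {stats.frac_missing_with_inference:.1%} with inference, "
    f"{stats.frac_missing_asserted_only:.1%} from direct assertions alone"
)
print(
    "(a=asserted, i=inferred supports per cell — the provenance a reviewer "
    "would inspect)"
)
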