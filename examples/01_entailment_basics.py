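"""Presence/absence entailment on the toy fin-to-limb partonomy.

Builds the five-term toy anatomy (entepicondyle part_of humerus part_of
forelimb skeleton part_of forelimb develops_from forelimb bud) and shows
how annotations propagate: any quality on the humerus implies presence of
everything above it, while absence of the forelimb bud cascades down to
the humerus — but absence of the humerus says nothing about the forelimb.
"""

from phenosynth import EQPhenotype, entails, presence_supporters
from phenosynth.eq_model import ABSENT_QUALITY
from phenosynth.fixtures import fig3_ontology

anatomy = fig3_ontology()

print("entities whose presence implies a present forelimb:")
for term in sorted(presence_supporters(anatomy, "TOY:forelimb")):
    print("  ", term, "-", anatomy.label(term))

l_shaped_humerus = EQPhenotype(entity="TOY:humerus", quality="PATO:0000052")
verdict = entails(anatomy, l_shaped_humerus, "TOY:forelimb_bud")
print("\n'humerus shaped' says about the forelimb bud:", verdict.value.value)
print("witness chain:", [f"{s} -{r.value}-> {o}" for s, r, o in verdict.chain])

absent_humerus = EQPhenotype(entity="TOY:humerus", quality=ABSENT_QUALITY)
print(
    "'humerus absent' says about the entepicondyle:",
    entails(anatomy, absent_humerus, "TOY:entepicondyle").value.value,
)
print(
    "'humerus absent' says about the forelimb:",
    entails(anatomy, absent_humerus, "TOY:forelimb").value.value,
    "(absence never propagates upward)",
)
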