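"""Presence/absence entailment semantics and the supporter-set duality."""

import pytest

from phenosynth.eq_model import (
    ABSENT_QUALITY,
    EQPhenotype,
    LACKS_ALL_PARTS_QUALITY,
    Polarity,
    PRESENT_QUALITY,
)
from phenosynth.fixtures import _motif_terms
from phenosynth.ontology import Relation
from phenosynth.reasoner import (
    Verdict,
    absence_supporters,
    entails,
    presence_class_equivalent,
    presence_supporters,
)

from conftest import build_kb
from oracles import oracle_absence_supporters, oracle_presence_supporters

SHAPE = "PATO:0000052"


class TestFig3Supporters:
    def test_presence_propagates_up_from_parts(self, fig3):
        assert presence_supporters(fig3, "TOY:forelimb") == {
            "TOY:forelimb",
            "TOY:forelimb_skeleton",
            "TOY:humerus",
            "TOY:entepicondyle",
        }

    def test_presence_reaches_precursor_via_develops_from(self, fig3):
        assert "TOY:humerus" in presence_supporters(fig3, "TOY:forelimb_bud")

    def test_absence_propagates_down_from_wholes(self, fig3):
        assert absence_supporters(fig3, "TOY:humerus") == {
            "TOY:humerus",
            "TOY:forelimb_skeleton",
            "TOY:forelimb",
            "TOY:forelimb_bud",
        }

    def test_absent_part_says_nothing_about_whole(self, fig3):
        assert "TOY:humerus" not in absence_supporters(fig3, "TOY:forelimb")

    def test_isolated_entity_supports_itself(self):
        from phenosynth.ontology import Ontology

        o = Ontology(namespace="anatomy", terms={"T:x": "x"}, edges=set())
        assert presence_supporters(o, "T:x") == {"T:x"}
        assert absence_supporters(o, "T:x") == {"T:x"}


class TestEntails:
    def test_shape_on_humerus_implies_forelimb_present(self, fig3):
        p = EQPhenotype("TOY:humerus", SHAPE)
        v = entails(fig3, p, "TOY:forelimb")
        assert v.value is Verdict.PRESENT

    def test_absent_bud_implies_absent_humerus(self, fig3):
        p = EQPhenotype("TOY:forelimb_bud", ABSENT_QUALITY)
        v = entails(fig3, p, "TOY:humerus")
        assert v.value is Verdict.ABSENT

    def test_absent_humerus_says_nothing_about_forelimb(self, fig3):
        p = EQPhenotype("TOY:humerus", ABSENT_QUALITY)
        assert entails(fig3, p, "TOY:forelimb").value is Verdict.NONE

    def test_lacks_all_parts_pattern_negates_towards(self, fig3):
        p = EQPhenotype(
            "TOY:forelimb", LACKS_ALL_PARTS_QUALITY,
            related_entity="TOY:forelimb_bud",
        )
        assert entails(fig3, p, "TOY:humerus").value is Verdict.ABSENT

    def test_polarity_safety(self, fig3):
        # an absence-type phenotype can never yield PRESENT, and vice versa
        for entity in fig3.terms:
            for anchor in fig3.terms:
                pv = entails(fig3, EQPhenotype(anchor, SHAPE), entity).value
                av = entails(fig3, EQPhenotype(anchor, ABSENT_QUALITY), entity).value
                assert pv in (Verdict.PRESENT, Verdict.NONE)
                assert av in (Verdict.ABSENT, Verdict.NONE)

    def test_chain_replays_verdict(self, fig3):
        p = EQPhenotype("TOY:entepicondyle", SHAPE)
        v = entails(fig3, p, "TOY:forelimb_bud")
        assert v.value is Verdict.PRESENT
        # chain is a connected upward path of real ontology edges
        cur = "TOY:entepicondyle"
        for s, rel, o in v.chain:
            assert s == cur
            assert (s, rel, o) in fig3.edges
            cur = o
        assert cur == "TOY:forelimb_bud"

        a = EQPhenotype("TOY:forelimb_bud", ABSENT_QUALITY)
        va = entails(fig3, a, "TOY:entepicondyle")
        assert va.value is Verdict.ABSENT
        cur = "TOY:forelimb_bud"
        for s, rel, o in va.chain:
            assert o == cur  # downward traversal of subject->object edges
            assert (s, rel, o) in fig3.edges
            cur = s
        assert cur == "TOY:entepicondyle"

    def test_reflexive_case_has_empty_chain(self, fig3):
        v = entails(fig3, EQPhenotype("TOY:humerus", SHAPE), "TOY:humerus")
        assert v.value is Verdict.PRESENT and v.chain == ()


class TestDualityAndOracle:
    @pytest.mark.parametrize("seed", [3, 12, 31])
    def test_supporters_match_oracle_and_duality(self, seed):
        _cfg, anatomy, _t, _s, _l = build_kb(seed, n_anatomy_terms=35)
        pres = {t: presence_supporters(anatomy, t) for t in anatomy.terms}
        absn = {t: absence_supporters(anatomy, t) for t in anatomy.terms}
        for t in anatomy.terms:
            assert pres[t] == oracle_presence_supporters(anatomy, t)
            assert absn[t] == oracle_absence_supporters(anatomy, t)
        for e in anatomy.terms:
            for e0 in anatomy.terms:
                assert (e0 in pres[e]) == (e in absn[e0])


class TestPresenceClassEquivalence:
    def test_reflexive(self, fig3):
        assert presence_class_equivalent(fig3, "TOY:humerus", "TOY:humerus")

    def test_injected_equivalence_pair(self):
        cfg, anatomy, _t, _s, _l = build_kb(5)
        x, y = _motif_terms(cfg)["presence_equivalence"]
        assert presence_class_equivalent(anatomy, x, y)
        assert presence_class_equivalent(anatomy, x, y, presence_only=True)

    def test_distinct_chain_terms_not_equivalent(self, fig3):
        assert not presence_class_equivalent(fig3, "TOY:humerus", "TOY:forelimb")
        # the weak variant is still false here: downward closures differ
        assert not presence_class_equivalent(
            fig3, "TOY:humerus", "TOY:forelimb", presence_only=True
        )

    def test_is_equivalence_relation(self):
        _cfg, anatomy, _t, _s, _l = build_kb(8, n_anatomy_terms=25)
        terms = anatomy.sorted_terms()
        eq = {
            (a, b): presence_class_equivalent(anatomy, a, b)
            for a in terms
            for b in terms
        }
        for a in terms:
            assert eq[(a, a)]
            for b in terms:
                assert eq[(a, b)] == eq[(b, a)]
                for c in terms:
                    if eq[(a, b)] and eq[(b, c)]:
                        assert eq[(a, c)]

    def test_matches_bruteforce_supporter_comparison(self):
        _cfg, anatomy, _t, _s, _l = build_kb(9, n_anatomy_terms=25)
        for a in anatomy.terms:
            for b in anatomy.terms:
                expected = oracle_presence_supporters(
                    anatomy, a
                ) == oracle_presence_supporters(anatomy, b) and (
                    oracle_absence_supporters(anatomy, a)
                    == oracle_absence_supporters(anatomy, b)
                )
                assert presence_class_equivalent(anatomy, a, b) == expected
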