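"""Isomorphic-character clustering and cause classification."""

import pytest

from phenosynth.clusters import (
    ClusterCause,
    classify_clusters,
    cluster_report,
    find_isomorphic_clusters,
)
from phenosynth.eq_model import PRESENT_QUALITY, EQPhenotype
from phenosynth.fixtures import _SourceBuilder, _motif_terms
from phenosynth.ontology import Ontology, Relation
from phenosynth.reasoner import presence_class_equivalent
from phenosynth.synthesis import CellValue, synthesize

from conftest import build_matrix
from oracles import oracle_clusters

SHAPE = "PATO:0000052"


def _tiny_taxonomy(n=3):
    terms = {"TX:root": "clade"}
    edges = set()
    ranks = {"TX:root": "class"}
    for i in range(n):
        t = f"TX:t{i}"
        terms[t] = f"taxon {i}"
        ranks[t] = "species"
        edges.add((t, Relation.IS_A, "TX:root"))
    return Ontology(namespace="taxonomy", terms=terms, edges=edges, ranks=ranks)


def _single_state_source(char_label, state_label, phenotypes, taxa):
    sb = _SourceBuilder("mX", "Tiny study")
    char = sb.new_char(char_label)
    sid = sb.add_state(char, state_label, phenotypes)
    for t in taxa:
        sb.assign(t, char, sid)
    return sb.build()


class TestFindClusters:
    def test_part_chain_forms_cluster(self):
        # annotations only on the part: whole and part get identical columns
        o = Ontology(
            namespace="anatomy",
            terms={"A:part": "part", "A:whole": "whole"},
            edges={("A:part", Relation.PART_OF, "A:whole")},
        )
        src = _single_state_source(
            "part", "part shaped", [EQPhenotype("A:part", SHAPE)], ["TX:t0", "TX:t2"]
        )
        m = synthesize(o, _tiny_taxonomy(), [src], "A:part or A:whole", "TX:root")
        clusters = find_isomorphic_clusters(m)
        assert [c.members for c in clusters] == [("A:part", "A:whole")]
        assert clusters[0].inferred_only

    def test_all_distinct_columns_no_clusters(self, fig3, fig3_tax, fig3_kb):
        m = synthesize(fig3, fig3_tax, fig3_kb[:1],
                       "TOY:entepicondyle or TOY:forelimb_bud", "TOY:clade")
        # entepicondyle present for B, bud missing everywhere (pruned)
        assert find_isomorphic_clusters(m) == []

    @pytest.mark.parametrize("seed", [1, 4, 22])
    def test_matches_all_pairs_oracle(self, seed):
        _a, _t, _s, _l, m = build_matrix(seed)
        got = [c.members for c in find_isomorphic_clusters(m)]
        assert got == oracle_clusters(m)

    def test_members_recheck_cell_by_cell(self, medium_matrix):
        _a, _t, _s, _l, m = medium_matrix
        for c in find_isomorphic_clusters(m):
            first = c.members[0]
            for other in c.members[1:]:
                for taxon in m.taxa:
                    assert m.cell(taxon, first).value is m.cell(taxon, other).value


class TestCauses:
    def test_equivalence_pair(self):
        o = Ontology(
            namespace="anatomy",
            terms={"A:x": "digit", "A:y": "digit skeleton", "A:r": "root"},
            edges={
                ("A:x", Relation.IS_A, "A:y"),
                ("A:y", Relation.PART_OF, "A:x"),
                ("A:y", Relation.PART_OF, "A:r"),
            },
        )
        src = _single_state_source(
            "digit", "digit shaped", [EQPhenotype("A:x", SHAPE)], ["TX:t1"]
        )
        m = synthesize(o, _tiny_taxonomy(), [src], "part_of some (A:r)", "TX:root")
        clusters = classify_clusters(find_isomorphic_clusters(m), o, m)
        assert [c.cause for c in clusters] == [ClusterCause.PRESENCE_EQUIVALENCE]

    def test_co_asserted_digits(self):
        o = Ontology(
            namespace="anatomy",
            terms={"A:d6": "digit 6", "A:d7": "digit 7", "A:d8": "digit 8"},
            edges=set(),
        )
        src = _single_state_source(
            "digits", "pedal digits 6, 7, and 8 present",
            [EQPhenotype(f"A:d{i}", PRESENT_QUALITY) for i in (6, 7, 8)],
            ["TX:t0", "TX:t1"],
        )
        m = synthesize(o, _tiny_taxonomy(), [src], "A:d6 or A:d7 or A:d8", "TX:root")
        clusters = classify_clusters(find_isomorphic_clusters(m), o, m)
        assert [c.cause for c in clusters] == [ClusterCause.CO_ASSERTION]
        assert not clusters[0].inferred_only

    def test_containment_chain(self):
        o = Ontology(
            namespace="anatomy",
            terms={"A:a": "femur bone", "A:b": "hindlimb", "A:c": "limb"},
            edges={
                ("A:a", Relation.PART_OF, "A:b"),
                ("A:b", Relation.PART_OF, "A:c"),
            },
        )
        src = _single_state_source(
            "femur", "femur bone shaped", [EQPhenotype("A:a", SHAPE)], ["TX:t0"]
        )
        m = synthesize(o, _tiny_taxonomy(), [src], "A:a or A:b or A:c", "TX:root")
        clusters = classify_clusters(find_isomorphic_clusters(m), o, m)
        assert [c.cause for c in clusters] == [ClusterCause.PART_CONTAINMENT]

    def test_unrelated_coincidence_is_residual(self):
        o = Ontology(
            namespace="anatomy",
            terms={"A:nail": "nail", "A:skin": "digit skin"},
            edges=set(),
        )
        sb = _SourceBuilder("mX", "Tiny study")
        ch1 = sb.new_char("nail")
        s1 = sb.add_state(ch1, "nail shaped", [EQPhenotype("A:nail", SHAPE)])
        ch2 = sb.new_char("skin")
        s2 = sb.add_state(ch2, "skin shaped", [EQPhenotype("A:skin", SHAPE)])
        for t in ("TX:t0", "TX:t1"):
            sb.assign(t, ch1, s1)
            sb.assign(t, ch2, s2)
        m = synthesize(o, _tiny_taxonomy(), [sb.build()], "A:nail or A:skin", "TX:root")
        clusters = classify_clusters(find_isomorphic_clusters(m), o, m)
        assert [c.cause for c in clusters] == [ClusterCause.INFERENCE_CHAIN]

    @pytest.mark.parametrize("seed", [1, 6, 19])
    def test_injected_motifs_recovered(self, seed):
        anatomy, _t, sources, ledger, m = build_matrix(seed)
        clusters = classify_clusters(find_isomorphic_clusters(m), anatomy, m, sources)
        for motif in ledger.motifs:
            hit = next(
                (c for c in clusters if set(motif.members) <= set(c.members)), None
            )
            assert hit is not None, f"{motif.kind} members not clustered together"
            if set(hit.members) == set(motif.members):
                assert hit.cause.value == motif.kind


class TestNecessityTheorem:
    @pytest.mark.parametrize("seed", [2, 9])
    def test_equivalent_characters_always_isomorphic(self, seed):
        anatomy, _t, _s, _l, m = build_matrix(seed)
        chars = list(m.characters)
        for i, x in enumerate(chars):
            for y in chars[i + 1 :]:
                if presence_class_equivalent(anatomy, x, y):
                    assert m.column(x) == m.column(y)


class TestReport:
    def test_empty_matrix(self):
        from phenosynth.synthesis import SyntheticMatrix

        table, summary = cluster_report([], SyntheticMatrix(characters=(), taxa=()))
        assert table.empty
        assert summary["n_clusters"] == 0 and summary["n_cells_in_clusters"] == 0

    def test_cell_totals_add_up(self, medium_matrix):
        anatomy, _t, sources, _l, m = medium_matrix
        clusters = classify_clusters(find_isomorphic_clusters(m), anatomy, m, sources)
        table, summary = cluster_report(clusters, m)
        expected = sum(
            1
            for c in clusters
            for e in c.members
            for t in m.taxa
            if m.cell(t, e).value is not CellValue.MISSING
        )
        assert summary["n_cells_in_clusters"] == expected
        assert table["n_populated_cells"].sum() == expected
        assert summary["n_clusters"] == len(clusters)
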