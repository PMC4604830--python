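"""Missing-data statistics, entailing-state counts, taxon sampling counts."""

import pytest

from phenosynth.eq_model import ABSENT_QUALITY, EQPhenotype
from phenosynth.fixtures import _SourceBuilder, fig3_sources
from phenosynth.reports import (
    entailing_state_counts,
    missing_data_stats,
    taxon_source_counts,
)
from phenosynth.synthesis import (
    CellValue,
    SupportMode,
    SyntheticMatrix,
    synthesize,
)

from conftest import build_matrix


class TestMissingDataStats:
    def test_empty_matrix(self):
        stats = missing_data_stats(SyntheticMatrix(characters=(), taxa=()))
        assert stats.n_cells == 0
        assert stats.frac_missing_with_inference == 1.0
        assert stats.frac_missing_asserted_only == 1.0

    def test_populated_cells_partition(self, medium_matrix):
        _a, _t, _s, _l, m = medium_matrix
        stats = missing_data_stats(m)
        assert stats.n_populated == stats.n_asserted_cells + stats.n_inferred_only_cells
        assert 0.0 <= stats.frac_missing_with_inference <= 1.0
        assert stats.frac_missing_with_inference <= stats.frac_missing_asserted_only

    def test_matches_bruteforce_recount(self, medium_matrix):
        _a, _t, _s, _l, m = medium_matrix
        stats = missing_data_stats(m)
        populated = asserted = 0
        for t in m.taxa:
            for e in m.characters:
                cell = m.cell(t, e)
                if cell.value is CellValue.MISSING:
                    continue
                populated += 1
                if any(s.mode is SupportMode.ASSERTED for s in cell.supports):
                    asserted += 1
        assert stats.n_populated == populated
        assert stats.n_asserted_cells == asserted
        assert stats.n_cells == len(m.taxa) * len(m.characters)
        assert stats.frac_missing_with_inference == pytest.approx(
            1 - populated / stats.n_cells
        )


class TestEntailingStateCounts:
    def test_taxon_without_data_has_zero_row(self, fig3, fig3_tax, fig3_kb):
        counts = entailing_state_counts(
            fig3_kb, fig3, fig3_tax,
            entities=sorted(fig3.terms), taxa=["TOY:taxonC", "TOY:taxonA"],
        )
        assert list(counts.index) == ["TOY:taxonC", "TOY:taxonA"]
        # taxon C has one absence state entailing absence of every term
        assert (counts.loc["TOY:taxonC"] == 1).all()

    def test_absence_on_whole_counts_for_all_parts(self, fig3, fig3_tax):
        sb = _SourceBuilder("mZ", "Absence study")
        ch = sb.new_char("forelimb")
        sid = sb.add_state(
            ch, "forelimb absent", [EQPhenotype("TOY:forelimb", ABSENT_QUALITY)]
        )
        sb.assign("TOY:taxonA", ch, sid)
        counts = entailing_state_counts(
            [sb.build()], fig3, fig3_tax,
            entities=["TOY:entepicondyle", "TOY:humerus", "TOY:forelimb",
                      "TOY:forelimb_bud"],
            taxa=["TOY:taxonA"],
        )
        row = counts.loc["TOY:taxonA"]
        assert row["TOY:entepicondyle"] == 1
        assert row["TOY:humerus"] == 1
        assert row["TOY:forelimb"] == 1
        assert row["TOY:forelimb_bud"] == 0  # absence never propagates upward

    @pytest.mark.parametrize("seed", [3, 16])
    def test_matches_naive_triple_enumeration(self, seed):
        anatomy, taxonomy, sources, _l, m = build_matrix(
            seed, n_anatomy_terms=25, n_taxa=12, n_sources=3
        )
        entities = list(m.characters)
        taxa = list(m.taxa)
        counts = entailing_state_counts(sources, anatomy, taxonomy, entities, taxa)
        from phenosynth.ontology import CLOSURE_RELATIONS

        from oracles import oracle_downward, oracle_upward

        for taxon in taxa:
            for entity in entities:
                triples = set()
                for src in sources:
                    chars = {c.char_id: c for c in src.characters}
                    for (t, char_id), sids in src.cells.items():
                        if t != taxon:
                            continue
                        for sid in sids:
                            state = chars[char_id].state(sid)
                            for p in state.phenotypes:
                                if p.negated_entity is None:
                                    hit = entity in oracle_upward(
                                        anatomy, p.entity, CLOSURE_RELATIONS
                                    )
                                else:
                                    hit = entity in oracle_downward(
                                        anatomy, p.negated_entity, CLOSURE_RELATIONS
                                    )
                                if hit:
                                    triples.add((src.matrix_id, char_id, sid))
                assert counts.loc[taxon, entity] == len(triples)

    def test_counts_never_negative_and_monotone(self, medium_matrix):
        anatomy, taxonomy, sources, _l, m = medium_matrix
        counts = entailing_state_counts(
            sources, anatomy, taxonomy, list(m.characters)[:10], list(m.taxa)[:10]
        )
        assert (counts.values >= 0).all()


class TestTaxonSourceCounts:
    def test_single_bundle_counts_one(self, fig3_tax, fig3_kb):
        table = taxon_source_counts(fig3_kb, fig3_tax, "TOY:clade")
        got = dict(zip(table["taxon"], table["n_matrices"]))
        assert got == {"TOY:taxonA": 1, "TOY:taxonB": 1, "TOY:taxonC": 1}
        assert set(table["rank"]) == {"species"}

    def test_duplicate_states_in_one_source_do_not_inflate(self, fig3_tax):
        sources = fig3_sources()
        sb = _SourceBuilder("toy01", "Toy Study 1 (2001)")
        ch = sb.new_char("humerus shape")
        s1 = sb.add_state(ch, "humerus L-shaped",
                          [EQPhenotype("TOY:humerus", "PATO:0000052")])
        ch2 = sb.new_char("humerus size")
        s2 = sb.add_state(ch2, "humerus large",
                          [EQPhenotype("TOY:humerus", "PATO:0000117")])
        sb.assign("TOY:taxonA", ch, s1)
        sb.assign("TOY:taxonA", ch2, s2)
        table = taxon_source_counts([sb.build()], fig3_tax, "TOY:clade")
        got = dict(zip(table["taxon"], table["n_matrices"]))
        assert got == {"TOY:taxonA": 1}

    def test_fixture_histogram_matches_ledger_sources(self, medium_kb):
        _cfg, _a, taxonomy, sources, _l = medium_kb
        table = taxon_source_counts(sources, taxonomy, "TAXON:0000000")
        expected = {}
        for src in sources:
            for (taxon, _c) in src.cells:
                expected.setdefault(taxon, set()).add(src.matrix_id)
        got = dict(zip(table["taxon"], table["n_matrices"]))
        assert got == {t: len(v) for t, v in expected.items()}
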