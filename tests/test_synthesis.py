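"""Supermatrix construction: characters, taxa, cells, provenance, pruning."""

import pytest

from phenosynth.eq_model import PRESENT_QUALITY
from phenosynth.fixtures import (
    default_entity_expression,
    default_taxon_expression,
    fig3_sources,
)
from phenosynth.io_nexml import matrix_to_json
from phenosynth.reasoner import entails
from phenosynth.synthesis import (
    CellValue,
    SupportMode,
    VariabilityBasis,
    cell_value_from_supports,
    generate_characters,
    select_taxa,
    synthesize,
    variable_subset,
)

from conftest import build_kb, build_matrix
from oracles import oracle_synthesize_values


class TestGenerateCharacters:
    def test_fig3_sorted(self, fig3):
        got = generate_characters(fig3, "part_of some (TOY:forelimb)")
        assert got == ["TOY:entepicondyle", "TOY:forelimb_skeleton", "TOY:humerus"]

    def test_leaf_expression(self, fig3):
        assert generate_characters(fig3, "TOY:entepicondyle") == ["TOY:entepicondyle"]

    def test_empty_result_warns(self, fig3, caplog):
        from phenosynth.ontology import Ontology

        lonely = Ontology(namespace="anatomy", terms={"T:x": "x"}, edges=set())
        with caplog.at_level("WARNING", logger="phenosynth.synthesis"):
            assert generate_characters(lonely, "part_of some (T:x)") == []
        assert any("no anatomy classes" in r.message for r in caplog.records)


class TestSelectTaxa:
    def test_root_selects_every_taxon_with_data(self, fig3_tax, fig3_kb):
        got = select_taxa(fig3_tax, "TOY:clade", fig3_kb)
        assert got == ["TOY:taxonA", "TOY:taxonB", "TOY:taxonC"]

    def test_clade_restriction(self, medium_kb):
        _cfg, _a, taxonomy, sources, _l = medium_kb
        genus = "TAXON:0001000"
        got = select_taxa(taxonomy, genus, sources)
        from phenosynth.ontology import Relation, downward_closure

        clade = downward_closure(taxonomy, genus, {Relation.IS_A})
        assert got and set(got) <= clade

    def test_out_of_clade_taxon_excluded(self, fig3_tax, fig3_kb):
        # restrict to a single species: the other two carry data but are out
        assert select_taxa(fig3_tax, "TOY:taxonB", fig3_kb) == ["TOY:taxonB"]


class TestSynthesize:
    def test_fig3_cells(self, fig3, fig3_tax, fig3_kb):
        m = synthesize(fig3, fig3_tax, fig3_kb,
                       "part_of some (TOY:forelimb)", "TOY:clade")
        values = {
            (t, e): m.cell(t, e).value for t in m.taxa for e in m.characters
        }
        # taxon A enters purely through a shape annotation (no direct P/A)
        assert values[("TOY:taxonA", "TOY:humerus")] is CellValue.PRESENT
        assert all(
            s.mode is SupportMode.INFERRED
            for s in m.cell("TOY:taxonA", "TOY:humerus").supports
        )
        assert values[("TOY:taxonA", "TOY:entepicondyle")] is CellValue.MISSING
        # taxon B asserts the entepicondyle; humerus follows by inference
        b_cell = m.cell("TOY:taxonB", "TOY:entepicondyle")
        assert b_cell.value is CellValue.PRESENT
        assert any(s.mode is SupportMode.ASSERTED for s in b_cell.supports)
        assert values[("TOY:taxonB", "TOY:humerus")] is CellValue.PRESENT
        # taxon C: absent bud cascades down the whole partonomy
        assert all(
            values[("TOY:taxonC", e)] is CellValue.ABSENT for e in m.characters
        )

    def test_empty_source_list(self, fig3, fig3_tax):
        m = synthesize(fig3, fig3_tax, [], "part_of some (TOY:forelimb)", "TOY:clade")
        assert m.characters == () and m.taxa == () and not m.cells

    def test_dangling_annotation_is_hard_error(self, fig3, fig3_tax):
        import copy

        from phenosynth.eq_model import source_matrix_from_dict, source_matrix_to_dict

        bad = copy.deepcopy(source_matrix_to_dict(fig3_sources()[0]))
        bad["characters"][0]["states"][0]["phenotypes"][0]["entity"] = "TOY:ghost"
        src = source_matrix_from_dict(bad)
        with pytest.raises(ValueError, match="TOY:ghost"):
            synthesize(fig3, fig3_tax, [src],
                       "part_of some (TOY:forelimb)", "TOY:clade")

    @pytest.mark.parametrize("seed", [2, 14])
    def test_cells_match_bruteforce_oracle(self, seed):
        anatomy, _t, sources, _l, m = build_matrix(
            seed, n_anatomy_terms=25, n_taxa=15, n_sources=3
        )
        expected = oracle_synthesize_values(anatomy, sources, m.characters, m.taxa)
        got = {k: c.value.value for k, c in m.cells.items()}
        assert got == expected

    def test_every_support_replays(self, medium_matrix):
        anatomy, _t, _s, _l, m = medium_matrix
        for (taxon, entity), cell in m.cells.items():
            for s in cell.supports:
                v = entails(anatomy, s.phenotype, entity)
                assert v.value.value == s.value.upper()
                assert s.taxon == taxon

    def test_deterministic_serialization(self, medium_kb):
        _cfg, anatomy, taxonomy, sources, _l = medium_kb
        runs = [
            synthesize(anatomy, taxonomy, sources,
                       default_entity_expression(), default_taxon_expression())
            for _ in range(2)
        ]
        assert matrix_to_json(runs[0]) == matrix_to_json(runs[1])

    def test_asserted_only_is_subset(self, medium_kb):
        _cfg, anatomy, taxonomy, sources, _l = medium_kb
        full = synthesize(anatomy, taxonomy, sources,
                          default_entity_expression(), default_taxon_expression(),
                          prune="none")
        lean = synthesize(anatomy, taxonomy, sources,
                          default_entity_expression(), default_taxon_expression(),
                          prune="none", asserted_only=True)
        assert set(lean.cells) <= set(full.cells)
        for key, cell in lean.cells.items():
            assert all(s.mode is SupportMode.ASSERTED for s in cell.supports)


class TestVariableSubset:
    def test_constant_column_dropped(self, fig3, fig3_tax, fig3_kb):
        # without the absence study, all columns are constant PRESENT
        m = synthesize(fig3, fig3_tax, fig3_kb[:1],
                       "part_of some (TOY:forelimb)", "TOY:clade")
        assert variable_subset(m).characters == ()

    def test_fig3_variable_and_basis(self, fig3, fig3_tax, fig3_kb):
        m = synthesize(fig3, fig3_tax, fig3_kb,
                       "part_of some (TOY:forelimb)", "TOY:clade")
        vs = variable_subset(m)
        assert set(vs.characters) == set(m.characters)  # absence made all variable
        # humerus column: inferred presence + inferred absence only
        assert vs.variability_basis["TOY:humerus"] is VariabilityBasis.INFERRED_ONLY
        # entepicondyle: asserted presence, absence only by inference
        assert (
            vs.variability_basis["TOY:entepicondyle"]
            is VariabilityBasis.VARIABLE_ONLY_BY_INFERENCE
        )

    def test_column_scan_oracle(self, medium_matrix):
        _a, _t, _s, _l, m = medium_matrix
        vs = variable_subset(m)
        expected = []
        for e in m.characters:
            col = [m.cell(t, e).value for t in m.taxa]
            present = CellValue.PRESENT in col or CellValue.BOTH in col
            absent = CellValue.ABSENT in col or CellValue.BOTH in col
            if present and absent:
                expected.append(e)
        assert list(vs.characters) == expected
        # no all-missing rows survive
        for taxon in vs.taxa:
            assert any(
                vs.cell(taxon, e).value is not CellValue.MISSING
                for e in vs.characters
            )


class TestCellValue:
    def test_value_is_pure_function_of_supports(self, medium_matrix):
        _a, _t, _s, _l, m = medium_matrix
        for cell in m.cells.values():
            assert cell_value_from_supports(cell.supports) is cell.value
        assert cell_value_from_supports([]) is CellValue.MISSING
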