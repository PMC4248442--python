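import numpy as np
import pandas as pd
import pytest

from feaspath.feasibility import FeasibilityCall
from feaspath.integration import (
    CompoundMapping,
    UtilizationPredictor,
    compare_species,
    concordance,
    count_mapped,
    map_compound,
    network_overlay,
    overlay_graph,
    packaged_mtb_msm_table,
    predict_utilization,
)
from feaspath.phenome import GrowthClassifier
from feaspath.transcriptome import expression_flags


@pytest.fixture(scope="module")
def flags(expression_fixture):
    expr, _ = expression_fixture
    return expression_flags(expr)


class TestMapCompound:
    def test_empty_entry_list_is_unmapped(self):
        table = {"X": CompoundMapping(condition="X")}
        hit = map_compound("X", table)
        assert not hit.mapped and hit.record is None

    def test_absent_condition_is_a_lookup_error(self):
        with pytest.raises(KeyError):
            map_compound("missing", {"X": CompoundMapping(condition="X")})

    def test_name_matching_folds_case_and_whitespace(self):
        table = {"D-Glucose": CompoundMapping("D-Glucose", ["met:g"])}
        assert map_compound("  d-glucose ", table).mapped

    def test_fixture_mapped_count(self, compound_fixture):
        table, truth = compound_fixture
        assert count_mapped(table) == 135
        # linear-scan oracle
        assert sum(1 for rec in table.values() if rec.entry_metabolites) == 135
        assert {c for c, rec in table.items() if rec.mapped} == truth.mapped_compounds

    def test_zero_mapped_config(self, plate_fixture, expression_fixture):
        from feaspath.simulate import FixtureConfig, generate_compound_map

        expr, _ = expression_fixture
        _, pm_truth = plate_fixture
        cfg = FixtureConfig(n_mapped_compounds=0)
        table, _ = generate_compound_map(cfg, pm_truth, expr)
        assert count_mapped(table) == 0


class TestPredictUtilization:
    def test_transporter_plus_expressed_enzyme_supported(self, flags):
        expressed_locus = flags.index[flags["expressed"]][0]
        rec = CompoundMapping("c", ["met"], ["T1"], [expressed_locus])
        pred, why = predict_utilization(rec, flags)
        assert pred == "supported" and expressed_locus in why

    def test_missing_transporter_blocks_support(self, flags):
        expressed_locus = flags.index[flags["expressed"]][0]
        rec = CompoundMapping("c", ["met"], [], [expressed_locus])
        pred, why = predict_utilization(rec, flags)
        assert pred == "not_supported" and "transporter" in why

    def test_silent_enzymes_block_support(self, flags):
        silent = flags.index[~flags["expressed"]][0]
        rec = CompoundMapping("c", ["met"], ["T1"], [silent])
        pred, why = predict_utilization(rec, flags)
        assert pred == "not_supported" and "non-expressed" in why

    def test_inducible_system_rescues_silent_enzymes(self, flags):
        silent = flags.index[~flags["expressed"]][0]
        rec = CompoundMapping("c", ["met"], ["T1"], [silent], inducible=True)
        assert predict_utilization(rec, flags)[0] == "supported"

    def test_unmapped_compound_is_unknown_not_error(self, flags):
        assert predict_utilization(CompoundMapping("c"), flags)[0] == "unknown"

    def test_monotone_in_evidence(self, flags):
        # adding a transporter or an expressed enzyme never flips
        # supported -> not_supported
        order = {"not_supported": 0, "unknown": 0, "supported": 1}
        expressed_locus = flags.index[flags["expressed"]][0]
        silent = flags.index[~flags["expressed"]][0]
        base = CompoundMapping("c", ["met"], [], [silent])
        more_t = CompoundMapping("c", ["met"], ["T1"], [silent])
        more_e = CompoundMapping("c", ["met"], ["T1"], [silent, expressed_locus])
        p0 = predict_utilization(base, flags)[0]
        p1 = predict_utilization(more_t, flags)[0]
        p2 = predict_utilization(more_e, flags)[0]
        assert order[p1] >= order[p0]
        assert order[p2] >= order[p1]

    def test_fixture_predictions_match_growth_classes(
        self, compound_fixture, plate_fixture, flags
    ):
        table, truth = compound_fixture
        _, pm_truth = plate_fixture
        preds = (
            UtilizationPredictor()
            .fit(flags, transporter_annotation=truth.transporter_loci)
            .predict(table)
        )
        by_cond = preds.set_index("condition")["prediction"]
        for cond in truth.mapped_compounds:
            cls = pm_truth.growth_class_by_condition[cond]
            expected = "supported" if cls in ("high", "moderate") else "not_supported"
            assert by_cond[cond] == expected


class TestConcordance:
    def test_perfect_agreement(self):
        preds = pd.DataFrame(
            {"condition": ["a", "b"], "prediction": ["supported", "not_supported"],
             "rationale": ["", ""]}
        )
        calls = pd.DataFrame(
            {"condition": ["a", "b"], "growth_class": ["high", "none"]}
        )
        out = concordance(preds, calls)
        assert out["agreement"] == 1.0 and out["n_mapped"] == 2

    def test_inverted_predictions(self):
        preds = pd.DataFrame(
            {"condition": ["a", "b"], "prediction": ["not_supported", "supported"],
             "rationale": ["", ""]}
        )
        calls = pd.DataFrame(
            {"condition": ["a", "b"], "growth_class": ["high", "none"]}
        )
        assert concordance(preds, calls)["agreement"] == 0.0

    def test_fixture_concordance_high(self, compound_fixture, plate_fixture, flags):
        table, truth = compound_fixture
        plates, _ = plate_fixture
        calls = GrowthClassifier().fit_predict(plates)
        preds = (
            UtilizationPredictor()
            .fit(flags, transporter_annotation=truth.transporter_loci)
            .predict(table)
        )
        out = concordance(preds, calls)
        assert out["n_mapped"] == 135
        assert out["n_unmapped"] == 149
        assert out["agreement"] >= 0.95


class TestCompareSpecies:
    def test_packaged_table_reproduces_printed_totals(self):
        matrix = packaged_mtb_msm_table()
        out = compare_species(matrix, "Msm", "Mtb")
        assert out["common"] == 31
        assert out["unique_a"] + out["unique_b"] == 9

    def test_differential_rows_match_bold_annotations(self):
        matrix = packaged_mtb_msm_table()
        out = compare_species(matrix, "Msm", "Mtb")
        flagged = set(matrix[matrix["differential"]]["source"])
        assert set(out["differential"]["source"]) == flagged

    def test_adenosine_counts_for_neither_species(self):
        matrix = packaged_mtb_msm_table()
        row = matrix[matrix["source"] == "Adenosine"].iloc[0]
        assert row["mtb_call"] == "X" and row["msm_call"] == "X"
        out = compare_species(matrix, "Msm", "Mtb")
        assert "Adenosine" not in set(out["differential"]["source"])

    def test_symmetric_up_to_swapping(self):
        matrix = packaged_mtb_msm_table()
        ab = compare_species(matrix, "Msm", "Mtb")
        ba = compare_species(matrix, "Mtb", "Msm")
        assert ab["common"] == ba["common"]
        assert ab["unique_a"] == ba["unique_b"]
        assert ab["unique_b"] == ba["unique_a"]

    def test_partition_of_usable_rows(self):
        matrix = packaged_mtb_msm_table()
        out = compare_species(matrix, "Msm", "Mtb")
        assert (
            out["common"] + out["unique_a"] + out["unique_b"] + out["both_no_growth"]
            == out["n_usable"]
        )

    def test_identical_columns_have_no_uniques(self):
        matrix = pd.DataFrame(
            {
                "source": ["s1", "s2"],
                "type": ["carbon", "carbon"],
                "a_call": ["Y", "X"],
                "b_call": ["Y", "X"],
            }
        )
        out = compare_species(matrix, "A", "B")
        assert out["unique_a"] == out["unique_b"] == 0

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            compare_species(packaged_mtb_msm_table(), "Msm", "Ecoli")


class TestNetworkOverlay:
    def test_empty_inputs_give_empty_tables(self):
        nodes, edges = network_overlay([], {})
        assert nodes.empty and edges.empty

    def test_expressed_edges_carry_expressed_genes(
        self, pathway_fixture, expression_fixture, compound_fixture
    ):
        expr, _ = expression_fixture
        pathways, _ = pathway_fixture
        table, _ = compound_fixture
        from feaspath.feasibility import PathwayFeasibilityClassifier

        clf = PathwayFeasibilityClassifier().fit(expr)
        calls = clf.decision_calls(pathways)
        nodes, edges = network_overlay(calls, table)
        flags_frame = clf.flags_
        genes = edges.loc[edges["expressed"], "gene"]
        assert all(
            flags_frame.loc[g, "expressed"] or flags_frame.loc[g, "above_median"]
            for g in genes
        )

    def test_pm_flagged_nodes_equal_mapped_count(self, compound_fixture):
        table, _ = compound_fixture
        nodes, _ = network_overlay([], table)
        assert int(nodes["pm_probed"].sum()) == count_mapped(table) == 135

    def test_overlay_graph_round_trip(self, compound_fixture):
        table, _ = compound_fixture
        call = FeasibilityCall("PWY_X", 1.0, "feasible", {1: "g1", 2: "none"})
        nodes, edges = network_overlay([call], table)
        g = overlay_graph(nodes, edges)
        assert g.number_of_nodes() > 0
        assert any(d.get("gene") == "g1" for _u, _v, d in g.edges(data=True))
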