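"""Expression-table parsing, modal tumor category, ordinal differential
flags, and pathway-graph annotation."""

import networkx as nx
import pytest

from bbbsim.overlay import (
    CELL_TYPES,
    OverlayError,
    ParseError,
    ExpressionRecord,
    annotate_network,
    differential_flags,
    load_synthetic_network,
    modal_tumor_category,
    parse_expression_table,
    read_sif,
)

HEADER = ("Class\tProtein\tEndothelial cells\tGlial cells\tNeuronal cells\t"
          "Neuropil\tNot detected\tLow\tMedium\tHigh")


def _table(*rows: str) -> str:
    return "\n".join([HEADER, *rows])


class TestParsing:
    def test_fixture_parses_one_record_per_protein_row(self, expression_records):
        assert len(expression_records) == 73
        symbols = [r.symbol for r in expression_records]
        assert len(set(symbols)) == len(symbols)

    def test_fixture_counts_sum_to_their_denominators(self, expression_records):
        for rec in expression_records:
            if rec.has_tumor_data:
                assert sum(rec.tumor_counts) == rec.n
                assert rec.n in {9, 10, 11, 12}

    def test_mdm2_row(self, records_by_symbol):
        rec = records_by_symbol["MDM2"]
        assert rec.tumor_counts == (0, 0, 0, 12)
        assert rec.n == 12
        assert rec.cortex["endothelial"] == "High"
        assert rec.cortex["neuropil"] == "Not Detected"

    def test_all_na_row_is_flagged_unusable(self, records_by_symbol):
        rec = records_by_symbol["PIK3R2"]
        assert not rec.has_tumor_data
        assert all(rec.cortex[ct] == "N/A" for ct in CELL_TYPES)

    def test_mixed_na_cortex_with_real_tumor_counts(self, records_by_symbol):
        rec = records_by_symbol["BRCA2"]  # cortex annotation unavailable
        assert all(rec.cortex[ct] == "N/A" for ct in CELL_TYPES)
        assert rec.tumor_counts == (2, 2, 7, 1) and rec.n == 12

    def test_question_mark_maps_to_uncertain(self, records_by_symbol):
        assert records_by_symbol["MSH6"].cortex["endothelial"] == "Uncertain"
        assert records_by_symbol["FOXO3"].cortex["neuropil"] == "Uncertain"

    def test_uniform_synthetic_row(self):
        rows = parse_expression_table(
            _table("X\tX\tHigh\tLow\tLow\tLow\t1/4\t1/4\t1/4\t1/4")
        )
        assert rows[0].tumor_counts == (1, 1, 1, 1)
        assert rows[0].n == 4

    def test_class_column_forward_fills(self):
        rows = parse_expression_table(
            _table(
                "AKT\tAKT1\tHigh\tHigh\tHigh\tHigh\t0\t0\t0\t5/5",
                "\tAKT2\tLow\tLow\tLow\tLow\t5/5\t0\t0\t0",
            )
        )
        assert [r.protein_class for r in rows] == ["AKT", "AKT"]

    def test_inconsistent_denominators_name_the_protein(self):
        with pytest.raises(ParseError, match="BADP"):
            parse_expression_table(
                _table("C\tBADP\tHigh\tHigh\tHigh\tHigh\t1/4\t1/5\t0\t0")
            )

    def test_malformed_fraction_reports_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_expression_table(
                _table("C\tP\tHigh\tHigh\tHigh\tHigh\t1//4\t0\t0\t3/4")
            )

    def test_counts_not_summing_to_denominator_rejected(self):
        with pytest.raises(ParseError, match="sum"):
            parse_expression_table(
                _table("C\tP\tHigh\tHigh\tHigh\tHigh\t1/4\t0\t0\t1/4")
            )

    def test_wrong_header_rejected(self):
        with pytest.raises(ParseError, match="header"):
            parse_expression_table("A\tB\tC\nx\ty\tz")


class TestModalCategory:
    def test_egfr_is_high_in_8_of_12(self, records_by_symbol):
        assert modal_tumor_category(records_by_symbol["EGFR"]) == ("High", 8, 12)

    def test_mdm2_is_high_in_12_of_12(self, records_by_symbol):
        assert modal_tumor_category(records_by_symbol["MDM2"]) == ("High", 12, 12)

    def test_four_way_tie_breaks_toward_high(self):
        rec = ExpressionRecord("C", "T", {ct: "Low" for ct in CELL_TYPES},
                               (3, 3, 3, 3), 12)
        assert modal_tumor_category(rec) == ("High", 3, 12)

    def test_unusable_record_raises(self, records_by_symbol):
        with pytest.raises(OverlayError, match="PIK3R2"):
            modal_tumor_category(records_by_symbol["PIK3R2"])

    def test_modal_count_bounds(self, expression_records):
        """count <= n, with equality exactly when every other count is 0."""
        for rec in expression_records:
            if not rec.has_tumor_data:
                continue
            cat, count, n = modal_tumor_category(rec)
            assert count <= n
            assert (count == n) == (sum(rec.tumor_counts) == count)


class TestDifferentialFlags:
    def test_egfr_up_versus_all_cortex_cell_types(self, records_by_symbol):
        flags = differential_flags(records_by_symbol["EGFR"])
        assert all(flags[ct] == "up" for ct in CELL_TYPES)

    def test_identical_categories_flag_same(self):
        rec = ExpressionRecord("C", "T", {ct: "Medium" for ct in CELL_TYPES},
                               (0, 0, 5, 0), 5)
        assert set(differential_flags(rec).values()) == {"same"}

    def test_uncertain_cortex_is_incomparable(self, records_by_symbol):
        assert differential_flags(records_by_symbol["FOXO3"])["neuropil"] == "incomparable"

    def test_na_tumor_is_incomparable_everywhere(self, records_by_symbol):
        flags = differential_flags(records_by_symbol["PIK3CG"])
        assert set(flags.values()) == {"incomparable"}

    @pytest.mark.parametrize(
        ("cortex", "counts", "expected"),
        [("Not Detected", (0, 0, 0, 5), "up"), ("High", (5, 0, 0, 0), "down")],
    )
    def test_flags_antisymmetric_under_ordinal_swap(self, cortex, counts, expected):
        rec = ExpressionRecord("C", "T", {ct: cortex for ct in CELL_TYPES}, counts, 5)
        flags = differential_flags(rec)
        assert set(flags.values()) == {expected}


class TestAnnotation:
    def test_mdm2_tumor_pie_is_all_high(self, expression_records):
        net = load_synthetic_network()
        ann = annotate_network(net, expression_records, mode="tumor")
        d = ann.nodes["MDM2"]
        assert (d["pie_not_detected"], d["pie_low"], d["pie_medium"], d["pie_high"]) \
            == (0.0, 0.0, 0.0, 1.0)

    def test_pie_fractions_sum_to_one_for_matched_nodes(self, expression_records):
        ann = annotate_network(load_synthetic_network(), expression_records,
                               mode="tumor")
        for _, d in ann.nodes(data=True):
            if d.get("expression_available"):
                total = (d["pie_not_detected"] + d["pie_low"] + d["pie_medium"]
                         + d["pie_high"])
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_unmatched_node_gets_not_available_color(self, expression_records):
        ann = annotate_network(load_synthetic_network(), expression_records,
                               mode="cortex")
        d = ann.nodes["UNKNOWN1"]
        assert not d["expression_available"]
        assert {d[f"quarter_{i}_color"] for i in (1, 2, 3, 4)} == {"olive"}

    def test_quarter_colors_follow_the_legend(self, expression_records):
        ann = annotate_network(load_synthetic_network(), expression_records,
                               mode="cortex")
        d = ann.nodes["MDM2"]  # High/High/High cortex, Not Detected neuropil
        assert d["color_endothelial"] == "deep pink"
        assert d["color_neuropil"] == "deep sky blue"
        assert d["quarter_1_color"] == d["color_endothelial"]  # clockwise order
        assert d["quarter_2_color"] == d["color_neuropil"]

    def test_symbol_matching_is_case_insensitive(self, expression_records):
        g = nx.Graph()
        g.add_node("x", symbol="mdm2")
        ann = annotate_network(g, expression_records, mode="tumor")
        assert ann.nodes["x"]["pie_high"] == 1.0

    def test_annotation_is_idempotent(self, expression_records):
        net = load_synthetic_network()
        once = annotate_network(net, expression_records, mode="cortex")
        twice = annotate_network(once, expression_records, mode="cortex")
        assert dict(once.nodes(data=True)) == dict(twice.nodes(data=True))

    def test_annotations_round_trip_through_graphml(self, tmp_path, expression_records):
        ann = annotate_network(load_synthetic_network(), expression_records,
                               mode="cortex")
        path = tmp_path / "annotated.graphml"
        nx.write_graphml(ann, path)
        back = nx.read_graphml(path)
        assert dict(back.nodes(data=True)) == dict(ann.nodes(data=True))

    def test_duplicate_symbols_rejected(self, expression_records):
        with pytest.raises(OverlayError, match="duplicate"):
            annotate_network(load_synthetic_network(),
                             expression_records + [expression_records[0]])

    def test_node_without_symbol_rejected(self, expression_records):
        g = nx.Graph()
        g.add_node("anonymous")
        with pytest.raises(OverlayError, match="symbol"):
            annotate_network(g, expression_records)


def test_read_sif(tmp_path):
    p = tmp_path / "edges.sif"
    p.write_text("EGFR\tactivates\tPIK3CA\tAKT1\nPTEN\tinhibits\tAKT1\nLONER\n")
    g = read_sif(p)
    assert set(g.nodes) == {"EGFR", "PIK3CA", "AKT1", "PTEN", "LONER"}
    assert g.edges["EGFR", "AKT1"]["relationship"] == "activates"
    assert g.nodes["LONER"]["symbol"] == "LONER"
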