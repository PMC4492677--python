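"""Tests of the tabular readers and the fold-change computations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfcoherence import (
    CategoryMap,
    ExpressionMatrix,
    category_percentages,
    classify_fold_changes,
    genome_fraction_altered,
    heat_values,
    read_categories,
    read_connectivity,
    read_expression,
)
from tfcoherence.foldchange import classify_direction


def make_expression(ratios, times=(10, 20, 40, 60, 120), genes=None):
    """Expression matrix holding the given ratio-scale fold changes."""
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    genes = genes or [f"g{i}" for i in range(ratios.shape[0])]
    return ExpressionMatrix(
        gene_ids=genes,
        time_points_min=list(times)[: ratios.shape[1]],
        values=np.log2(ratios),
    )


class TestReaders:
    def test_expression_fixture_round_trip(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tt10\tt20\tt40\tt60\tt120\n"
                     "gA\t0.5\t1.0\t-2.0\t0\t3.25\n"
                     "gB\t0\t0\t0\t0\t0\n"
                     "gC\t-1\t2\t1.5\t0.25\t-0.125\n")
        m = read_expression(p)
        assert m.gene_ids == ["gA", "gB", "gC"]
        assert m.time_points_min == [10, 20, 40, 60, 120]
        assert m.values[0, 4] == 3.25

    def test_missing_cell_drops_gene_and_logs(self, tmp_path, caplog):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tt10\tt20\ngA\t0.5\t\ngB\t1\t2\n")
        with caplog.at_level("INFO", logger="tfcoherence.io"):
            m = read_expression(p)
        assert m.gene_ids == ["gB"]
        assert "1 gene(s) removed" in caplog.text

    def test_duplicate_gene_id_is_error(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tt10\ngA\t0.5\ngA\t1.0\n")
        with pytest.raises(ValueError, match="gA"):
            read_expression(p)

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tt10\tt20\ngA\t0.5\tbogus\n")
        with pytest.raises(ValueError, match="bogus.*gA.*t20"):
            read_expression(p)

    def test_connectivity_edges_to_matrix(self, tmp_path):
        p = tmp_path / "conn.tsv"
        p.write_text("tf\tgene\nFur\tfepA\nFur\tentA\n")
        conn = read_connectivity(p)
        assert conn.tf_names == ["Fur"]
        assert conn.gene_ids == ["entA", "fepA"]
        assert (conn.entries == 1).all()

    def test_duplicate_edge_collapsed_with_warning(self, tmp_path, caplog):
        p = tmp_path / "conn.tsv"
        p.write_text("tf\tgene\nFur\tfepA\nFur\tfepA\nFur\tentA\n")
        with caplog.at_level("WARNING", logger="tfcoherence.io"):
            conn = read_connectivity(p)
        assert conn.entries.sum() == 2
        assert "duplicated edge" in caplog.text

    def test_empty_connectivity_is_error(self, tmp_path):
        p = tmp_path / "conn.tsv"
        p.write_text("tf\tgene\n")
        with pytest.raises(ValueError, match="empty"):
            read_connectivity(p)

    def test_malformed_connectivity_line_numbered(self, tmp_path):
        p = tmp_path / "conn.tsv"
        p.write_text("tf\tgene\nFur\tfepA\n\tentA\n")
        with pytest.raises(ValueError, match="line 3"):
            read_connectivity(p)

    def test_category_lookup(self, tmp_path):
        p = tmp_path / "cats.tsv"
        p.write_text("gene\tcategory\n"
                     "entA\tiron transport and acquisition\n"
                     "entB\tiron transport and acquisition\n"
                     "spy\tstress response\n")
        cats = read_categories(p)
        assert cats["entA"] == "iron transport and acquisition"
        assert cats.get("unknown") is None

    def test_multi_category_gene_keeps_first(self, tmp_path, caplog):
        p = tmp_path / "cats.tsv"
        p.write_text("gene\tcategory\ngA\tfirst\ngA\tsecond\n")
        with caplog.at_level("WARNING", logger="tfcoherence.io"):
            cats = read_categories(p)
        assert cats["gA"] == "first"
        assert cats.multi_category_genes == ["gA"]


class TestClassification:
    def test_boundaries_inclusive(self):
        table = classify_fold_changes(make_expression([[2.0, 0.5, 1.9, 0.51, 1.0]]))
        assert list(table["direction"]) == ["up", "down", "unchanged", "unchanged",
                                            "unchanged"]

    def test_extreme_upregulation_is_up(self):
        # a spy-like 600-fold induction
        table = classify_fold_changes(make_expression([[600.0, 1000.0, 80.0]]))
        assert (table["direction"] == "up").all()

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6,
                              allow_nan=False), min_size=1, max_size=30))
    def test_classification_partitions_all_records(self, ratios):
        direction = classify_direction(np.asarray(ratios))
        n_up = (direction == "up").sum()
        n_down = (direction == "down").sum()
        n_unchanged = (direction == "unchanged").sum()
        assert n_up + n_down + n_unchanged == len(ratios)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False),
           st.floats(min_value=1.0, max_value=100.0))
    def test_increasing_fold_change_never_demotes(self, fc, factor):
        order = {"down": 0, "unchanged": 1, "up": 2}
        lo = classify_direction(np.array([fc]))[0]
        hi = classify_direction(np.array([fc * factor]))[0]
        assert order[hi] >= order[lo]


class TestCategorySummaries:
    def test_six_of_ten_up_is_sixty_percent(self):
        # mirrors the iron-gene pattern: ~60% of the category up at 10 min
        ratios = [[3.0]] * 6 + [[1.0]] * 4
        expr = make_expression(np.array(ratios).reshape(10, 1), times=(10,))
        cats = CategoryMap({f"g{i}": "iron transport and acquisition"
                            for i in range(10)})
        table = classify_fold_changes(expr, cats)
        out = category_percentages(table)
        row = out.iloc[0]
        assert row["pct_up"] == 60.0
        assert row["pct_down"] == 0.0

    def test_nothing_altered_gives_zero_percent(self):
        expr = make_expression(np.ones((5, 2)), times=(10, 20))
        cats = CategoryMap({f"g{i}": "c" for i in range(5)})
        out = category_percentages(classify_fold_changes(expr, cats))
        assert (out["pct_up"] == 0).all() and (out["pct_down"] == 0).all()

    def test_all_up_partition_bound(self):
        expr = make_expression(np.full((4, 1), 8.0), times=(10,))
        cats = CategoryMap({f"g{i}": "c" for i in range(4)})
        out = category_percentages(classify_fold_changes(expr, cats))
        assert out.iloc[0]["pct_up"] == 100.0
        assert out.iloc[0]["pct_down"] == 0.0

    def test_uncategorised_genes_excluded_and_counts_consistent(self):
        ratios = np.array([[4.0], [4.0], [0.25], [1.0]])
        expr = make_expression(ratios, times=(10,))
        cats = CategoryMap({"g0": "a", "g1": "a", "g2": "a"})  # g3 unmapped
        table = classify_fold_changes(expr, cats)
        out = category_percentages(table)
        # summed category counts equal classification counts on mapped genes
        mapped = table[table["category"].notna()]
        assert out.iloc[0]["pct_up"] * 3 / 100 == (mapped["direction"] == "up").sum()
        assert set(out["category"]) == {"a"}

    def test_empty_category_absent_not_zero(self):
        expr = make_expression(np.ones((2, 1)), times=(10,))
        cats = CategoryMap({"g0": "a", "g1": "a", "orphan": "b"})
        out = category_percentages(classify_fold_changes(expr, cats))
        assert "b" not in set(out["category"])


class TestGenomeFraction:
    def test_planted_counts_give_printed_percentages(self):
        # 57 up and 144 down out of a 1,000-gene genome -> 5.7% / 14.4%
        ratios = np.concatenate([np.full(57, 4.0), np.full(144, 0.25),
                                 np.full(99, 1.0)])
        expr = make_expression(ratios.reshape(-1, 1), times=(120,))
        out = genome_fraction_altered(classify_fold_changes(expr), genome_size=1000)
        assert out.iloc[0]["pct_up"] == pytest.approx(5.7)
        assert out.iloc[0]["pct_down"] == pytest.approx(14.4)

    def test_simple_fraction(self):
        ratios = np.full(100, 4.0)
        expr = make_expression(ratios.reshape(-1, 1), times=(10,))
        out = genome_fraction_altered(classify_fold_changes(expr), genome_size=1000)
        assert out.iloc[0]["pct_up"] == 10.0

    def test_empty_table_gives_empty_summary(self):
        table = pd.DataFrame(columns=["gene", "time_min", "fold_change", "direction"])
        out = genome_fraction_altered(table, genome_size=100)
        assert out.empty

    def test_genome_smaller_than_observed_rejected(self):
        expr = make_expression(np.ones((5, 1)), times=(10,))
        with pytest.raises(ValueError, match="genome_size"):
            genome_fraction_altered(classify_fold_changes(expr), genome_size=3)


class TestHeatValues:
    def test_ln_identities(self):
        expr = make_expression([[1.0, math.e, 80.0]], times=(10, 20, 40))
        heat = heat_values(classify_fold_changes(expr))
        assert heat.iloc[0, 0] == 0.0
        assert heat.iloc[0, 1] == pytest.approx(1.0)
        assert heat.iloc[0, 2] == pytest.approx(math.log(80.0), abs=1e-12)
        assert heat.iloc[0, 2] == pytest.approx(4.382, abs=5e-4)

    def test_downregulation_negative_unchanged_bounded(self):
        expr = make_expression([[0.25, 1.5]], times=(10, 20))
        heat = heat_values(classify_fold_changes(expr))
        assert heat.iloc[0, 0] < 0
        assert math.log(0.5) < heat.iloc[0, 1] < math.log(2.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=1e-4, max_value=1e4, allow_nan=False))
    def test_heat_antisymmetric_in_reciprocal(self, fc):
        expr = make_expression([[fc, 1.0 / fc]], times=(10, 20))
        heat = heat_values(classify_fold_changes(expr))
        assert heat.iloc[0, 0] == pytest.approx(-heat.iloc[0, 1], rel=1e-9, abs=1e-12)

    def test_strictly_increasing_in_fold_change(self):
        fcs = np.array([[0.1, 0.5, 1.0, 2.0, 10.0]])
        expr = make_expression(fcs)
        heat = heat_values(classify_fold_changes(expr))
        assert (np.diff(heat.to_numpy()[0]) > 0).all()

    def test_nonpositive_fold_change_rejected(self):
        table = pd.DataFrame({"gene": ["g0"], "time_min": [10.0],
                              "fold_change": [0.0], "direction": ["down"]})
        with pytest.raises(ValueError, match="nonpositive"):
            heat_values(table)
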