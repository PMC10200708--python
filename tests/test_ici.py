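import numpy as np
import pandas as pd
import pytest

import apexmap as am
from apexmap.ici import _expression_matrix, category_counts, ici_scores, permutation_null


@pytest.fixture
def two_markers():
    return am.MarkerSet("adaxial", ["g1", "g2"], [1.0, 0.5])


class TestComputeIci:
    def test_single_expressed_marker(self, two_markers):
        e = pd.Series({"g1": 2.0, "g2": 0.0})
        assert am.compute_ici(e, two_markers) == pytest.approx(1.0)

    def test_both_markers_expressed(self, two_markers):
        e = pd.Series({"g1": 2.0, "g2": 4.0})
        assert am.compute_ici(e, two_markers) == pytest.approx(2.0)

    def test_no_expressed_markers_gives_zero(self, two_markers):
        assert am.compute_ici(pd.Series({"g1": 0.0, "g2": 0.0}), two_markers) == 0.0

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            am.compute_ici(
                pd.Series({"g1": 1.0}),
                am.MarkerSet("adaxial", np.array([]), np.array([])),
            )

    def test_alternative_formula_penalizes_dropout(self, two_markers):
        e = pd.Series({"g1": 2.0, "g2": 0.0})
        assert am.compute_ici(e, two_markers, formula="alternative") == pytest.approx(0.5)

    def test_marker_order_invariance(self):
        e = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        m1 = am.MarkerSet("t", ["a", "b", "c"], [0.9, 0.5, 0.2])
        m2 = am.MarkerSet("t", ["c", "a", "b"], [0.2, 0.9, 0.5])
        assert am.compute_ici(e, m1) == pytest.approx(am.compute_ici(e, m2))

    def test_uniform_rescaling_scales_ici_linearly(self, two_markers):
        e = pd.Series({"g1": 2.0, "g2": 4.0})
        base = am.compute_ici(e, two_markers)
        assert am.compute_ici(e * 7.0, two_markers) == pytest.approx(7.0 * base)


class TestPermutationNull:
    def _setup(self, n_genes=50, n_cells=20, seed=5):
        rng = np.random.default_rng(seed)
        expr = rng.poisson(2.0, size=(n_genes, n_cells)).astype(float)
        gene_ids = np.array([f"G{i}" for i in range(n_genes)], dtype=object)
        s = {"adaxial": rng.uniform(-1, 1, n_genes),
             "abaxial": rng.uniform(-1, 1, n_genes)}
        return expr, gene_ids, s

    def test_same_seed_identical_null(self):
        expr, genes, s = self._setup()
        params = am.IciParams(n_permutations=20, seed=9)
        n1 = permutation_null(expr, genes, {"adaxial": 5, "abaxial": 7}, s, params)
        n2 = permutation_null(expr, genes, {"adaxial": 5, "abaxial": 7}, s, params)
        assert np.array_equal(n1["adaxial"], n2["adaxial"])
        assert np.array_equal(n1["abaxial"], n2["abaxial"])

    def test_forced_draw_equals_experimental_ici(self):
        expr, genes, s = self._setup()
        params = am.IciParams(n_permutations=1, seed=3)
        null = permutation_null(expr, genes, {"adaxial": 6}, s, params)
        # replicate the single internal draw and score it as a marker set
        rng = np.random.default_rng(3)
        idx = rng.choice(len(genes), size=6, replace=False)
        expected = (s["adaxial"][idx] @ expr[idx, :]) / 6
        assert np.allclose(null["adaxial"][0], expected)

    def test_oversized_marker_set_rejected(self):
        expr, genes, s = self._setup()
        with pytest.raises(ValueError, match="exceeds"):
            permutation_null(expr, genes, {"adaxial": 51}, s, am.IciParams())


class TestAssignIdentity:
    def _nulls(self, n_cells=4, n_perm=100, scale=1.0, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, scale, size=(n_perm, n_cells))

    def test_decision_rule(self):
        nulls = {"adaxial": self._nulls(), "abaxial": self._nulls(seed=1)}
        high, low = 5.0, -5.0
        ici = {
            "adaxial": np.array([high, low, high, low]),
            "abaxial": np.array([low, high, high, low]),
        }
        table, _ = am.assign_identity(ici, nulls, am.IciParams())
        assert list(table["category"]) == ["adaxial", "abaxial", "mixed", "none"]

    def test_value_just_above_null_max_is_significant_for_both(self):
        nulls = {"adaxial": self._nulls(), "abaxial": self._nulls(seed=2)}
        ici = {t: np.full(4, nulls[t].max() + 1e-9) for t in nulls}
        table, _ = am.assign_identity(ici, nulls, am.IciParams())
        assert (table["category"] == "mixed").all()

    def test_merge_none_into_mixed(self):
        nulls = {"adaxial": self._nulls(), "abaxial": self._nulls(seed=3)}
        ici = {t: np.full(4, -10.0) for t in nulls}
        table, _ = am.assign_identity(
            ici, nulls, am.IciParams(merge_none_into_mixed=True)
        )
        assert (table["category"] == "mixed").all()


class TestPipeline:
    def test_mixed_blend_population_called_mixed(self, default_experiment, marker_sets):
        _, ref, matrix, _, truth = default_experiment
        params = am.IciParams(n_permutations=200, seed=21)
        result = am.ici_pipeline(matrix, marker_sets, ref, params)
        merged = result.table.merge(truth.cells, on="barcode")
        blend = merged[merged["identity"] == "mixed"]
        assert (blend["category"] == "mixed").mean() > 0.5

    def test_subset_definitions_and_counts(self, default_experiment, marker_sets):
        _, ref, matrix, _, truth = default_experiment
        params = am.IciParams(n_permutations=50, seed=22)
        barcode_subset = truth.cells["barcode"].iloc[:10].tolist()
        result = am.ici_pipeline(
            matrix, marker_sets, ref, params,
            subsets={"first10": {"barcodes": barcode_subset}},
        )
        row = result.category_counts.set_index("subset").loc["first10"]
        assert row["n_cells"] == 10

    def test_empty_subset_yields_zero_row(self):
        table = pd.DataFrame({"category": ["adaxial", "mixed"]})
        counts = category_counts(table, {"empty": np.zeros(2, dtype=bool)})
        row = counts.set_index("subset").loc["empty"]
        assert row["n_cells"] == 0 and row["adaxial"] == 0

    def test_scale_free_significance(self, default_experiment, marker_sets):
        # scaling every cell's expression by a constant rescales experimental
        # and null ICI together, so significance calls are unchanged
        _, ref, matrix, _, _ = default_experiment
        params = am.IciParams(n_permutations=50, seed=4, expression_source="raw")
        expr = _expression_matrix(matrix, params)
        sizes = {t: len(marker_sets[t]) for t in marker_sets}
        s = {t: ref.specificity(t).reindex(matrix.genes, fill_value=0).to_numpy()
             for t in marker_sets}
        ici1 = ici_scores(expr, matrix.genes, marker_sets["adaxial"])
        null1 = permutation_null(expr, matrix.genes, sizes, s, params)["adaxial"]
        ici2 = ici_scores(expr * 3.0, matrix.genes, marker_sets["adaxial"])
        null2 = permutation_null(expr * 3.0, matrix.genes, sizes, s, params)["adaxial"]
        assert np.allclose(ici2, 3.0 * ici1)
        sig1 = ici1 > np.percentile(null1, 95)
        sig2 = ici2 > np.percentile(null2, 95)
        assert np.array_equal(sig1, sig2)
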