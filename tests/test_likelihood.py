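import numpy as np
import pandas as pd
import pytest

import apexmap as am
from apexmap.likelihood import _sym_laplacian


class TestKnnGraph:
    def test_collinear_points_symmetrized(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        w = am.build_knn_graph(coords, knn=1, kernel="binary")
        assert w[1, 0] > 0 and w[1, 2] > 0  # middle connects to both
        assert w[0, 2] == 0

    def test_adjacency_exactly_symmetric(self):
        rng = np.random.default_rng(0)
        w = am.build_knn_graph(rng.normal(size=(40, 3)), knn=5)
        assert (w != w.T).nnz == 0

    def test_binary_full_knn_gives_complete_graph(self):
        rng = np.random.default_rng(1)
        n = 10
        w = am.build_knn_graph(rng.normal(size=(n, 3)), knn=n - 1, kernel="binary")
        assert w.nnz == n * (n - 1)

    def test_knn_at_least_n_rejected(self):
        with pytest.raises(ValueError, match="knn"):
            am.build_knn_graph(np.zeros((3, 2)), knn=3)

    def test_duplicate_points_handled(self):
        coords = np.array([[0.0, 0], [0.0, 0], [1.0, 0], [2.0, 0]])
        w = am.build_knn_graph(coords, knn=2)
        assert np.isfinite(w.toarray()).all()


class TestSmoother:
    def test_beta_zero_returns_indicator(self):
        rng = np.random.default_rng(2)
        w = am.build_knn_graph(rng.normal(size=(20, 3)), knn=3)
        ind = (rng.random(20) < 0.5).astype(float)
        assert np.array_equal(am.smooth_sample_density(w, ind, 0.0), ind)

    def test_large_beta_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        w = am.build_knn_graph(rng.normal(size=(25, 3)), knn=4)
        lap = _sym_laplacian(w).toarray()
        lam, vecs = np.linalg.eigh(lap)
        ind = (rng.random(25) < 0.4).astype(float)
        for beta in (1.0, 10.0, 1e8):
            oracle = vecs @ ((vecs.T @ ind) / (1.0 + beta * lam))
            dens = am.smooth_sample_density(w, ind, beta)
            assert np.allclose(dens, np.clip(oracle, 0, None), atol=1e-6)
        # in the large-beta limit the density collapses onto the Laplacian
        # nullspace (constant up to the degree weighting)
        v0 = vecs[:, 0]
        limit = (v0 @ ind) * v0
        assert np.allclose(
            am.smooth_sample_density(w, ind, 1e8), np.clip(limit, 0, None),
            atol=1e-6,
        )

    def test_smoother_is_linear(self):
        rng = np.random.default_rng(4)
        w = am.build_knn_graph(rng.normal(size=(15, 3)), knn=3)
        ind = rng.random(15)
        d1 = am.smooth_sample_density(w, ind, 5.0)
        d2 = am.smooth_sample_density(w, 2.0 * ind, 5.0)
        assert np.allclose(d2, 2.0 * d1)


class TestRelativeLikelihood:
    def test_equal_densities_give_half(self):
        f = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(am.relative_likelihood(f, f), np.full(3, 0.5))

    def test_zero_other_density_gives_one(self):
        f = np.array([1.0, 1.0])
        o = np.array([0.0, 2.0])
        assert am.relative_likelihood(f, o)[0] == 1.0

    def test_sample_size_scaling_invariance(self):
        # doubling a sample's cell count doubles its raw density signal;
        # per-sample normalization removes the factor exactly
        rng = np.random.default_rng(5)
        f, o = rng.random(30) + 0.1, rng.random(30) + 0.1
        assert np.array_equal(
            am.relative_likelihood(f, o), am.relative_likelihood(f, 2.0 * o)
        )

    def test_focal_swap_complements_exactly(self):
        rng = np.random.default_rng(6)
        f, o = rng.random(100) + 0.01, rng.random(100) + 0.01
        assert np.array_equal(
            am.relative_likelihood(f, o), 1.0 - am.relative_likelihood(o, f)
        )

    def test_likelihoods_of_both_samples_sum_to_one(self):
        rng = np.random.default_rng(7)
        f, o = rng.random(50), rng.random(50)
        total = am.relative_likelihood(f, o) + am.relative_likelihood(o, f)
        assert np.array_equal(total, np.ones(50))


class TestClassify:
    def test_all_equal_all_unaffected(self):
        assert (am.classify_cells(np.full(10, 0.5)) == "unaffected").all()

    def test_outlier_enriched(self):
        x = np.concatenate([np.zeros(50), [0.0001], [10.0]])
        assert am.classify_cells(x)[-1] == "enriched"

    def test_exact_two_sigma_boundary_unaffected(self):
        # mean 0, sd 1 exactly; values at +-2 sit on the boundary
        x = np.array([2.0, -2.0, 0, 0, 0, 0, 0, 0])
        assert x.mean() == 0.0 and x.std() == 1.0
        assert (am.classify_cells(x) == "unaffected").all()

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError):
            am.classify_cells(np.array([0.5]))


class TestAnalysis:
    def test_symmetric_design_centres_on_half(self, default_experiment):
        # no depletion anywhere: likelihood should hover around 0.5
        _, _, _, meta, _ = default_experiment
        res = am.sample_likelihood_analysis(meta, "mut", am.GraphParams(knn=8, beta=10))
        own = res[res["cell_replicate"] == res["likelihood_replicate"]]
        assert abs(own["likelihood"].mean() - 0.5) < 0.05
        assert (own["category"] == "unaffected").mean() > 0.9

    def test_swapping_focal_sample_complements_likelihood(self, default_experiment):
        _, _, _, meta, _ = default_experiment
        p = am.GraphParams(knn=6, beta=5)
        mut = am.sample_likelihood_analysis(meta, "mut", p)
        wt = am.sample_likelihood_analysis(meta, "wt", p)
        assert np.array_equal(
            mut["likelihood"].to_numpy(), 1.0 - wt["likelihood"].to_numpy()
        )


class TestClusterFractions:
    def _result(self, cats, reps=None):
        n = len(cats)
        reps = reps or [1] * n
        return pd.DataFrame({
            "barcode": [f"C{i}" for i in range(n)],
            "cell_replicate": reps,
            "likelihood_replicate": reps,
            "category": cats,
        })

    def test_fraction_arithmetic(self):
        res = self._result(["depleted"] * 4 + ["unaffected"] * 6)
        clusters = {f"C{i}": 0 for i in range(10)}
        fr = am.cluster_fractions(res, clusters)
        row = fr.iloc[0]
        assert (row["frac_depleted"], row["frac_unaffected"], row["frac_enriched"]) == (
            0.4, 0.6, 0.0
        )

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        cats = rng.choice(["depleted", "unaffected", "enriched"], size=60)
        res = self._result(list(cats), reps=list(rng.choice([1, 2], 60)))
        clusters = {f"C{i}": i % 3 for i in range(60)}
        fr = am.cluster_fractions(res, clusters)
        sums = fr[["frac_depleted", "frac_unaffected", "frac_enriched"]].sum(axis=1)
        assert np.allclose(sums, 1.0)


class TestParameterSearch:
    def _data(self, n=60, seed=9):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(n, 3))
        labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        return coords, labels

    def test_argmin_contract_and_determinism(self):
        coords, labels = self._data()
        args = dict(knn_grid=[2, 5], beta_grid=[1.0, 10.0],
                    n_label_permutations=5, seed=1)
        (k, b), surf = am.parameter_search(coords, labels, "a", **args)
        assert ((surf["knn"] == k) & (surf["beta"] == b)).any()
        assert surf["mse"].min() == surf.set_index(["knn", "beta"]).loc[(k, b), "mse"]
        (k2, b2), surf2 = am.parameter_search(coords, labels, "a", **args)
        assert (k, b) == (k2, b2) and surf.equals(surf2)

    def test_oversized_knn_skipped_with_warning(self):
        coords, labels = self._data(n=10)
        with pytest.warns(UserWarning, match="skipping knn"):
            _, surf = am.parameter_search(
                coords, labels, "a", [2, 50], [1.0], n_label_permutations=2, seed=0
            )
        assert set(surf["knn"]) == {2}

    def test_all_knn_oversized_rejected(self):
        coords, labels = self._data(n=5)
        with pytest.raises(ValueError, match="every knn"), pytest.warns(UserWarning):
            am.parameter_search(coords, labels, "a", [10], [1.0],
                                n_label_permutations=2, seed=0)
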