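import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import pare
from pare.embedding import _EMBEDDERS, available_embedders


class TestTsneAffinities:
    def test_equilateral_points_give_uniform_affinities(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]])
        A = pare.tsne_affinities(pare.pairwise_distances(pts), perplexity=2)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(A.values[off], 1.0 / 6.0, atol=1e-12)

    def test_conditional_entropies_match_perplexity(self, rng):
        y = rng.normal(size=(10, 3))
        D = pare.pairwise_distances(y)
        perp = 4.0
        A = pare.tsne_affinities(D, perplexity=perp)
        d2 = D.values**2
        for i in range(10):
            mask = np.arange(10) != i
            w = np.exp(-d2[i, mask] / (2 * A.bandwidths[i] ** 2))
            p = w / w.sum()
            h = -(p * np.log2(p)).sum()
            assert abs(h - np.log2(perp)) < 1e-5

    def test_symmetrized_matrix_sums_to_one(self, rng):
        D = pare.pairwise_distances(rng.normal(size=(14, 4)))
        A = pare.tsne_affinities(D, perplexity=6)
        assert A.values.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(A.values, A.values.T, atol=1e-15)
        assert np.all(np.diag(A.values) == 0)

    def test_scale_invariance(self, rng):
        y = rng.normal(size=(11, 3))
        D1 = pare.pairwise_distances(y)
        D2 = pare.DissimilarityMatrix(D1.values * 7.3)
        A1 = pare.tsne_affinities(D1, perplexity=5)
        A2 = pare.tsne_affinities(D2, perplexity=5)
        assert np.abs(A1.values - A2.values).max() < 1e-8

    def test_perplexity_bounds_enforced(self, rng):
        D = pare.pairwise_distances(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="perplexity"):
            pare.tsne_affinities(D, perplexity=5)
        with pytest.raises(ValueError, match="perplexity"):
            pare.tsne_affinities(D, perplexity=1.0)

    def test_infeasible_perplexity_names_sample(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]])
        D = pare.pairwise_distances(pts, sample_ids=["a", "b", "c"])
        with pytest.raises(ValueError, match="infeasible for sample '[abc]'"):
            pare.tsne_affinities(D, perplexity=1.5)


class TestUmapAffinities:
    def test_nearest_neighbor_membership_is_one(self, rng):
        D = pare.pairwise_distances(rng.normal(size=(12, 4)))
        k = 5
        V = pare.umap_affinities(D, n_neighbors=k)
        # recompute directed memberships from the stored bandwidths
        for i in range(12):
            rho, tau = V.bandwidths[i]
            j = np.argmin(np.where(np.arange(12) == i, np.inf, D.values[i]))
            assert math.exp(-(D.values[i, j] - rho) / tau) == pytest.approx(1.0)

    def test_symmetry_of_fuzzy_union(self, rng):
        D = pare.pairwise_distances(rng.normal(size=(15, 3)))
        V = pare.umap_affinities(D, n_neighbors=6)
        np.testing.assert_allclose(V.values, V.values.T, atol=1e-15)
        assert V.values.min() >= 0.0 and V.values.max() <= 1.0
        assert np.all(np.diag(V.values) == 0)

    def test_per_row_calibration_sum(self, rng):
        y = rng.normal(size=(12, 3))
        D = pare.pairwise_distances(y)
        k = 5
        V = pare.umap_affinities(D, n_neighbors=k)
        for i in range(12):
            order = np.argsort(np.where(np.arange(12) == i, np.inf, D.values[i]))
            nbrs = order[:k]
            rho, tau = V.bandwidths[i]
            s = np.exp(-(D.values[i, nbrs] - rho) / tau).sum()
            assert abs(s - np.log2(k)) < 1e-5

    def test_neighbor_bounds_enforced(self, rng):
        D = pare.pairwise_distances(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError, match="n_neighbors"):
            pare.umap_affinities(D, n_neighbors=6)

    def test_gram_mode_is_distinct_but_valid(self, small_data):
        y, meta = small_data
        G = pare.double_center(pare.pairwise_distances(y))
        H = pare.hat_matrix(pare.build_design(meta, ["batch"]))
        delta = pare.adjusted_gram(G, H)
        Vd = pare.adjusted_umap_affinities(delta, n_neighbors=5, mode="distance")
        Vg = pare.adjusted_umap_affinities(delta, n_neighbors=5, mode="gram")
        for V in (Vd, Vg):
            np.testing.assert_allclose(V.values, V.values.T, atol=1e-15)
            assert V.values.min() >= 0.0 and V.values.max() <= 1.0
        # the literal Gram-entry kernel ranks neighbors differently in general
        assert not np.allclose(Vd.values, Vg.values)


class TestPareInput:
    def test_empty_design_preserves_original_distances(self, small_data):
        y, _ = small_data
        prep = pare.pare_input(y, design=None)
        got = squareform(pdist(prep.coords))
        want = squareform(pdist(y))
        assert np.abs(got - want).max() < 1e-8

    def test_batch_shift_annihilated(self, shifted_batches):
        ds = shifted_batches(batch_effect=10.0)
        X = pare.build_design(ds.metadata, ["batch"])
        prep = pare.pare_input(ds.features, X)
        got = squareform(pdist(prep.coords))
        # oracle: distances of the gamma-free data after the same adjustment
        free = ds.batch_free_features()
        prep_free = pare.pare_input(free, X)
        want = squareform(pdist(prep_free.coords))
        assert np.abs(got - want).max() < 1e-6

    def test_full_rank_truncation_is_identity(self, small_data):
        y, meta = small_data
        X = pare.build_design(meta, ["batch"])
        full = pare.pare_input(y, X)
        capped = pare.pare_input(y, X, n_coords=full.k)
        d1 = squareform(pdist(full.coords))
        d2 = squareform(pdist(capped.coords))
        assert np.abs(d1 - d2).max() < 1e-10

    def test_truncation_error_monotone_in_k(self, small_data):
        y, meta = small_data
        X = pare.build_design(meta, ["batch"])
        full = pare.pare_input(y, X)
        ref = squareform(pdist(full.coords))
        errs = []
        for k in range(1, full.k + 1):
            dk = squareform(pdist(pare.pare_input(y, X, n_coords=k).coords))
            errs.append(np.linalg.norm(dk - ref))
        assert all(e1 >= e2 - 1e-10 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] < 1e-10

    def test_general_path_matches_euclidean_path(self, small_data):
        y, meta = small_data
        X = pare.build_design(meta, ["batch", "age"])
        e_path = pare.pare_input(y, X)
        d_path = pare.pare_input(pare.pairwise_distances(y), X)
        want = squareform(pdist(e_path.coords))
        assert np.abs(d_path.values - want).max() < 1e-8

    def test_affinity_equivalence_of_both_routes(self):
        # adjusted coordinates vs adjusted distance matrix give the same kernels
        rng = np.random.default_rng(5)
        y = rng.normal(size=(30, 6))
        meta = pd.DataFrame({"b": ["x"] * 15 + ["y"] * 15},
                            index=[f"s{i}" for i in range(30)])
        X = pare.build_design(meta, ["b"])
        E = pare.pare_input(y, X)
        Dadj = pare.pare_input(pare.pairwise_distances(y), X)
        A1 = pare.tsne_affinities(pare.pairwise_distances(E.coords), perplexity=8)
        A2 = pare.tsne_affinities(Dadj, perplexity=8)
        assert np.abs(A1.values - A2.values).max() < 1e-8
        V1 = pare.umap_affinities(pare.pairwise_distances(E.coords), n_neighbors=6)
        V2 = pare.umap_affinities(Dadj, n_neighbors=6)
        assert np.abs(V1.values - V2.values).max() < 1e-8


class TestEmbedderRegistry:
    def test_builtins_present(self):
        assert {"tsne", "umap", "pcoa"} <= set(available_embedders())

    def test_duplicate_registration_rejected(self):
        with pytest.raises(ValueError, match="already registered"):
            pare.register_embedder("tsne", lambda x, d, s: x)

    def test_unknown_method_errors(self, small_data):
        y, _ = small_data
        with pytest.raises(ValueError, match="unknown embedding method"):
            pare.pare_embed(y, spec=pare.EmbeddingSpec(method="nope"))

    def test_trivial_embedder_returns_first_two_columns(self, small_data):
        y, meta = small_data
        name = "first_two"
        if name not in _EMBEDDERS:
            pare.register_embedder(name, lambda x, is_d, spec: np.asarray(x)[:, :2])
        X = pare.build_design(meta, ["batch"])
        E = pare.pare_input(y, X)
        res = pare.pare_embed(y, X, pare.EmbeddingSpec(method=name))
        np.testing.assert_allclose(res.coords, E.coords[:, :2], atol=1e-12)
        assert res.adjusted_for == ["batch"]

    def test_pcoa_embedder_matches_direct_eigendecomposition(self, small_data):
        y, meta = small_data
        X = pare.build_design(meta, ["batch"])
        res = pare.pare_embed(y, X, pare.EmbeddingSpec(method="pcoa"))
        G = pare.double_center(pare.pairwise_distances(y))
        delta = pare.adjusted_gram(G, pare.hat_matrix(X))
        direct = pare.principal_coordinates(delta, k=2).coords
        # compare distance matrices: signs/rotations of tied eigenvalues differ
        d1 = squareform(pdist(res.coords))
        d2 = squareform(pdist(direct))
        assert np.abs(d1 - d2).max() < 1e-8


class TestEmbeddingRuns:
    def test_tsne_deterministic_under_seed(self, shifted_batches):
        ds = shifted_batches(batch_effect=3.0)
        X = pare.build_design(ds.metadata, ["batch"])
        spec = pare.EmbeddingSpec(method="tsne", perplexity=8, seed=3)
        r1 = pare.pare_embed(ds.features, X, spec)
        r2 = pare.pare_embed(ds.features, X, spec)
        assert np.array_equal(r1.coords, r2.coords)
        assert r1.adjusted_for == ["batch"]
        assert np.isfinite(r1.coords).all()

    def test_umap_runs_and_is_deterministic(self, shifted_batches):
        ds = shifted_batches(batch_effect=3.0)
        X = pare.build_design(ds.metadata, ["batch"])
        spec = pare.EmbeddingSpec(method="umap", n_neighbors=8, seed=3)
        r1 = pare.pare_embed(ds.features, X, spec)
        r2 = pare.pare_embed(ds.features, X, spec)
        assert np.array_equal(r1.coords, r2.coords)
        assert r1.coords.shape == (ds.n, 2)

    def test_spec_validation(self, small_data):
        y, _ = small_data
        with pytest.raises(ValueError, match="perplexity"):
            pare.pare_embed(y, spec=pare.EmbeddingSpec(method="tsne", perplexity=40))
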