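"""PCA, component-count estimation, deflation, ICA and contributors."""

import math

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from icaflow.decomposition import (
    ContributorSet,
    IcaModel,
    contributor_overlap,
    default_k_max,
    deflate_first_component,
    estimate_ncp,
    fit_pca,
    run_fastica,
    select_contributors,
)
from icaflow.io import DataError


def matched_correlations(S_rec, S_true):
    """|correlation| of recovered vs planted sources after optimal matching."""
    C = np.array([
        [abs(np.corrcoef(S_true[:, i], S_rec[:, j])[0, 1])
         for j in range(S_rec.shape[1])]
        for i in range(S_true.shape[1])
    ])
    ri, ci = linear_sum_assignment(-C)
    return C[ri, ci]


class TestPca:
    def test_rank_one_matrix_has_single_variance_fraction(self, rng):
        X = np.outer(rng.normal(size=12), rng.normal(size=30))
        pca = fit_pca(X)
        assert pca.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(pca.variance_fraction[1:] < 1e-12)

    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(9, 5))
        pca = fit_pca(X)
        Xc = X - X.mean(axis=0)
        ev = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (X.shape[0] - 1)))[::-1]
        assert np.allclose(pca.eigenvalues, ev[: pca.n_components], atol=1e-10)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(8, 6))
        pca = fit_pca(X)
        recon = pca.scores @ pca.loadings.T
        assert np.allclose(recon, X - pca.center, atol=1e-10)

    def test_loadings_are_orthonormal(self, rng):
        pca = fit_pca(rng.normal(size=(10, 7)))
        G = pca.loadings.T @ pca.loadings
        assert np.allclose(G, np.eye(pca.n_components), atol=1e-10)

    def test_k_too_large_is_fatal(self, rng):
        with pytest.raises(DataError):
            fit_pca(rng.normal(size=(5, 4)), K=10)


class TestComponentCount:
    @staticmethod
    def planted(seed, n=200, m=30, r=3, noise=0.1):
        rng = np.random.default_rng(seed)
        signal = rng.normal(size=(m, r)) @ rng.normal(size=(r, n))
        return signal + rng.normal(size=(m, n)) * noise * signal.std()

    def test_gcv_recovers_planted_rank(self):
        hits = sum(estimate_ncp(self.planted(s), "gcv", 15)[0] == 3
                   for s in range(20))
        assert hits >= 18

    def test_gcv_on_pure_noise_selects_nothing(self):
        picks = [estimate_ncp(np.random.default_rng(100 + s).normal(size=(30, 200)),
                              "gcv", 15)[0] for s in range(10)]
        assert sum(k <= 1 for k in picks) > len(picks) / 2

    def test_smooth_method_finds_the_scree_elbow(self):
        k, _ = estimate_ncp(self.planted(7, noise=0.05), "smooth", 10)
        assert 1 <= k <= 4

    def test_k_max_beyond_rank_is_fatal(self):
        with pytest.raises(DataError):
            estimate_ncp(self.planted(0, n=10, m=8), "gcv", K_max=9)

    def test_default_k_max_stays_below_saturation(self):
        for m, n in [(22, 195), (28, 5084), (10, 10)]:
            k = default_k_max(m, n)
            assert 1 <= k <= min(m, n) - 2
            assert m + n * k + m * k - k * k - k <= n * m / 2


class TestDeflation:
    def test_rank_one_matrix_deflates_to_zero(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=25))
        res = deflate_first_component(X, fit_pca(X))
        assert np.max(np.abs(res.X_hat)) < 1e-10

    def test_residual_is_orthogonal_to_first_loading(self, rng):
        X = rng.normal(size=(10, 30))
        pca = fit_pca(X)
        res = deflate_first_component(X, pca)
        assert np.max(np.abs(res.X_hat @ pca.loadings[:, 0])) < 1e-8

    def test_variance_bookkeeping(self, rng):
        X = rng.normal(size=(12, 40))
        pca = fit_pca(X)
        res = deflate_first_component(X, pca)
        var_x = np.sum((X - X.mean(axis=0)) ** 2)
        var_hat = np.sum(res.X_hat ** 2)
        assert (var_x - var_hat) / var_x == pytest.approx(
            pca.variance_fraction[0], rel=1e-8)
        assert np.linalg.matrix_rank(res.Y) <= 1

    def test_dimension_mismatch_is_fatal(self, rng):
        X = rng.normal(size=(10, 30))
        with pytest.raises(DataError):
            deflate_first_component(rng.normal(size=(10, 29)), fit_pca(X))


class TestFastIca:
    def test_planted_laplace_sources_recovered(self):
        rng = np.random.default_rng(3)
        m, n, k = 100, 200, 2
        S = rng.laplace(size=(m, k))
        X = S @ rng.normal(size=(k, n))
        X += rng.normal(size=(m, n)) * (X.std() / np.sqrt(10))
        ica = run_fastica(X, k, seed=0)
        assert ica.converged
        assert np.all(matched_correlations(ica.S, S) >= 0.95)

    def test_single_component_on_rank_one_matrix_equals_pc1(self, rng):
        X = np.outer(rng.laplace(size=30), rng.normal(size=50))
        X += rng.normal(size=(30, 50)) * 1e-3
        ica = run_fastica(X, 1, seed=0)
        pca = fit_pca(X, K=1)
        r = np.corrcoef(ica.S[:, 0], pca.scores[:, 0])[0, 1]
        assert abs(r) >= 0.999

    def test_seed_invariant_component_subspace(self):
        rng = np.random.default_rng(9)
        S = rng.laplace(size=(120, 2))
        X = S @ rng.normal(size=(2, 150))
        a = run_fastica(X, 2, seed=1)
        b = run_fastica(X, 2, seed=99)
        # principal angles between the two recovered source subspaces
        qa, _ = np.linalg.qr(a.S)
        qb, _ = np.linalg.qr(b.S)
        sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert np.max(angles) < 1e-3

    def test_sign_orientation_is_deterministic(self):
        rng = np.random.default_rng(5)
        S = rng.laplace(size=(80, 3))
        X = S @ rng.normal(size=(3, 120))
        ica = run_fastica(X, 3, seed=0)
        for j in range(3):
            assert ica.A[j, np.argmax(np.abs(ica.A[j]))] > 0


class TestContributors:
    @staticmethod
    def model(weights):
        weights = np.atleast_2d(np.asarray(weights, dtype=float))
        k, n = weights.shape
        return IcaModel(S=np.zeros((3, k)), A=weights, mean=np.zeros(n), k=k,
                        converged=True, iterations=1, seed=0, tolerance=1e-4,
                        gene_ids=[f"G{i}" for i in range(n)])

    @pytest.mark.parametrize("n,expected", [(10, 1), (25, 3), (5084, 509)])
    def test_set_size_is_ceil_n_over_10(self, n, expected, rng):
        sets = select_contributors(self.model(rng.normal(size=(2, n))))
        assert all(len(s) == expected == math.ceil(n / 10) for s in sets)

    def test_top_weights_selected(self):
        w = np.zeros(20)
        w[[4, 11]] = [5.0, -7.0]
        (s,) = select_contributors(self.model(w))
        assert s.genes == ["G11", "G4"]
        assert s.boundary == 5.0

    def test_boundary_ties_break_by_input_order(self):
        w = np.ones(20)  # all tied: first two by stable order
        (s,) = select_contributors(self.model(w))
        assert s.genes == ["G0", "G1"]

    def test_selection_invariant_to_gene_order_without_ties(self, rng):
        w = rng.normal(size=30)
        (a,) = select_contributors(self.model(w))
        perm = rng.permutation(30)
        model_p = self.model(w[perm])
        model_p.gene_ids = [f"G{i}" for i in perm]
        (b,) = select_contributors(model_p)
        assert a.gene_set == b.gene_set


class TestOverlap:
    @staticmethod
    def cs(name, genes):
        return ContributorSet(name, list(genes), np.ones(len(genes)), 1.0)

    def test_disjoint_sets(self):
        mat, unique = contributor_overlap(
            [self.cs("IC1", "abc"), self.cs("IC2", "def")])
        assert mat[0, 1] == 0 and mat[0, 0] == 3
        assert unique == {"IC1": 3, "IC2": 3}

    def test_identical_sets(self):
        mat, unique = contributor_overlap(
            [self.cs("IC1", "abc"), self.cs("IC2", "abc")])
        assert mat[0, 1] == 3
        assert unique == {"IC1": 0, "IC2": 0}

    def test_matches_brute_force_set_algebra(self, rng):
        pool = [f"g{i}" for i in range(50)]
        sets = [self.cs(f"IC{j}", rng.choice(pool, size=15, replace=False))
                for j in range(4)]
        mat, unique = contributor_overlap(sets)
        for i in range(4):
            for j in range(4):
                assert mat[i, j] == len(set(sets[i].genes) & set(sets[j].genes))
            others = set().union(*(s.genes for k, s in enumerate(sets) if k != i))
            assert unique[f"IC{i}"] == len(set(sets[i].genes) - others)
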