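"""Matrix decomposition of the differential-gene expression matrix.

The expression of the differential genes is modelled as a linear mixture
of statistically independent source signals, ``X^T = S A``: each of the
k sources is an expression mode active across samples, and the mixing
matrix rows carry the gene weights of each mode.

The dominant response to the intervention (the first principal
component) can mask weaker independent modes; deflation removes its
rank-1 reconstruction (``Y^T = z1 (x) phi1``, ``X_hat^T = X^T - Y^T``)
before ICA is re-run with one fewer component.

Internally all computation uses samples-as-rows (m x n); the public I/O
convention stays genes x samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import DataError, ExpressionMatrix

__all__ = [
    "PcaModel",
    "DeflationResult",
    "IcaModel",
    "ContributorSet",
    "RankOnePCA",
    "ExpressionICA",
    "fit_pca",
    "estimate_ncp",
    "deflate_first_component",
    "run_fastica",
    "select_contributors",
    "contributor_overlap",
]


def _as_samples_by_genes(X) -> np.ndarray:
    """Accept an ExpressionMatrix (genes x samples) or an (m, n) array."""
    if isinstance(X, ExpressionMatrix):
        return X.values.T.copy()
    return np.array(X, dtype=float)


@dataclass
class PcaModel:
    """SVD-based PCA of the gene-centered samples x genes matrix."""

    scores: np.ndarray            # z, (m, K)
    loadings: np.ndarray          # phi, (n, K), orthonormal columns
    eigenvalues: np.ndarray       # (K,), covariance eigenvalues
    variance_fraction: np.ndarray  # (K,)
    center: np.ndarray            # (n,) per-gene means
    total_variance: float         # sum of all covariance eigenvalues

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class DeflationResult:
    """Rank-1 approximation Y and deflated residual X_hat (both m x n)."""

    Y: np.ndarray
    X_hat: np.ndarray


@dataclass
class IcaModel:
    """FastICA decomposition X^T ~ S A (+ gene means)."""

    S: np.ndarray        # (m, k) source activations over samples
    A: np.ndarray        # (k, n) gene mixing weights
    mean: np.ndarray     # (n,) per-gene centering
    k: int
    converged: bool
    iterations: int
    seed: int
    tolerance: float
    nonlinearity: str = "logcosh"
    alpha1: float = 1.0
    gene_ids: list[str] | None = None


@dataclass
class ContributorSet:
    """Top-decile genes of one independent component."""

    component: str
    genes: list[str]              # ordered by |weight| descending
    weights: np.ndarray           # matching |weight| values
    boundary: float               # smallest included |weight|

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


class RankOnePCA(BaseEstimator, TransformerMixin):
    """PCA with rank-1 deflation as the transform.

    ``fit(X)`` runs SVD-based PCA on the gene-centered samples x genes
    matrix; ``transform(X)`` subtracts the rank-1 reconstruction of the
    first principal component from the centered matrix, leaving a
    residual orthogonal to the first loading vector.

    Attributes
    ----------
    scores_, loadings_, eigenvalues_, variance_fraction_, center_,
    total_variance_ : fitted PCA quantities (see :class:`PcaModel`).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        M = _as_samples_by_genes(X)
        m, n = M.shape
        if m < 2 or n < 2:
            raise DataError("PCA needs at least 2 samples and 2 genes")
        k_max = min(n, m - 1)
        K = k_max if self.n_components is None else int(self.n_components)
        if not 1 <= K <= k_max:
            raise DataError(f"n_components must be in [1, {k_max}], got {K}")
        center = M.mean(axis=0)
        Mc = M - center
        u, s, vt = np.linalg.svd(Mc, full_matrices=False)
        total = float((s ** 2).sum())
        self.scores_ = u[:, :K] * s[:K]
        self.loadings_ = vt[:K].T
        self.eigenvalues_ = s[:K] ** 2 / (m - 1)
        self.variance_fraction_ = (s[:K] ** 2 / total) if total > 0 else np.zeros(K)
        self.center_ = center
        self.total_variance_ = total / (m - 1)
        self.n_features_in_ = n
        return self

    def transform(self, X):
        M = _as_samples_by_genes(X)
        if M.shape[1] != self.n_features_in_:
            raise DataError("gene dimension does not match the fitted model")
        Mc = M - self.center_
        z1 = Mc @ self.loadings_[:, 0]
        return Mc - np.outer(z1, self.loadings_[:, 0])

    def to_model(self) -> PcaModel:
        return PcaModel(
            scores=self.scores_,
            loadings=self.loadings_,
            eigenvalues=self.eigenvalues_,
            variance_fraction=self.variance_fraction_,
            center=self.center_,
            total_variance=self.total_variance_,
        )


def fit_pca(X, K: int | None = None) -> PcaModel:
    """PCA of a genes x samples ExpressionMatrix (or m x n array)."""
    return RankOnePCA(n_components=K).fit(X).to_model()


def default_k_max(m: int, n: int) -> int:
    """Largest sensible K_max for :func:`estimate_ncp` on an m x n matrix.

    Caps the search where the bilinear parameter count df_k exceeds half
    the number of data cells (beyond that the GCV denominator collapses
    and the criterion rewards near-saturated fits), and always stays two
    below full rank so the rank-k residual never vanishes.
    """
    hard = max(1, min(m - 2, n - 2))
    nm = n * m
    k = 1
    for cand in range(1, hard + 1):
        df = m + n * cand + m * cand - cand * cand - cand
        if df > nm / 2:
            break
        k = cand
    return k


def estimate_ncp(
    X, method: str = "gcv", K_max: int | None = None
) -> tuple[int, np.ndarray]:
    """Estimate the optimal number of principal components.

    ``gcv`` minimises the generalized cross-validation criterion

        GCV(k) = (n*m*RSS_k) / (n*m - df_k)^2,

    where RSS_k is the squared Frobenius residual of the rank-k
    reconstruction of the centered matrix and
    ``df_k = m + n*k + m*k - k^2 - k`` counts the parameters of the
    k-component bilinear fit including centering.  ``smooth`` is an
    eigen-gap heuristic: it picks the k maximising the ratio of
    successive smoothed eigenvalue drops.

    Returns the chosen k and the per-k criterion curve
    (``gcv``: GCV(0..K_max); ``smooth``: drop ratios for k=1..K_max).
    """
    M = _as_samples_by_genes(X)
    m, n = M.shape
    hard_max = min(n - 1, m - 1)
    if K_max is None:
        K_max = hard_max
    if K_max > hard_max:
        raise DataError(f"K_max={K_max} exceeds min(n-1, m-1)={hard_max}")
    Mc = M - M.mean(axis=0)
    s = np.linalg.svd(Mc, compute_uv=False)
    ev = s ** 2
    total = float(ev.sum())
    if method == "gcv":
        crit = np.empty(K_max + 1)
        for k in range(K_max + 1):
            rss = total - float(ev[:k].sum())
            df_k = m + n * k + m * k - k * k - k
            denom = n * m - df_k
            if denom <= 0:
                crit[k] = np.inf
                continue
            crit[k] = (n * m * rss) / denom ** 2
        if np.any(np.isnan(crit)):
            raise DataError("non-finite GCV criterion")
        if not np.isfinite(crit).any():
            raise DataError("GCV criterion undefined for every k; reduce K_max")
        return int(np.argmin(crit)), crit
    elif method == "smooth":
        lam = ev[: K_max + 1].copy()
        # light smoothing of the scree before taking drops
        if lam.size >= 3:
            sm = lam.copy()
            sm[1:-1] = (lam[:-2] + 2 * lam[1:-1] + lam[2:]) / 4.0
            lam = sm
        drops = -np.diff(lam)  # drop after component k (k = 1..K_max)
        eps = 1e-12 * max(total, 1.0)
        ratios = drops[:-1] / np.maximum(drops[1:], eps)
        if ratios.size == 0:
            return 1, drops
        return int(np.argmax(ratios)) + 1, ratios
    raise DataError(f"unknown method {method!r}; choose 'gcv' or 'smooth'")


def deflate_first_component(X, pca: PcaModel) -> DeflationResult:
    """Subtract the first principal component's rank-1 reconstruction.

    ``Y = outer(z1, phi1)`` and ``X_hat = centered(X) - Y``; the residual
    has zero projection on phi1 and the total variance decreases by
    exactly the first eigenvalue.
    """
    M = _as_samples_by_genes(X)
    if M.shape[1] != pca.loadings.shape[0] or M.shape[0] != pca.scores.shape[0]:
        raise DataError("matrix dimensions do not match the fitted PCA")
    Mc = M - pca.center
    Y = np.outer(pca.scores[:, 0], pca.loadings[:, 0])
    return DeflationResult(Y=Y, X_hat=Mc - Y)


class ExpressionICA(BaseEstimator, TransformerMixin):
    """FastICA of a samples x genes expression matrix.

    Simultaneous (parallel) fixed-point extraction with the log-cosh
    contrast ``g(u) = tanh(alpha1 * u)``; the data are gene-centered and
    whitened to ``n_components`` dimensions.  Components are
    sign-oriented so that each component's largest-|weight| gene has a
    positive weight, making the output deterministic up to permutation.

    Attributes
    ----------
    S_ : ndarray (m, k) — source activations over samples.
    A_ : ndarray (k, n) — gene mixing weights (X^T ~ S_ A_ + mean_).
    converged_ : bool; n_iter_ : int.
    """

    def __init__(self, n_components: int = 2, seed: int = 0,
                 tolerance: float = 1e-4, max_iter: int = 1000,
                 alpha1: float = 1.0):
        self.n_components = n_components
        self.seed = seed
        self.tolerance = tolerance
        self.max_iter = max_iter
        self.alpha1 = alpha1

    def fit(self, X, y=None):
        M = _as_samples_by_genes(X)
        m, n = M.shape
        k = int(self.n_components)
        if not 1 <= k <= min(n, m):
            raise DataError(f"n_components must be in [1, {min(n, m)}], got {k}")
        self.mean_ = M.mean(axis=0)
        ica = FastICA(
            n_components=k,
            algorithm="parallel",
            fun="logcosh",
            fun_args={"alpha": self.alpha1},
            tol=self.tolerance,
            max_iter=self.max_iter,
            whiten="unit-variance",
            random_state=self.seed,
        )
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(M)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                converged = False
                warnings.warn(
                    f"FastICA did not converge within {self.max_iter} iterations; "
                    "results returned with converged=False"
                )
        A = ica.mixing_.T  # (k, n)
        # orient: largest-|weight| gene of each component gets a positive weight
        for j in range(k):
            idx = int(np.argmax(np.abs(A[j])))
            if A[j, idx] < 0:
                A[j] = -A[j]
                S[:, j] = -S[:, j]
        self.S_ = S
        self.A_ = A
        self.converged_ = converged
        self.n_iter_ = int(ica.n_iter_)
        self.n_features_in_ = n
        return self

    def transform(self, X):
        # project new samples onto the fitted sources via least squares
        M = _as_samples_by_genes(X) - self.mean_
        return M @ np.linalg.pinv(self.A_)

    def to_model(self, seed: int | None = None,
                 gene_ids: list[str] | None = None) -> IcaModel:
        return IcaModel(
            S=self.S_, A=self.A_, mean=self.mean_, k=self.A_.shape[0],
            converged=self.converged_, iterations=self.n_iter_,
            seed=self.seed if seed is None else seed,
            tolerance=self.tolerance, alpha1=self.alpha1, gene_ids=gene_ids,
        )


def run_fastica(
    X, k: int, seed: int, tolerance: float = 1e-4, max_iter: int = 1000,
    gene_ids: list[str] | None = None,
) -> IcaModel:
    """FastICA with the study settings (parallel, logcosh, alpha1=1)."""
    if isinstance(X, ExpressionMatrix) and gene_ids is None:
        gene_ids = list(X.feature_ids)
    est = ExpressionICA(n_components=k, seed=seed, tolerance=tolerance,
                        max_iter=max_iter).fit(X)
    return est.to_model(gene_ids=gene_ids)


def select_contributors(
    ica: IcaModel, gene_ids: list[str] | None = None
) -> list[ContributorSet]:
    """Ninth-decile contributor genes per component.

    Each component's contributor set holds the ``ceil(n/10)`` genes with
    the largest absolute mixing weight (rank-based, so the set size is
    identical across components; ties at the boundary are broken by the
    stable input gene order).
    """
    if gene_ids is None:
        gene_ids = ica.gene_ids
    if gene_ids is None:
        raise DataError("gene ids are required to name contributors")
    n = len(gene_ids)
    if ica.A.shape[1] != n:
        raise DataError(f"mixing matrix has {ica.A.shape[1]} genes, ids {n}")
    if n < 10:
        raise DataError("contributor selection needs at least 10 genes")
    size = math.ceil(n / 10)
    sets = []
    for j in range(ica.k):
        w = np.abs(ica.A[j])
        order = np.argsort(-w, kind="stable")[:size]
        sets.append(
            ContributorSet(
                component=f"IC{j + 1}",
                genes=[gene_ids[i] for i in order],
                weights=w[order],
                boundary=float(w[order[-1]]),
            )
        )
    return sets


def contributor_overlap(
    sets: list[ContributorSet],
) -> tuple[np.ndarray, dict[str, int]]:
    """Pairwise intersection sizes and per-component unique counts.

    The returned matrix is symmetric with the set sizes on the diagonal;
    ``unique[c]`` counts the members of component c found in no other
    component's set.
    """
    if len(sets) < 2:
        raise DataError("overlap needs at least 2 contributor sets")
    k = len(sets)
    mat = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            mat[i, j] = len(sets[i].gene_set & sets[j].gene_set)
    unique = {}
    for i, s in enumerate(sets):
        others: set[str] = set()
        for j, o in enumerate(sets):
            if j != i:
                others |= o.gene_set
        unique[s.component] = len(s.gene_set - others)
    return mat, unique
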