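"""Differential expression via per-feature linear models with
empirical-Bayes variance moderation.

Each feature's log2 expression is regressed on an intercept, a binary
gender covariate g (0 = female, 1 = male) and the completed distance d
in km (0 for pre-race samples)::

    y_k = beta0_k + beta1_k * g + beta2_k * d + eps_k

Residual variances are shrunk toward a global prior estimated by
matching the first two moments of log(sigma2) to a scaled-F model
(digamma/trigamma inversion), giving moderated t-statistics with
``d0 + df`` degrees of freedom.  Features are ranked per coefficient by
Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator

from .io import DataError, ExpressionMatrix, FeatureAnnotation, SampleInfo

__all__ = [
    "DESIGN_COLUMNS",
    "build_design",
    "ModeratedLinearModel",
    "ModeratedFit",
    "DifferentialList",
    "fit_linear_models",
    "ebayes_moderate",
    "bh_adjust",
    "select_differential",
    "select_strong_effects",
    "hierarchical_order",
]

DESIGN_COLUMNS = ("intercept", "gender", "distance")
TESTED_COEFFICIENTS = ("gender", "distance")


def build_design(samples: list[SampleInfo]) -> pd.DataFrame:
    """Design matrix with columns intercept, gender (0/1), distance (km)."""
    if len(samples) < 4:
        raise DataError("need at least 4 samples to fit the 3-coefficient model")
    g = np.array([1.0 if s.gender == "male" else 0.0 for s in samples])
    d = np.array([s.distance_km for s in samples], dtype=float)
    for name, col in (("gender", g), ("distance", d)):
        if np.allclose(col, col[0]):
            raise DataError(f"covariate {name!r} is constant: design is rank deficient")
    X = pd.DataFrame(
        {"intercept": 1.0, "gender": g, "distance": d},
        index=[s.sample_id for s in samples],
    )
    if np.linalg.matrix_rank(X.to_numpy()) < 3:
        raise DataError("design matrix is rank deficient")
    return X


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            return x
    raise RuntimeError("trigamma inversion did not converge")


def _estimate_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the log residual variances.

    Under the scaled inverse-chi-square prior, log(sigma2) is a shifted
    log-F variate; its mean and excess variance identify s0^2 and d0.
    """
    ok = sigma2 > 0
    z = np.log(sigma2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess dispersion beyond sampling noise: infinite prior df
        return np.inf, float(np.exp(emean))
    try:
        d0 = 2.0 * _trigamma_inverse(evar)
    except RuntimeError:
        warnings.warn(
            "trigamma inversion failed; falling back to an infinite prior "
            "(all variances shrunk to s0^2)"
        )
        return np.inf, float(np.exp(emean))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


class ModeratedLinearModel(BaseEstimator):
    """Per-output OLS with empirical-Bayes moderated t-statistics.

    scikit-learn style estimator: ``fit(X, Y)`` takes the design matrix
    ``X`` (m samples x p coefficients) and the response matrix ``Y``
    (m samples x n features) and fits one ordinary least-squares model
    per feature, then shrinks the residual variances toward an
    estimated prior.

    Parameters
    ----------
    prior_df : float or None, default None
        Prior degrees of freedom d0.  ``None`` estimates (d0, s0^2)
        from the data; ``0`` disables moderation (ordinary t-statistics);
        ``numpy.inf`` shrinks every variance fully to s0^2.
    min_moderation_features : int, default 10
        Minimum number of features with positive residual variance
        required before the prior is estimated.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features, p)
        OLS coefficients, one row per feature.
    sigma2_ : ndarray of shape (n_features,)
        Residual variances RSS / df_residual.
    unscaled_var_ : ndarray of shape (p,)
        Diagonal of (X'X)^-1; Var(beta_j) = sigma2 * unscaled_var_[j].
    df_residual_ : int
    d0_, s0_squared_ : float
        Estimated (or forced) prior degrees of freedom and variance.
    posterior_var_ : ndarray of shape (n_features,)
        Shrunken variances (d0*s0^2 + df*sigma2) / (d0 + df).
    t_, p_values_, adj_p_values_ : ndarray of shape (n_features, p)
        Moderated t-statistics, two-sided p-values and BH-adjusted
        p-values per coefficient (adjusted within coefficient).
    """

    def __init__(self, prior_df: float | None = None,
                 min_moderation_features: int = 10):
        self.prior_df = prior_df
        self.min_moderation_features = min_moderation_features

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        m, p = X.shape
        if Y.shape[0] != m:
            raise DataError(f"X has {m} rows but Y has {Y.shape[0]}")
        if np.linalg.matrix_rank(X) < p:
            raise DataError("design matrix is rank deficient")
        df = m - p
        if df < 1:
            raise DataError(f"no residual degrees of freedom (m={m}, p={p})")
        xtx_inv = np.linalg.inv(X.T @ X)
        coef = Y.T @ X @ xtx_inv  # (n, p)
        resid = Y - X @ coef.T
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = rss / df

        self.n_features_in_ = p
        self.coef_ = coef
        self.sigma2_ = sigma2
        self.unscaled_var_ = np.diag(xtx_inv).copy()
        self.df_residual_ = df

        if self.prior_df is None:
            if int((sigma2 > 0).sum()) < self.min_moderation_features:
                raise DataError(
                    "too few features with positive residual variance to "
                    "estimate the variance prior"
                )
            self.d0_, self.s0_squared_ = _estimate_prior(sigma2, df)
        else:
            self.d0_ = float(self.prior_df)
            ok = sigma2 > 0
            z = np.log(sigma2[ok]) if ok.any() else np.array([0.0])
            self.s0_squared_ = float(np.exp(z.mean()))

        d0 = self.d0_
        if np.isinf(d0):
            post = np.full_like(sigma2, self.s0_squared_)
            df_total = np.inf
        else:
            post = (d0 * self.s0_squared_ + df * sigma2) / (d0 + df)
            df_total = d0 + df
        self.posterior_var_ = post
        self.df_total_ = df_total

        se = np.sqrt(np.outer(post, self.unscaled_var_))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
            t = np.where(coef == 0, 0.0, t)
        if np.isinf(df_total):
            pvals = 2.0 * stats.norm.sf(np.abs(t))
        else:
            pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
        self.t_ = t
        self.p_values_ = pvals
        self.adj_p_values_ = np.column_stack(
            [bh_adjust(pvals[:, j]) for j in range(p)]
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_.T


@dataclass
class ModeratedFit:
    """Per-feature linear-model results on an expression matrix."""

    feature_ids: list[str]
    design: pd.DataFrame
    coef: np.ndarray          # (n, 3): intercept, gender, distance
    unscaled_var: np.ndarray  # (3,)
    sigma2: np.ndarray        # (n,)
    df_residual: int
    d0: float | None = None
    s0_squared: float | None = None
    posterior_var: np.ndarray | None = None
    t_mod: np.ndarray | None = None       # (n, 3)
    p_value: np.ndarray | None = None     # (n, 3)
    adj_p: np.ndarray | None = None       # (n, 3)

    @property
    def moderated(self) -> bool:
        return self.t_mod is not None

    def coefficient_index(self, coefficient: str) -> int:
        if coefficient not in DESIGN_COLUMNS:
            raise DataError(
                f"unknown coefficient {coefficient!r}; choose from {DESIGN_COLUMNS}"
            )
        return DESIGN_COLUMNS.index(coefficient)

    def to_frame(self, coefficient: str = "distance") -> pd.DataFrame:
        j = self.coefficient_index(coefficient)
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "beta": self.coef[:, j],
                "sigma2": self.sigma2,
            }
        )
        if self.moderated:
            df["t_mod"] = self.t_mod[:, j]
            df["p"] = self.p_value[:, j]
            df["adj_p"] = self.adj_p[:, j]
        return df


def fit_linear_models(expr: ExpressionMatrix, design: pd.DataFrame) -> ModeratedFit:
    """Ordinary least squares per feature; moderation fields left empty."""
    if list(design.index) != expr.sample_ids:
        raise DataError("design rows do not match expression sample order")
    model = ModeratedLinearModel(prior_df=0)
    model.fit(design.to_numpy(), expr.values.T)
    return ModeratedFit(
        feature_ids=list(expr.feature_ids),
        design=design,
        coef=model.coef_,
        unscaled_var=model.unscaled_var_,
        sigma2=model.sigma2_,
        df_residual=model.df_residual_,
    )


def ebayes_moderate(fit: ModeratedFit, prior_df: float | None = None) -> ModeratedFit:
    """Fill the moderated-statistic fields of an OLS fit.

    ``prior_df`` overrides the estimated d0 (0 reproduces ordinary
    t-statistics; +inf shrinks all variances to s0^2).
    """
    n = len(fit.feature_ids)
    df = fit.df_residual
    if prior_df is None:
        if int((fit.sigma2 > 0).sum()) < 10:
            raise DataError("need >= 10 features with sigma2 > 0 for moderation")
        d0, s0_sq = _estimate_prior(fit.sigma2, df)
    else:
        d0 = float(prior_df)
        ok = fit.sigma2 > 0
        s0_sq = float(np.exp(np.log(fit.sigma2[ok]).mean())) if ok.any() else 0.0
    if np.isinf(d0):
        post = np.full(n, s0_sq)
        df_total = np.inf
    else:
        post = (d0 * s0_sq + df * fit.sigma2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(np.outer(post, fit.unscaled_var))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.coef / se, np.inf * np.sign(fit.coef))
        t = np.where(fit.coef == 0, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = np.column_stack([bh_adjust(p[:, j]) for j in range(p.shape[1])])
    return ModeratedFit(
        feature_ids=fit.feature_ids,
        design=fit.design,
        coef=fit.coef,
        unscaled_var=fit.unscaled_var,
        sigma2=fit.sigma2,
        df_residual=df,
        d0=d0,
        s0_squared=s0_sq,
        posterior_var=post,
        t_mod=t,
        p_value=p,
        adj_p=adj,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("bh_adjust expects a 1-d array")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class DifferentialList:
    """Significant features for one coefficient, with gene-level summary."""

    coefficient: str
    table: pd.DataFrame  # feature_id, gene_id, beta, t_mod, p, adj_p, direction
    alpha: float
    counts: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table["feature_id"])

    @property
    def genes(self) -> set[str]:
        g = self.table["gene_id"]
        return set(g[g != ""])

    def regulation_map(self) -> dict[str, str]:
        """gene -> up/down from the sign of the coefficient.

        When several features map to one gene the feature with the
        smallest adjusted p-value decides the direction.
        """
        best: dict[str, tuple[float, str]] = {}
        for _, row in self.table.iterrows():
            gene = row["gene_id"]
            if not gene:
                continue
            if gene not in best or row["adj_p"] < best[gene][0]:
                best[gene] = (row["adj_p"], row["direction"])
        return {g: d for g, (_, d) in best.items()}


def select_differential(
    fit: ModeratedFit,
    coefficient: str,
    annotation: FeatureAnnotation,
    alpha: float = 0.05,
) -> DifferentialList:
    """Features with adjusted p < alpha for one coefficient.

    Gene ids come from unambiguous annotations only; multi-annotated and
    unannotated features keep an empty gene_id and are counted in
    ``counts``.  Direction is the sign of the coefficient (down for
    negative).
    """
    if not fit.moderated:
        raise DataError("run ebayes_moderate before selecting differential features")
    j = fit.coefficient_index(coefficient)
    sig = fit.adj_p[:, j] < alpha
    idx = np.flatnonzero(sig)
    # rank by adjusted p-value then raw p for a stable, reportable order
    idx = idx[np.lexsort((fit.p_value[idx, j], fit.adj_p[idx, j]))]
    from .io import map_features_to_genes  # local import avoids cycle at module load

    feats = [fit.feature_ids[i] for i in idx]
    unambiguous, ambiguous, unannotated = map_features_to_genes(feats, annotation)
    gene_ids = [unambiguous.get(f, "") for f in feats]
    beta = fit.coef[idx, j]
    table = pd.DataFrame(
        {
            "feature_id": feats,
            "gene_id": gene_ids,
            "beta": beta,
            "t_mod": fit.t_mod[idx, j],
            "p": fit.p_value[idx, j],
            "adj_p": fit.adj_p[idx, j],
            "direction": np.where(beta < 0, "down", "up"),
        }
    )
    distinct = set(unambiguous.values())
    n_single = len(unambiguous)
    result = DifferentialList(coefficient=coefficient, table=table, alpha=alpha)
    # regulation percentages are over distinct genes, each gene's direction
    # decided by its best-ranked feature
    reg = result.regulation_map()
    n_down = sum(1 for d in reg.values() if d == "down")
    pct_down = 100.0 * n_down / len(reg) if reg else float("nan")
    result.counts = {
        "features": len(feats),
        "single_annotation": n_single,
        "multi_annotation": len(ambiguous),
        "unannotated": len(unannotated),
        "distinct_genes": len(distinct),
        "pct_down": pct_down,
        "pct_up": 100.0 - pct_down if reg else float("nan"),
    }
    return result


def select_strong_effects(
    diff: DifferentialList, convention: str = "signed"
) -> list[str]:
    """Features whose |beta| exceeds mean + 2 SD over the differential set.

    ``convention`` fixes which values the mean/SD are taken over:
    ``"signed"`` (default) uses the signed coefficients,
    ``"absolute"`` uses their absolute values.  In both cases |beta| is
    compared against the threshold.
    """
    if len(diff.table) < 2:
        raise DataError("strong-effect selection needs at least 2 differential features")
    beta = diff.table["beta"].to_numpy()
    vals = beta if convention == "signed" else np.abs(beta)
    if convention not in ("signed", "absolute"):
        raise DataError(f"unknown convention {convention!r}")
    mu, sd = float(vals.mean()), float(vals.std(ddof=1))
    if sd <= 0:
        warnings.warn("zero variance of beta over the differential set: no selection")
        return []
    keep = np.abs(beta) > mu + 2.0 * sd
    return [f for f, k in zip(diff.table["feature_id"], keep) if k]


def hierarchical_order(
    expr: ExpressionMatrix,
    features: list[str],
    standardize: bool = True,
) -> tuple[list[str], list[str]]:
    """Complete-linkage leaf orders for a heatmap of selected features.

    Rows (features) and columns (samples) are clustered with complete
    linkage on Euclidean distances; rows are standardised to zero mean /
    unit variance first (configurable).
    """
    if len(features) < 2:
        raise DataError("need at least 2 features to cluster")
    sub = expr.subset_features(features)
    M = sub.values
    if standardize:
        sd = M.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        M = (M - M.mean(axis=1, keepdims=True)) / sd
    row_order = leaves_list(linkage(M, method="complete", metric="euclidean"))
    if expr.m_samples >= 2:
        col_order = leaves_list(linkage(M.T, method="complete", metric="euclidean"))
    else:
        col_order = np.arange(expr.m_samples)
    return (
        [features[i] for i in row_order],
        [sub.sample_ids[j] for j in col_order],
    )
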