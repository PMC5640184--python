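"""Sample-level quality screening and the low-expression filter.

Array quality is screened with relative log expression (RLE: per-sample
deviations from gene-wise medians) and a robust outlier flag on the
first two principal components of the sample cloud.  The exclusion rule
(robust z on PC1/PC2, cut 3.0) is this package's numeric
operationalisation of a visual screen; it is configurable.

The non-supervised low-expression filter keeps a feature when its
expression exceeds the grand mean of the matrix on strictly more than
``min_samples`` arrays (both inequalities strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataError, ExpressionMatrix

__all__ = ["QcReport", "compute_rle", "pca_outlier_screen", "filter_low_expressed"]

# consistency factor making the MAD unbiased for the normal SD
_MAD_SCALE = 1.4826


@dataclass
class QcReport:
    """Per-sample QC metrics plus the study-level grand mean."""

    sample_ids: list[str]
    rle_median: np.ndarray | None = None
    rle_iqr: np.ndarray | None = None
    pc_scores: np.ndarray | None = None  # (m, 2)
    outlier_flag: np.ndarray | None = None
    overall_mean: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        if self.rle_median is not None:
            df["rle_median"] = self.rle_median
            df["rle_iqr"] = self.rle_iqr
        if self.pc_scores is not None:
            df["pc1"] = self.pc_scores[:, 0]
            df["pc2"] = self.pc_scores[:, 1]
            df["outlier_flag"] = self.outlier_flag
        if self.overall_mean is not None:
            df["overall_mean"] = self.overall_mean
        return df


def compute_rle(expr: ExpressionMatrix) -> QcReport:
    """Relative log expression: deviations from gene-wise medians.

    For each sample j the RLE values are ``expr[i, j] - median_i`` where
    ``median_i`` is the median of feature i across samples; the report
    stores each sample's median and IQR of those deviations.
    """
    if expr.m_samples < 2:
        raise DataError("RLE needs at least two samples as a deviation reference")
    deviations = expr.values - np.median(expr.values, axis=1, keepdims=True)
    q25, med, q75 = np.percentile(deviations, [25, 50, 75], axis=0)
    return QcReport(
        sample_ids=expr.sample_ids,
        rle_median=med,
        rle_iqr=q75 - q25,
        overall_mean=float(expr.values.mean()),
    )


def pca_outlier_screen(expr: ExpressionMatrix, z_cut: float = 3.0) -> QcReport:
    """Flag samples deviant on PC1/PC2 of the feature-centered matrix.

    A sample is flagged when its robust z-score
    ``|score - median| / (1.4826 * MAD)`` exceeds ``z_cut`` on either of
    the first two principal components.
    """
    if expr.m_samples < 3:
        raise DataError("PCA outlier screen needs at least three samples")
    X = expr.values - expr.values.mean(axis=1, keepdims=True)  # center features
    # sample scores from the SVD of the samples x features matrix
    u, s, vt = np.linalg.svd(X.T, full_matrices=False)
    if s[0] <= 1e-12:
        warnings.warn("zero-variance matrix: no PCA outliers flagged")
        scores = np.zeros((expr.m_samples, 2))
        flags = np.zeros(expr.m_samples, dtype=bool)
        return QcReport(expr.sample_ids, pc_scores=scores, outlier_flag=flags,
                        overall_mean=float(expr.values.mean()))
    k = min(2, s.size)
    scores = np.zeros((expr.m_samples, 2))
    scores[:, :k] = u[:, :k] * s[:k]
    flags = np.zeros(expr.m_samples, dtype=bool)
    for c in range(k):
        col = scores[:, c]
        mad = np.median(np.abs(col - np.median(col)))
        if mad <= 1e-12:
            continue
        z = np.abs(col - np.median(col)) / (_MAD_SCALE * mad)
        flags |= z > z_cut
    return QcReport(expr.sample_ids, pc_scores=scores, outlier_flag=flags,
                    overall_mean=float(expr.values.mean()))


def filter_low_expressed(expr: ExpressionMatrix, min_samples: int) -> ExpressionMatrix:
    """Keep features expressed above the grand mean on > ``min_samples`` arrays.

    The grand mean is computed over all cells of the input matrix, so the
    filter is applied once, after any sample exclusion (re-applying it to
    its own output would recompute the mean and may drop more features).
    """
    overall_mean = expr.values.mean()
    counts = (expr.values > overall_mean).sum(axis=1)
    keep = counts > min_samples
    if not keep.any():
        raise DataError(
            f"low-expression filter removed all {expr.n_features} features "
            f"(min_samples={min_samples}); lower the threshold"
        )
    kept_ids = [f for f, k in zip(expr.feature_ids, keep) if k]
    return ExpressionMatrix(kept_ids, expr.samples, expr.values[keep, :])
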