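"""Gene filtering, quantile normalization and PCA-based QC.

Filtering precedes differential analysis and removes lowly expressed
(low median) and non-informative (low variance) genes. Quantile
normalization forces every sample to share one empirical value
distribution; ties within a sample receive the mean of the reference
values at the rank positions they occupy. PCA variance fractions are
computed as a QC summary only (samples as observations, genes as centered
but unscaled features).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_genes(
    matrix: ExpressionMatrix,
    min_median: float = 1.0,
    min_sd: float = 0.1,
) -> ExpressionMatrix:
    """Retain genes with across-sample median >= ``min_median`` AND
    standard deviation (ddof=1) >= ``min_sd``; order is preserved.

    Defaults are deliberately mild; both thresholds are in log2 units.
    Raises ``ValueError`` if no gene survives.
    """
    if min_median < 0 or min_sd < 0:
        raise ValueError("filter thresholds must be >= 0")
    med = matrix.data.median(axis=1)
    sd = matrix.data.std(axis=1, ddof=1)
    low_median = med < min_median
    low_sd = sd < min_sd
    keep = ~(low_median | low_sd)
    if not keep.any():
        raise ValueError(
            "all genes removed by filtering; lower min_median/min_sd "
            f"(removed {int(low_median.sum())} by median, {int(low_sd.sum())} by sd)"
        )
    logger.info(
        "gene filter: kept %d/%d (removed %d below median %g, %d below sd %g)",
        int(keep.sum()),
        matrix.n_genes,
        int(low_median.sum()),
        min_median,
        int(low_sd.sum()),
        min_sd,
    )
    return ExpressionMatrix(matrix.data.loc[keep])


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Map every sample onto the mean empirical distribution.

    After normalization each column's sorted value vector equals the
    across-sample mean of the sorted input columns. Tied values within a
    sample receive the mean of the reference values at their occupied rank
    positions, so the map is well defined and idempotent.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    data = matrix.data
    arr = data.to_numpy()
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the assigned reference values across each tie group
        tie_means = pd.Series(assigned).groupby(col).transform("mean")
        out[:, j] = tie_means.to_numpy()
    return ExpressionMatrix(pd.DataFrame(out, index=data.index, columns=data.columns))


def pca_variance(matrix: ExpressionMatrix, n_components: int) -> np.ndarray:
    """Fractions of total variance along the leading principal components.

    Samples are observations and genes are (centered, unscaled) features.
    The returned fractions are non-negative, non-increasing and sum to <= 1.
    """
    bound = min(matrix.n_genes, matrix.n_samples)
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components must be in [1, {bound}] for a "
            f"{matrix.n_genes} x {matrix.n_samples} matrix"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(matrix.data.to_numpy().T)
    return pca.explained_variance_ratio_
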