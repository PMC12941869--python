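"""Per-gene z-score standardization and composite signature scores.

The Tumor Score (TS) of a sample is the mean standardized expression of
the genes up-regulated in tumor vs normal minus the mean standardized
expression of the genes down-regulated in that contrast; the Recurrence
Score (RS) is the analogous composite built from the recurrent-vs-primary
contrast. Averaging many signature genes damps per-gene noise, which is
the point of a composite score in heterogeneous tumors.

Standardization is computed per gene across all samples of the scored
matrix by default (mean 0, sd 1 with the n-1 denominator); an optional
reference group restricts the mean/sd estimation to a subset (e.g. normal
samples) while still transforming everyone.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .signatures import GeneSignature

logger = logging.getLogger(__name__)


def zscore_standardize(
    matrix: ExpressionMatrix,
    reference_samples: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Per-gene standardization: subtract mean, divide by sd (ddof=1).

    Zero-variance genes cannot be standardized; they are removed with a
    warning listing them. If ``reference_samples`` is given, mean and sd
    come from those columns only.
    """
    if matrix.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    ref = matrix.data if reference_samples is None else matrix.data[list(reference_samples)]
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("all genes have zero variance; nothing to standardize")
    if constant.any():
        names = matrix.data.index[constant].tolist()
        logger.warning(
            "removing %d zero-variance gene(s) before standardization: %s",
            len(names),
            names[:10],
        )
    data = matrix.data.loc[~constant]
    z = data.sub(mean[~constant], axis=0).div(sd[~constant], axis=0)
    return ExpressionMatrix(z)


def composite_score(
    zmatrix: ExpressionMatrix, signature: GeneSignature
) -> tuple[pd.Series, int, int]:
    """Mean z of up-signature genes minus mean z of down-signature genes.

    Signature genes absent from the matrix are dropped (logged); an empty
    side after intersection contributes 0 with a warning. Returns the
    per-sample score plus the number of up/down genes actually used.
    Raises ``ValueError`` if both sides are empty after intersection.
    """
    genes = set(zmatrix.gene_ids)
    up = sorted(signature.up & genes)
    down = sorted(signature.down & genes)
    n_dropped = len(signature.up - genes) + len(signature.down - genes)
    if n_dropped:
        logger.info(
            "signature %s: %d gene(s) not in matrix dropped", signature.name, n_dropped
        )
    if not up and not down:
        raise ValueError(
            f"signature {signature.name!r} shares no genes with the matrix"
        )
    zero = pd.Series(0.0, index=zmatrix.data.columns)
    up_mean = zmatrix.data.loc[up].mean(axis=0) if up else zero
    down_mean = zmatrix.data.loc[down].mean(axis=0) if down else zero
    if not up or not down:
        side = "up" if not up else "down"
        logger.warning(
            "signature %s: empty %s side after intersection; it contributes 0",
            signature.name,
            side,
        )
    score = up_mean - down_mean
    score.name = signature.name
    return score, len(up), len(down)


def compute_ts_rs(
    matrix: ExpressionMatrix,
    sig_tumor_vs_normal: GeneSignature,
    sig_recurrent_vs_primary: GeneSignature,
    reference_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample Tumor Score and Recurrence Score on one standardized matrix.

    Returns a frame with columns ``sample_id``, ``ts``, ``rs`` and the
    up/down gene counts used for each score. Both scores are computed for
    every sample; downstream classification simply never consults RS for
    normal-like assignments.
    """
    z = zscore_standardize(matrix, reference_samples=reference_samples)
    ts, ts_up, ts_down = composite_score(z, sig_tumor_vs_normal)
    rs, rs_up, rs_down = composite_score(z, sig_recurrent_vs_primary)
    table = pd.DataFrame(
        {
            "sample_id": list(z.sample_ids),
            "ts": ts.to_numpy(),
            "rs": rs.to_numpy(),
        }
    )
    table.attrs["genes_used"] = {
        "ts_up": ts_up,
        "ts_down": ts_down,
        "rs_up": rs_up,
        "rs_down": rs_down,
    }
    if not np.isfinite(table[["ts", "rs"]].to_numpy()).all():
        raise ValueError("non-finite scores computed")
    return table
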