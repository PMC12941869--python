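"""Two-group differential expression on log2 expression matrices.

Per gene: a two-sided two-sample t-test, Benjamini-Hochberg step-up
adjustment, and a significance call combining an inclusive fold-change
bound (|log2FC| >= log2(1.5) by default) with a strict FDR bound
(q < 0.05). Fold change is the difference of group means on the log2
scale.

The default statistic is the pooled-variance (Student) t: with the tiny
reference groups typical of tumor/normal designs (e.g. 154 vs 5) the
Welch-Satterthwaite degrees of freedom collapse toward the small group's
size and power suffers badly, whereas on a common log2 scale after
quantile normalization the equal-variance assumption is reasonable.
Welch's unequal-variance test is available via ``statistic="welch"`` for
cohorts where per-group variances genuinely differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, VALID_GROUPS

logger = logging.getLogger(__name__)

# variance floor guarding the Welch denominator for degenerate genes
_VAR_FLOOR = 1e-12

CONTRAST_GROUPS = {
    "tumor_vs_normal": ("primary", "normal"),
    "recurrent_vs_normal": ("recurrent", "normal"),
    "recurrent_vs_primary": ("recurrent", "primary"),
}


@dataclass
class ContrastResult:
    """Per-gene results of one two-group comparison.

    ``table`` columns: gene, log2fc (mean A - mean B, log2 scale), t, p, q,
    neglog10q, direction ({up, down, none}), passes, zero_var (True where
    a group had zero within-group variance and the floor applied).
    """

    name: str
    group_a: str
    group_b: str
    table: pd.DataFrame
    fc_threshold: float
    fdr: float

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def passing(self, direction: str | None = None) -> set[str]:
        t = self.table[self.table["passes"]]
        if direction is not None:
            t = t[t["direction"] == direction]
        return set(t["gene"])


def _group_arrays(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    return matrix.data[group_a].to_numpy(), matrix.data[group_b].to_numpy()


def welch_test(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Vectorized Welch t-test of group A vs group B for every gene.

    Returns a frame indexed by gene with columns ``t``, ``p``, ``df`` and
    ``zero_var``. Two-sided p-values use the Welch-Satterthwaite degrees of
    freedom. A gene with zero variance in both groups and equal means gets
    t=0, p=1; zero variances are floored at 1e-12 (flagged) so the
    statistic stays finite.
    """
    a, b = _group_arrays(matrix, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    zero_var = (va <= _VAR_FLOOR) | (vb <= _VAR_FLOOR)
    va = np.maximum(va, _VAR_FLOOR)
    vb = np.maximum(vb, _VAR_FLOOR)

    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"t": t, "p": p, "df": df, "zero_var": zero_var}, index=matrix.data.index
    )


def student_test(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Vectorized pooled-variance (Student) t-test; same schema as
    :func:`welch_test` with df = n_a + n_b - 2."""
    a, b = _group_arrays(matrix, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    zero_var = (va <= _VAR_FLOOR) | (vb <= _VAR_FLOOR)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    pooled = np.maximum(pooled, _VAR_FLOOR)
    t = (ma - mb) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    df = float(na + nb - 2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"t": t, "p": p, "df": df, "zero_var": zero_var}, index=matrix.data.index
    )


def bh_adjust(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    With p sorted ascending, q_(i) = min_{j >= i} p_(j) * m / j capped at 1,
    mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    # running min over the suffix (largest rank downwards), capped at 1
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_de(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    group_a: str,
    group_b: str,
    fc_threshold: float = 1.5,
    fdr: float = 0.05,
    name: str | None = None,
    statistic: str = "pooled",
) -> ContrastResult:
    """Run one contrast (group A vs group B) and call significance.

    A gene passes iff |log2fc| >= log2(fc_threshold) (inclusive) and
    q < fdr (strict). ``direction`` is "up"/"down" for passing genes by the
    sign of log2fc, "none" otherwise. ``statistic`` selects the per-gene
    test: ``"pooled"`` (default) or ``"welch"``.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (linear-scale fold change)")
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    for grp in (group_a, group_b):
        if grp not in VALID_GROUPS:
            raise ValueError(f"unknown group {grp!r}; allowed: {VALID_GROUPS}")
    ids_a = annotation.loc[annotation["group"] == group_a, "sample_id"].tolist()
    ids_b = annotation.loc[annotation["group"] == group_b, "sample_id"].tolist()
    absent = [g for g, ids in ((group_a, ids_a), (group_b, ids_b)) if not ids]
    if absent:
        raise ValueError(f"group(s) absent from annotation: {absent}")

    if statistic not in ("pooled", "welch"):
        raise ValueError(f"unknown statistic {statistic!r}; use 'pooled' or 'welch'")
    test_fn = student_test if statistic == "pooled" else welch_test
    wt = test_fn(matrix, ids_a, ids_b)
    log2fc = (
        matrix.data[ids_a].mean(axis=1) - matrix.data[ids_b].mean(axis=1)
    ).to_numpy()
    q = bh_adjust(wt["p"].to_numpy())
    log2_bound = np.log2(fc_threshold)
    passes = (np.abs(log2fc) >= log2_bound) & (q < fdr)
    direction = np.where(passes, np.where(log2fc > 0, "up", "down"), "none")
    with np.errstate(divide="ignore"):
        neglog10q = -np.log10(q)
    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "log2fc": log2fc,
            "t": wt["t"].to_numpy(),
            "p": wt["p"].to_numpy(),
            "q": q,
            "neglog10q": neglog10q,
            "direction": direction,
            "passes": passes,
            "zero_var": wt["zero_var"].to_numpy(),
        }
    )
    name = name or f"{group_a}_vs_{group_b}"
    logger.info(
        "contrast %s: %d up, %d down of %d genes (FC >= %g, FDR < %g)",
        name,
        int((direction == "up").sum()),
        int((direction == "down").sum()),
        len(table),
        fc_threshold,
        fdr,
    )
    return ContrastResult(
        name=name,
        group_a=group_a,
        group_b=group_b,
        table=table,
        fc_threshold=fc_threshold,
        fdr=fdr,
    )


def run_contrasts(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    fc_threshold: float = 1.5,
    fdr: float = 0.05,
    statistic: str = "pooled",
) -> dict[str, ContrastResult]:
    """The three study contrasts over a consistent gene universe.

    Returns ``tumor_vs_normal`` (primary vs normal), ``recurrent_vs_normal``
    and ``recurrent_vs_primary``. All three groups must be present.
    """
    present = set(annotation["group"])
    missing = set(VALID_GROUPS) - present
    if missing:
        raise ValueError(f"annotation lacks group(s): {sorted(missing)}")
    return {
        name: call_de(
            matrix, annotation, ga, gb, fc_threshold, fdr, name=name, statistic=statistic
        )
        for name, (ga, gb) in CONTRAST_GROUPS.items()
    }
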