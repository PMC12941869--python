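"""Threshold fitting and four-class assignment from TS/RS score tables.

The classification is hierarchical: the Tumor Score separates normal-like
samples (class 1) from tumor-like samples; among tumor-like samples the
Recurrence Score distinguishes the proliferative core (class 2, low RS),
a transitional state (class 3, intermediate RS) and a recurrence-adapted
aggressive state (class 4, high RS).

Thresholds are fitted by exact one-dimensional k-means: the optimal
partition of the sorted scores into k contiguous clusters is found by
dynamic programming (the Ckmeans.1d.dp formulation), which is
deterministic, permutation-invariant and immune to the local optima of
Lloyd iterations under heavily imbalanced cluster sizes. Cut points are
midpoints between adjacent sorted centroids. Fixed user-supplied
thresholds are supported as an escape hatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_NAMES = {
    1: "Normal-like",
    2: "Primary Tumor—Proliferative Core",
    3: "Primary Tumor—Transitional",
    4: "Recurrence-Adapted (Aggressive)",
}


@dataclass
class StratificationModel:
    """TS/RS decision boundaries.

    ``tau_ts`` separates normal-like from tumor-like; ``c_low < c_high``
    split tumor-like RS values into low/intermediate/high. ``method`` is
    ``data_driven`` (k-means fit) or ``fixed``.
    """

    tau_ts: float
    c_low: float
    c_high: float
    method: str = "data_driven"
    ts_centroids: tuple[float, ...] = ()
    rs_centroids: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in ("tau_ts", "c_low", "c_high"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.c_low < self.c_high:
            raise ValueError("c_low must be < c_high")


def kmeans_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Exact 1-D k-means: globally optimal centroids, sorted ascending.

    Sorts the values and finds the minimum within-cluster sum-of-squares
    partition into k contiguous segments by dynamic programming, using
    prefix sums for O(1) segment costs (O(k n^2) overall). Ties in the
    data cannot affect the result since the partition depends only on the
    sorted values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: int, j: int) -> float:
        # within-SS of x[i:j] (0-based, half-open)
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                val = cost[c - 1, i] + seg_cost(i, j)
                if val < best:
                    best, arg = val, i
            cost[c, j] = best
            split[c, j] = arg
    # recover segment boundaries
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[c, j]
        bounds.append(j)
    bounds = bounds[::-1]
    centroids = np.array(
        [x[bounds[i] : bounds[i + 1]].mean() for i in range(k)]
    )
    return centroids


def fit_thresholds(scores: pd.DataFrame) -> StratificationModel:
    """Fit tau_ts and (c_low, c_high) from a TS/RS score table.

    tau_ts is the midpoint of the two centroids of a 2-means clustering of
    all TS values; c_low/c_high are midpoints between adjacent sorted
    centroids of a 3-means clustering of RS restricted to tumor-like
    samples (ts >= tau_ts). With fewer than 3 tumor-like samples the RS
    cuts fall back to tertiles of all RS values, with a warning.
    """
    ts = scores["ts"].to_numpy(dtype=float)
    rs = scores["rs"].to_numpy(dtype=float)
    if ts.size < 4 or not np.isfinite(ts).all():
        raise ValueError("need >= 4 samples with finite TS")
    ts_centroids = kmeans_1d(ts, 2)
    tau_ts = float(ts_centroids.mean())

    rs_tumor = rs[ts >= tau_ts]
    if rs_tumor.size >= 3 and np.unique(rs_tumor).size >= 3:
        rs_centroids = kmeans_1d(rs_tumor, 3)
        c_low = float((rs_centroids[0] + rs_centroids[1]) / 2)
        c_high = float((rs_centroids[1] + rs_centroids[2]) / 2)
        method = "data_driven"
    else:
        logger.warning(
            "only %d tumor-like sample(s); falling back to fixed tertile RS cuts",
            rs_tumor.size,
        )
        c_low, c_high = (float(q) for q in np.quantile(rs, [1 / 3, 2 / 3]))
        if not c_low < c_high:  # degenerate spread
            c_low, c_high = c_low - 0.5, c_low + 0.5
        rs_centroids = np.array([])
        method = "fixed"
    model = StratificationModel(
        tau_ts=tau_ts,
        c_low=c_low,
        c_high=c_high,
        method=method,
        ts_centroids=tuple(ts_centroids),
        rs_centroids=tuple(rs_centroids),
    )
    logger.info(
        "fitted thresholds: tau_ts=%.4f, c_low=%.4f, c_high=%.4f (%s)",
        model.tau_ts,
        model.c_low,
        model.c_high,
        method,
    )
    return model


def assign_classes(scores: pd.DataFrame, model: StratificationModel) -> pd.DataFrame:
    """Assign every sample to one of the four classes.

    Boundary conventions: ts exactly at tau_ts is tumor-like; rs exactly at
    a cut belongs to the higher class. RS is recorded but never consulted
    for class-1 assignments.
    """
    ts = scores["ts"].to_numpy(dtype=float)
    rs = scores["rs"].to_numpy(dtype=float)
    if not (np.isfinite(ts).all() and np.isfinite(rs).all()):
        raise ValueError("non-finite score encountered")
    class_id = np.ones(ts.size, dtype=int)
    tumor = ts >= model.tau_ts
    class_id[tumor & (rs < model.c_low)] = 2
    class_id[tumor & (rs >= model.c_low) & (rs < model.c_high)] = 3
    class_id[tumor & (rs >= model.c_high)] = 4
    return pd.DataFrame(
        {
            "sample_id": scores["sample_id"].to_numpy(),
            "ts": ts,
            "rs": rs,
            "class_id": class_id,
            "class_name": [CLASS_NAMES[c] for c in class_id],
        }
    )


def stratification_report(
    assignment: pd.DataFrame, annotation: pd.DataFrame
) -> dict:
    """Class counts overall and cross-tabulated by sample group."""
    if set(assignment["sample_id"]) != set(annotation["sample_id"]):
        raise ValueError("assignment and annotation sample ids do not match")
    merged = assignment.merge(annotation, on="sample_id")
    counts = assignment["class_id"].value_counts().sort_index()
    crosstab = pd.crosstab(merged["group"], merged["class_id"])
    return {
        "class_counts": counts.to_dict(),
        "by_group": crosstab,
        "classes_observed": sorted(assignment["class_id"].unique().tolist()),
    }
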