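"""End-to-end pipeline driver and latent-class recovery evaluation.

``run_pipeline`` chains simulation (or loading), preprocessing, the three
differential contrasts, signature construction, TS/RS scoring and
four-class stratification, optionally writing every stage's output plus a
manifest. ``recovery_metrics`` scores an assignment against the latent
classes of a synthetic cohort (confusion matrix, accuracy, adjusted Rand
index, per-class recall).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io_formats, preprocess, scoring, stratify
from .differential import ContrastResult, run_contrasts
from .io_formats import ExpressionMatrix
from .signatures import GeneSignature, build_signature
from .synthetic_cohort import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

CLASS_LABELS = (1, 2, 3, 4)


@dataclass
class RecoveryReport:
    """Agreement between latent and assigned classes."""

    confusion: pd.DataFrame  # rows: latent class, columns: assigned class
    accuracy: float
    ari: float
    per_class_recall: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ari": self.ari,
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
            "confusion": self.confusion.to_dict(),
        }


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix  # preprocessed matrix all stages ran on
    annotation: pd.DataFrame
    contrasts: dict[str, ContrastResult]
    signatures: dict[str, GeneSignature]
    scores: pd.DataFrame
    model: stratify.StratificationModel
    assignment: pd.DataFrame
    report: dict
    recovery: RecoveryReport | None = None
    manifest: dict = field(default_factory=dict)


def recovery_metrics(
    truth: Sequence[int], assigned: pd.DataFrame | Sequence[int]
) -> RecoveryReport:
    """Confusion matrix, accuracy, ARI and per-class recall.

    ``assigned`` may be a ClassAssignment frame (its ``class_id`` column is
    used) or a plain label sequence aligned with ``truth``. ARI follows the
    permutation-model expectation correction; two identical single-class
    partitions score 1.0.
    """
    truth = np.asarray(truth, dtype=int)
    if isinstance(assigned, pd.DataFrame):
        assigned = assigned["class_id"].to_numpy()
    assigned = np.asarray(assigned, dtype=int)
    if truth.shape != assigned.shape:
        raise ValueError("truth and assignment lengths differ")
    for name, labels in (("truth", truth), ("assigned", assigned)):
        if not np.isin(labels, CLASS_LABELS).all():
            raise ValueError(f"{name} labels must be in 1..4")
    confusion = pd.crosstab(
        pd.Series(truth, name="latent"), pd.Series(assigned, name="assigned")
    ).reindex(index=CLASS_LABELS, columns=CLASS_LABELS, fill_value=0)
    accuracy = float((truth == assigned).mean())
    ari = float(adjusted_rand_score(truth, assigned))
    recall = {}
    for cls in CLASS_LABELS:
        total = int(confusion.loc[cls].sum())
        if total:
            recall[cls] = float(confusion.loc[cls, cls] / total)
    return RecoveryReport(
        confusion=confusion, accuracy=accuracy, ari=ari, per_class_recall=recall
    )


def _parse_inputs_config(config: dict) -> dict | SimulationConfig:
    """Validate the input side of a config up front (cheap, no simulation)."""
    paths = config.get("paths", {})
    if "expression" in paths:
        if "annotation" not in paths:
            raise ValueError("paths block needs both 'expression' and 'annotation'")
        return dict(paths)
    sim = dict(config.get("simulation", {}))
    sim.setdefault("seed", int(config.get("seed", 0)))
    return SimulationConfig.from_dict(sim)


def _build_inputs(
    inputs: dict | SimulationConfig, config: dict
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    if isinstance(inputs, SimulationConfig):
        cohort = simulate_cohort(inputs)
        return cohort.matrix, cohort.annotation
    matrix = io_formats.load_expression(
        inputs["expression"],
        missing_policy=config.get("missing_policy", "reject"),
    )
    annotation = io_formats.load_annotation(inputs["annotation"])
    return matrix, annotation


def run_pipeline(
    config: dict | str | Path, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the full stratification chain from a config.

    The config either carries a ``simulation`` block (synthetic cohort,
    seeded by the top-level ``seed``) or a ``paths`` block pointing at an
    expression matrix and annotation. A ``thresholds`` block may override
    filtering, fold-change/FDR and fixed TS/RS cut points. Deterministic
    given the seed; each stage is timed and logged, and any stage error
    aborts with a stage-named message.
    """
    if not isinstance(config, dict):
        config = io_formats.load_config(config)
    inputs_cfg = _parse_inputs_config(config)  # validation errors surface here
    thresholds = config.get("thresholds", {})
    manifest: dict = {"stages": {}, "seed": config.get("seed", 0)}
    t_all = time.perf_counter()

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 4)}
        return result

    matrix, annotation = stage("inputs", _build_inputs, inputs_cfg, config)
    n_raw = matrix.n_genes

    filtered = stage(
        "filter",
        preprocess.filter_genes,
        matrix,
        thresholds.get("min_median", 1.0),
        thresholds.get("min_sd", 0.1),
    )
    manifest["stages"]["filter"]["genes_removed"] = n_raw - filtered.n_genes
    if thresholds.get("skip_quantile_normalization", False):
        norm = filtered
    else:
        norm = stage("quantile_normalize", preprocess.quantile_normalize, filtered)
    n_qc = min(3, min(norm.n_genes, norm.n_samples))
    qc = stage("pca_qc", preprocess.pca_variance, norm, n_qc)
    manifest["pca_variance_fractions"] = [float(v) for v in qc]

    contrasts = stage(
        "contrasts",
        run_contrasts,
        norm,
        annotation,
        thresholds.get("fc_threshold", 1.5),
        thresholds.get("fdr", 0.05),
        thresholds.get("statistic", "pooled"),
    )
    # DE counts are logged so runs on real cohorts can be compared externally
    manifest["de_counts"] = {
        name: {
            "up": len(res.passing("up")),
            "down": len(res.passing("down")),
        }
        for name, res in contrasts.items()
    }

    signatures = {
        name: stage(f"signature:{name}", build_signature, contrasts[name])
        for name in ("tumor_vs_normal", "recurrent_vs_primary")
    }
    scores = stage(
        "scores",
        scoring.compute_ts_rs,
        norm,
        signatures["tumor_vs_normal"],
        signatures["recurrent_vs_primary"],
    )
    if {"tau_ts", "c_low", "c_high"} <= set(thresholds):
        model = stratify.StratificationModel(
            tau_ts=float(thresholds["tau_ts"]),
            c_low=float(thresholds["c_low"]),
            c_high=float(thresholds["c_high"]),
            method="fixed",
        )
    else:
        model = stage("fit_thresholds", stratify.fit_thresholds, scores)
    assignment = stage("assign", stratify.assign_classes, scores, model)
    report = stage("report", stratify.stratification_report, assignment, annotation)

    recovery = None
    if "latent_class" in annotation.columns and annotation["latent_class"].notna().all():
        aligned = annotation.set_index("sample_id").loc[
            assignment["sample_id"], "latent_class"
        ]
        recovery = stage(
            "recovery", recovery_metrics, aligned.to_numpy(dtype=int), assignment
        )
        manifest["recovery"] = {"accuracy": recovery.accuracy, "ari": recovery.ari}

    manifest["class_counts"] = {str(k): int(v) for k, v in report["class_counts"].items()}
    manifest["total_seconds"] = round(time.perf_counter() - t_all, 4)

    result = PipelineResult(
        matrix=norm,
        annotation=annotation,
        contrasts=contrasts,
        signatures=signatures,
        scores=scores,
        model=model,
        assignment=assignment,
        report=report,
        recovery=recovery,
        manifest=manifest,
    )
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every stage output plus a JSON manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_expression(result.matrix, out / "expression_preprocessed.tsv")
    io_formats.write_annotation(result.annotation, out / "annotation.tsv")
    for name, contrast in result.contrasts.items():
        io_formats.write_results(contrast.table, out / f"contrast_{name}.tsv")
    for name, sig in result.signatures.items():
        io_formats.write_gene_sets(sig.to_collection(), out / f"signature_{name}.gmt")
    io_formats.write_results(result.scores, out / "scores.tsv")
    io_formats.write_results(result.assignment, out / "assignment.tsv")
    crosstab = result.report["by_group"].reset_index()
    io_formats.write_results(crosstab, out / "class_by_group.tsv", sort_by="group")
    manifest = dict(result.manifest)
    manifest["model"] = {
        "tau_ts": result.model.tau_ts,
        "c_low": result.model.c_low,
        "c_high": result.model.c_high,
        "method": result.model.method,
    }
    if result.recovery is not None:
        manifest["recovery"] = result.recovery.to_dict()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("artifacts written to %s", out)
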