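"""Synthetic bulk-expression cohorts with a latent four-state structure.

The generator emulates a glioblastoma study design: a small set of normal
brain samples, a large primary-tumor group and a handful of recurrent
tumors (default 5 / 154 / 13). Every sample carries a latent biological
class:

1. normal-like, 2. proliferative core, 3. transitional,
4. recurrence-adapted (aggressive).

Expression is additive Gaussian on the log2 scale:

    x[g, s] = mu_g + effect(panel(g), class(s)) + eps,   eps ~ N(0, sigma^2)

with per-gene baselines ``mu_g ~ N(baseline_mean, baseline_sd^2)`` floored
at zero. Five marker panels carry the class signal; panel gene lists start
with canonical marker symbols (GRIN1/SYN2... neuronal, MYBL2/TOP2A...
cell-cycle, CCL18/CD209... immune, OLIG1/OLIG2... proneural) and are padded
with synthetic names up to the configured sizes. All remaining genes are
null (no class effect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, validate_annotation

logger = logging.getLogger(__name__)

PANEL_NAMES = (
    "neuronal",
    "proliferative",
    "transitional_ecm",
    "recurrence_immune_ecm",
    "proneural",
)

# Marker symbols seeding each panel, in the directions the four classes
# are defined by: neuronal/synaptic genes high in normal brain, cell-cycle
# genes high in tumor, immune/ECM genes high in recurrence-adapted samples,
# proneural lineage genes lost in recurrence-adapted samples.
PANEL_MARKERS: dict[str, tuple[str, ...]] = {
    "neuronal": ("GRIN1", "PRKCG", "RYR2", "GABRA5", "SLC17A7", "NEFM", "SYN2", "C1QL3"),
    "proliferative": ("MYBL2", "UBE2C", "TOP2A", "RRM2", "PBK", "DLGAP5", "CCNB2", "BIRC5"),
    "transitional_ecm": ("HAS1", "COL6A3"),
    "recurrence_immune_ecm": ("CCL18", "CCL13", "CD209", "CR1", "LILRB5", "LYVE1", "PAPPA"),
    "proneural": ("OLIG1", "OLIG2", "BCAN", "ARC", "HES6", "SLITRK3"),
}

CLASSES = (1, 2, 3, 4)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort design and effect structure for :func:`simulate_cohort`.

    Sample counts default to the study design (5 normal, 154 primary,
    13 recurrent). Effect sizes (``delta_tumor``, ``delta_recurrence``) and
    noise (``sigma``) are in log2 units. ``transitional_fraction_of_effect``
    scales the partial (class-3) effects. ``primary_state_fractions`` and
    ``recurrent_state_fractions`` give the latent-class mixture within the
    primary (classes 2/3/4) and recurrent (classes 3/4) groups.
    """

    n_normal: int = 5
    n_primary: int = 154
    n_recurrent: int = 13
    n_genes: int = 5000
    panel_sizes: dict[str, int] = field(
        default_factory=lambda: {name: 50 for name in PANEL_NAMES}
    )
    delta_tumor: float = 2.0
    delta_recurrence: float = 2.0
    transitional_fraction_of_effect: float = 0.5
    sigma: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    primary_state_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    recurrent_state_fractions: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name in ("n_normal", "n_primary", "n_recurrent", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if set(self.panel_sizes) != set(PANEL_NAMES):
            raise ValueError(f"panel_sizes must have keys {PANEL_NAMES}")
        if any(size <= 0 for size in self.panel_sizes.values()):
            raise ValueError("panel sizes must be positive")
        if sum(self.panel_sizes.values()) > self.n_genes:
            raise ValueError("panels jointly exceed n_genes")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 < self.transitional_fraction_of_effect < 1:
            raise ValueError("transitional_fraction_of_effect must be in (0,1)")
        for name in ("primary_state_fractions", "recurrent_state_fractions"):
            fr = getattr(self, name)
            if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        return self

    @staticmethod
    def from_dict(d: dict) -> "SimulationConfig":
        cfg = SimulationConfig()
        known = set(cfg.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for tup in ("primary_state_fractions", "recurrent_state_fractions"):
            if tup in d:
                d[tup] = tuple(d[tup])
        if "panel_sizes" in d:
            d["panel_sizes"] = {**{n: 50 for n in PANEL_NAMES}, **d["panel_sizes"]}
        return replace(cfg, **d).validate()


@dataclass
class SimulatedCohort:
    """A simulated matrix plus its ground truth.

    ``annotation`` carries the latent class of every sample; ``panels`` maps
    each panel name to its gene list (a subset of the matrix genes);
    ``effects`` holds the expected mean shift of each (panel, class) pair.
    """

    matrix: ExpressionMatrix
    annotation: pd.DataFrame
    panels: dict[str, list[str]]
    effects: pd.DataFrame  # index: panel, columns: class 1..4
    config: SimulationConfig

    @property
    def null_genes(self) -> list[str]:
        in_panel = set().union(*(set(v) for v in self.panels.values()))
        return [g for g in self.matrix.gene_ids if g not in in_panel]


def class_effect(config: SimulationConfig, panel: str, latent_class: int) -> float:
    """Expected mean shift (log2 units, relative to the gene baseline)."""
    dt, dr = config.delta_tumor, config.delta_recurrence
    f = config.transitional_fraction_of_effect
    if panel == "neuronal":
        return dt if latent_class == 1 else 0.0
    if panel == "proliferative":
        return dt if latent_class >= 2 else 0.0
    if panel == "transitional_ecm":
        return f * dr if latent_class >= 3 else 0.0
    if panel == "recurrence_immune_ecm":
        return {3: f * dr, 4: dr}.get(latent_class, 0.0)
    if panel == "proneural":
        return {3: -f * dr, 4: -dr}.get(latent_class, 0.0)
    raise ValueError(f"unknown panel {panel!r}")


def _largest_remainder_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion n among classes by largest remainder (deterministic)."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _panel_gene_names(config: SimulationConfig) -> dict[str, list[str]]:
    panels: dict[str, list[str]] = {}
    for name in PANEL_NAMES:
        size = config.panel_sizes[name]
        markers = list(PANEL_MARKERS[name])[:size]
        tag = name.upper()
        padded = markers + [
            f"{tag}_SYN{i:04d}" for i in range(1, size - len(markers) + 1)
        ]
        panels[name] = padded
    return panels


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Draw one cohort from the additive-Gaussian four-state model.

    Deterministic for a fixed config (including ``seed``): two calls with
    the same config produce bit-identical matrices.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed)

    panels = _panel_gene_names(config)
    panel_genes = [g for name in PANEL_NAMES for g in panels[name]]
    n_null = config.n_genes - len(panel_genes)
    gene_ids = panel_genes + [f"NULL_SYN{i:05d}" for i in range(1, n_null + 1)]

    # samples and latent classes: normal -> 1, primary -> {2,3,4},
    # recurrent -> {3,4}; within-group allocation is deterministic
    sample_ids: list[str] = []
    groups: list[str] = []
    latent: list[int] = []
    sample_ids += [f"TN_{i:03d}" for i in range(1, config.n_normal + 1)]
    groups += ["normal"] * config.n_normal
    latent += [1] * config.n_normal
    p_counts = _largest_remainder_counts(config.n_primary, config.primary_state_fractions)
    sample_ids += [f"TT_{i:03d}" for i in range(1, config.n_primary + 1)]
    groups += ["primary"] * config.n_primary
    for cls, cnt in zip((2, 3, 4), p_counts):
        latent += [cls] * cnt
    r_counts = _largest_remainder_counts(config.n_recurrent, config.recurrent_state_fractions)
    sample_ids += [f"TR_{i:03d}" for i in range(1, config.n_recurrent + 1)]
    groups += ["recurrent"] * config.n_recurrent
    for cls, cnt in zip((3, 4), r_counts):
        latent += [cls] * cnt

    n_genes, n_samples = len(gene_ids), len(sample_ids)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    baseline = np.maximum(baseline, 0.0)  # floor: no negative log2 intensities

    effect = np.zeros((n_genes, n_samples))
    row = 0
    for name in PANEL_NAMES:
        size = config.panel_sizes[name]
        shifts = np.array([class_effect(config, name, c) for c in latent])
        effect[row : row + size, :] = shifts[np.newaxis, :]
        row += size

    values = (
        baseline[:, np.newaxis]
        + effect
        + rng.normal(0.0, config.sigma, size=(n_genes, n_samples))
    )
    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))

    annotation = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "latent_class": latent}
    )
    annotation["latent_class"] = annotation["latent_class"].astype("Int64")
    validate_annotation(annotation)

    effects = pd.DataFrame(
        {c: [class_effect(config, p, c) for p in PANEL_NAMES] for c in CLASSES},
        index=list(PANEL_NAMES),
    )
    logger.info(
        "simulated cohort: %d genes x %d samples (classes: %s)",
        n_genes,
        n_samples,
        annotation["latent_class"].value_counts().sort_index().to_dict(),
    )
    return SimulatedCohort(
        matrix=matrix,
        annotation=annotation,
        panels=panels,
        effects=effects,
        config=config,
    )


def truth_report(cohort: SimulatedCohort) -> pd.DataFrame:
    """Long-form table of expected mean shifts, one row per (panel, class).

    Shifts are relative to the per-gene baseline; recovery tests compare
    empirical panel means against these values.
    """
    rows = [
        {
            "panel": panel,
            "latent_class": cls,
            "expected_shift": cohort.effects.loc[panel, cls],
            "n_genes": len(cohort.panels[panel]),
        }
        for panel in PANEL_NAMES
        for cls in CLASSES
    ]
    return pd.DataFrame(rows)
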