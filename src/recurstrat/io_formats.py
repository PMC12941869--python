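"""Readers, writers and validated containers for every external format the
pipeline touches.

Conventions
-----------
* Expression matrices are genes-in-rows, samples-in-columns, tab-separated,
  UTF-8, with values on a log2 scale after preprocessing.
* Sample annotations are two/three-column TSV: ``sample_id``, ``group``
  (one of ``normal``/``primary``/``recurrent``) and an optional
  ``latent_class`` column (1-4), present only for synthetic cohorts.
* Gene sets use the standard GMT dialect: one set per line as
  ``name<TAB>description<TAB>member1<TAB>member2...``.
* Configs are YAML with ``simulation``, ``thresholds``, ``paths`` blocks and
  a top-level ``seed``.

Gene identifiers are opaque, case-sensitive strings (HGNC symbols in
practice); no identifier mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_GROUPS = ("normal", "primary", "recurrent")


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene
    identifiers and whose columns hold unique sample identifiers. The frame
    is validated on construction: duplicates and missing values are rejected
    (missingness is handled at load time, never silently imputed).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        if self.data.isna().any().any():
            bad = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise ValidationError(
                f"missing values in rows for genes {bad[:5]} after loading"
            )
        # enforce a float matrix once so downstream numerics never re-coerce
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[genes])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions.

    ``sets`` preserves insertion order; every set is non-empty and names are
    unique (dict keys).
    """

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation frame (sample_id, group[, latent_class])."""
    required = {"sample_id", "group"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    if annotation["sample_id"].duplicated().any():
        dups = annotation.loc[annotation["sample_id"].duplicated(), "sample_id"]
        raise ValidationError(f"duplicate sample ids in annotation: {dups.tolist()[:5]}")
    bad = set(annotation["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValidationError(
            f"unknown group labels {sorted(bad)}; allowed: {VALID_GROUPS}"
        )
    if "latent_class" in annotation.columns:
        cls = annotation["latent_class"].dropna()
        if not cls.isin([1, 2, 3, 4]).all():
            raise ValidationError("latent_class values must be in 1..4")
    return annotation


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def load_expression(
    path: str | Path,
    delimiter: str = "\t",
    missing_policy: str = "reject",
) -> ExpressionMatrix:
    """Load a genes x samples expression table.

    The first column holds gene identifiers, the header row sample
    identifiers. ``missing_policy`` is ``"reject"`` (default: any missing or
    non-numeric cell is an error) or ``"drop-gene"`` (rows containing
    missing values are dropped with a warning).

    Raises :class:`ValidationError` with row/column context for a missing
    file, duplicated identifiers, non-numeric cells or ragged rows.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"expression file not found: {path}")
    if missing_policy not in ("reject", "drop-gene"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValidationError(f"malformed table in {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(
            f"duplicate gene identifiers in {path}: {dups[:5]} "
            "(duplicates are rejected, never aggregated)"
        )
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample identifiers in {path}: {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # cells that were present but not parseable as numbers
    bad_cells = numeric.isna() & df.notna()
    na_rows = numeric.isna().any(axis=1)
    if missing_policy == "reject":
        if na_rows.any():
            gene = numeric.index[na_rows][0]
            col = numeric.columns[numeric.loc[gene].isna()][0]
            kind = "non-numeric" if bad_cells.loc[gene, col] else "missing"
            raise ValidationError(
                f"{kind} value at gene {gene!r}, sample {col!r} in {path}"
            )
    else:
        if bad_cells.any().any():
            gene = numeric.index[bad_cells.any(axis=1)][0]
            col = numeric.columns[bad_cells.loc[gene]][0]
            raise ValidationError(
                f"non-numeric value at gene {gene!r}, sample {col!r} in {path}"
            )
        if na_rows.any():
            dropped = numeric.index[na_rows].tolist()
            logger.warning(
                "dropping %d gene row(s) with missing values: %s",
                len(dropped),
                dropped[:10],
            )
            numeric = numeric.loc[~na_rows]
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV (genes in rows, repr-exact floats)."""
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def load_annotation(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep=delimiter)
    if "latent_class" in df.columns:
        df["latent_class"] = df["latent_class"].astype("Int64")
    return validate_annotation(df)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annotation)
    annotation.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def load_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>members...`` per line.

    Duplicate members within a line are deduplicated with a warning;
    duplicate set names or lines with fewer than three fields are errors.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"gene set file not found: {path}")
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = set(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %r contains repeated members; deduplicated",
                    path,
                    lineno,
                    name,
                )
            sets[name] = unique
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a GMT file with members in sorted order (deterministic output)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# Result tables and configs
# ---------------------------------------------------------------------------


def write_results(table: pd.DataFrame, path: str | Path, sort_by: str | None = None) -> None:
    """Write a result table as TSV with a deterministic row ordering.

    If ``sort_by`` is omitted the first column named ``gene`` or
    ``sample_id`` (if any) defines the order; floats are written with
    round-trip-exact precision so a reload reproduces the table.
    """
    out = table.copy()
    if sort_by is None:
        for candidate in ("gene", "sample_id"):
            if candidate in out.columns:
                sort_by = candidate
                break
    if sort_by is not None:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"result table not found: {path}")
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Load a YAML config with ``simulation``/``thresholds``/``paths``/``seed``."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValidationError(f"config root must be a mapping, got {type(cfg).__name__}")
    return dict(cfg)
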