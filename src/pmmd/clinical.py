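"""Clinical tabular preparation.

The clinical schema has one continuous variable (age), one unordered
category (gender), one ordinal (education level) and seven binary symptom
indicators.  Preparation runs outlier flagging (robust z on median/MAD,
flagged cells become missing), imputation (median / mode), then
standardization and encoding (z-score continuous and ordinal columns,
full one-hot for unordered categories, binary indicators passed through
as 0/1).  All statistics are fitted on training rows and carried in a
:class:`ClinicalTransform` that is reapplied verbatim to test rows, so no
test information leaks into the fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SYMPTOM_COLUMNS

__all__ = [
    "ColumnSchema",
    "ClinicalTransform",
    "UnimputableColumnError",
    "flag_outliers",
    "impute",
    "standardize_encode",
    "fit_clinical_transform",
]


class UnimputableColumnError(ValueError):
    """A column is entirely missing, so no imputation statistic exists."""


@dataclass(frozen=True)
class ColumnSchema:
    """Column typing for the clinical table."""

    continuous: tuple[str, ...] = ("age",)
    ordinal: tuple[str, ...] = ("education_level",)
    categorical: tuple[str, ...] = ("gender",)
    binary: tuple[str, ...] = tuple(SYMPTOM_COLUMNS)

    @property
    def all_feature_columns(self) -> tuple[str, ...]:
        return self.continuous + self.ordinal + self.categorical + self.binary


DEFAULT_SCHEMA = ColumnSchema()

# MAD -> SD consistency constant for normal data
_MAD_SCALE = 0.6745


def flag_outliers(
    table: pd.DataFrame,
    z_threshold: float = 3.5,
    schema: ColumnSchema = DEFAULT_SCHEMA,
    stats: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Flag gross outliers in continuous columns as missing.

    Cells with robust z-score ``|0.6745 * (x - median) / MAD|`` above
    ``z_threshold`` are set to NaN (elimination by conversion: the row
    survives).  Columns with MAD 0 or fewer than 3 observed values are
    skipped.  ``stats`` carries (median, MAD) pairs fitted elsewhere
    (test-time reuse); the fitted pairs are returned.
    """
    out = table.copy()
    fitted: dict[str, tuple[float, float]] = {}
    for col in schema.continuous:
        if col not in out.columns:
            continue
        x = pd.to_numeric(out[col], errors="coerce")
        if stats is not None and col in stats:
            med, mad = stats[col]
        else:
            obs = x.dropna()
            if len(obs) < 3:
                continue
            med = float(obs.median())
            mad = float((obs - med).abs().median())
        fitted[col] = (med, mad)
        if mad == 0:
            continue
        z = _MAD_SCALE * (x - med) / mad
        out.loc[z.abs() > z_threshold, col] = np.nan
    return out, fitted


def impute(
    table: pd.DataFrame,
    schema: ColumnSchema = DEFAULT_SCHEMA,
    stats: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fill missing cells: median for continuous, mode elsewhere.

    Mode ties resolve to the smallest value.  A column that is entirely
    missing (and has no supplied statistic) raises
    :class:`UnimputableColumnError`.
    """
    out = table.copy()
    fitted: dict[str, float] = {}
    for col in schema.all_feature_columns:
        if col not in out.columns:
            continue
        if col in schema.categorical:
            series = out[col]
        else:
            series = pd.to_numeric(out[col], errors="coerce")
        if stats is not None and col in stats:
            fill = stats[col]
        else:
            obs = series.dropna()
            if obs.empty:
                raise UnimputableColumnError(f"column {col!r} is entirely missing")
            if col in schema.continuous:
                fill = float(obs.median())
            else:
                fill = sorted(obs.mode().tolist())[0]
        fitted[col] = fill
        out[col] = series.fillna(fill)
    return out, fitted


@dataclass
class ClinicalTransform:
    """Fitted preparation state, reapplied unchanged to test rows."""

    schema: ColumnSchema
    z_threshold: float
    outlier_stats: dict[str, tuple[float, float]]
    impute_stats: dict[str, float]
    scale_stats: dict[str, tuple[float, float]]   # column -> (mean, sd)
    categories: dict[str, list]                   # column -> training levels
    feature_names: list[str] = field(default_factory=list)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        """Transform rows into the numeric feature frame."""
        flagged, _ = flag_outliers(table, self.z_threshold, self.schema,
                                   stats=self.outlier_stats)
        filled, _ = impute(flagged, self.schema, stats=self.impute_stats)
        cols: dict[str, np.ndarray] = {}
        for col in self.schema.continuous + self.schema.ordinal:
            mean, sd = self.scale_stats[col]
            x = pd.to_numeric(filled[col], errors="coerce").to_numpy(dtype=float)
            cols[col] = (x - mean) / (sd if sd > 0 else 1.0)
        for col in self.schema.categorical:
            levels = self.categories[col]
            values = filled[col].astype(str)
            known = values.isin([str(lv) for lv in levels])
            if not known.all():
                warnings.warn(
                    f"unseen {col!r} categories mapped to 'unknown'", stacklevel=2
                )
            for lv in levels:
                cols[f"{col}={lv}"] = (values == str(lv)).to_numpy(dtype=float)
            cols[f"{col}=unknown"] = (~known).to_numpy(dtype=float)
        for col in self.schema.binary:
            cols[col] = pd.to_numeric(filled[col], errors="coerce").to_numpy(dtype=float)
        out = pd.DataFrame(cols, index=table.index)[self.feature_names]
        if out.isna().any().any() or not np.isfinite(out.to_numpy()).all():
            raise ValueError("transformed clinical features contain non-finite values")
        return out

    # ------------------------------------------------------------- state I/O
    def save(self, path: str | Path) -> None:
        payload = {
            "z_threshold": self.z_threshold,
            "outlier_stats": self.outlier_stats,
            "impute_stats": self.impute_stats,
            "scale_stats": self.scale_stats,
            "categories": self.categories,
            "feature_names": self.feature_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))

    @classmethod
    def load(cls, path: str | Path, schema: ColumnSchema = DEFAULT_SCHEMA
             ) -> "ClinicalTransform":
        raw = json.loads(Path(path).read_text())
        return cls(
            schema=schema,
            z_threshold=raw["z_threshold"],
            outlier_stats={k: tuple(v) for k, v in raw["outlier_stats"].items()},
            impute_stats=raw["impute_stats"],
            scale_stats={k: tuple(v) for k, v in raw["scale_stats"].items()},
            categories=raw["categories"],
            feature_names=raw["feature_names"],
        )


def fit_clinical_transform(
    train: pd.DataFrame,
    z_threshold: float = 3.5,
    schema: ColumnSchema = DEFAULT_SCHEMA,
) -> ClinicalTransform:
    """Fit the full preparation pipeline on training rows only."""
    flagged, outlier_stats = flag_outliers(train, z_threshold, schema)
    filled, impute_stats = impute(flagged, schema)
    scale_stats: dict[str, tuple[float, float]] = {}
    for col in schema.continuous + schema.ordinal:
        x = pd.to_numeric(filled[col], errors="coerce").to_numpy(dtype=float)
        scale_stats[col] = (float(x.mean()), float(x.std()))
    categories = {
        col: sorted(filled[col].astype(str).unique().tolist())
        for col in schema.categorical
    }
    names: list[str] = list(schema.continuous + schema.ordinal)
    for col in schema.categorical:
        names.extend(f"{col}={lv}" for lv in categories[col])
        names.append(f"{col}=unknown")
    names.extend(schema.binary)
    return ClinicalTransform(
        schema=schema,
        z_threshold=z_threshold,
        outlier_stats=outlier_stats,
        impute_stats=impute_stats,
        scale_stats=scale_stats,
        categories=categories,
        feature_names=names,
    )


def standardize_encode(
    table: pd.DataFrame,
    transform: ClinicalTransform | None = None,
    z_threshold: float = 3.5,
    schema: ColumnSchema = DEFAULT_SCHEMA,
) -> tuple[pd.DataFrame, ClinicalTransform]:
    """Encode a table, fitting the transform when none is supplied."""
    if transform is None:
        transform = fit_clinical_transform(table, z_threshold, schema)
    return transform.apply(table), transform
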