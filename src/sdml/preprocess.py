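"""Preprocessing: imputation, 1.5-IQR target trimming, skew transforms, encoding.

The fixed pipeline order is impute -> trim -> transform -> encode. Imputation
is round-robin random-forest regression (each incomplete column regressed on
all others, iterated to tolerance). Outlier rows are removed when the target
falls outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` with linearly interpolated
quartiles. Continuous columns whose adjusted Fisher–Pearson sample skewness
exceeds the threshold (default 1.0) are replaced by ``log10(x + shift)`` with
``shift = max(0, eps - min(x))``. Categorical labels are mapped to integer
codes in order of first appearance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .config import PreprocessConfig
from .data import CATEGORICAL, FeatureTable, InsufficientDataError

logger = logging.getLogger("sdml")


class UnimputableError(ValueError):
    """A column (or every column) is entirely missing."""


@dataclass
class ColumnReport:
    n_imputed: int = 0
    n_trimmed: int = 0
    skewness_before: float | None = None
    skewness_after: float | None = None
    transform_applied: str = "none"      # none | log10
    shift: float = 0.0
    encoding: list | None = None         # label order for categorical columns


@dataclass
class PreprocessReport:
    columns: dict[str, ColumnReport] = field(default_factory=dict)
    n_rows_in: int = 0
    n_rows_out: int = 0

    def column(self, name: str) -> ColumnReport:
        return self.columns.setdefault(name, ColumnReport())

    @property
    def n_trimmed(self) -> int:
        return self.n_rows_in - self.n_rows_out


def sample_skewness(x: np.ndarray) -> float:
    """Adjusted Fisher–Pearson sample skewness (bias-corrected)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3 or np.ptp(x) == 0:
        return 0.0
    return float(stats.skew(x, bias=False))


# ------------------------------------------------------------------ impute

def impute_missing(
    table: FeatureTable,
    seed: int = 0,
    max_rounds: int = 10,
    n_trees: int = 100,
    tol: float = 1e-3,
) -> tuple[FeatureTable, PreprocessReport]:
    """Fill NaN cells by iterative random-forest regression.

    Each incomplete column is regressed on all others and re-predicted,
    round-robin, until the largest change falls below ``tol`` (scaled) or
    ``max_rounds`` is reached. Deterministic for a fixed seed.
    """
    df = table.data
    report = PreprocessReport(n_rows_in=len(df), n_rows_out=len(df))
    numeric = [c for c in df.columns if df[c].dtype.kind in "fi"]
    missing_counts = df[numeric].isna().sum()
    for col in numeric:
        report.column(col).n_imputed = int(missing_counts[col])
    if missing_counts.sum() == 0:
        return table, report
    fully_missing = [c for c in numeric if df[c].isna().all()]
    if fully_missing:
        raise UnimputableError(f"columns entirely missing: {fully_missing}")
    if not any(df[c].notna().all() for c in numeric):
        raise UnimputableError("no fully observed column to anchor imputation")

    imputer = IterativeImputer(
        estimator=RandomForestRegressor(n_estimators=n_trees, random_state=seed),
        max_iter=max_rounds,
        tol=tol,
        random_state=seed,
        sample_posterior=False,
    )
    filled = imputer.fit_transform(df[numeric].to_numpy(float))
    out = df.copy()
    out[numeric] = filled
    # keep categorical codes integral after regression imputation
    for col in table.categorical_features:
        if col in numeric:
            out[col] = np.rint(out[col]).clip(lower=0).astype(int)
    logger.info("impute_missing: filled %d cells", int(missing_counts.sum()))
    return table.with_data(out), report


# -------------------------------------------------------------------- trim

def trim_outliers(table: FeatureTable) -> tuple[FeatureTable, PreprocessReport]:
    """Drop rows whose target lies outside the 1.5-IQR fences.

    Quartiles use linear interpolation; with IQR = 0 nothing is strictly
    outside ``[Q1, Q3]`` so nothing is removed.
    """
    if table.target_name is None:
        raise ValueError("trim_outliers requires a target column")
    if table.n_rows < 4:
        raise InsufficientDataError("need at least 4 rows to estimate quartiles")
    y = table.y.to_numpy(float)
    q1, q3 = np.percentile(y, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (y >= lo) & (y <= hi)
    report = PreprocessReport(n_rows_in=len(y), n_rows_out=int(keep.sum()))
    report.column(table.target_name).n_trimmed = int((~keep).sum())
    out = table.with_data(table.data.loc[keep].reset_index(drop=True))
    logger.info("trim_outliers: removed %d of %d rows", int((~keep).sum()), len(y))
    return out, report


# --------------------------------------------------------------- transform

def transform_skewed(
    table: FeatureTable,
    skew_threshold: float = 1.0,
    epsilon: float = 1e-6,
) -> tuple[FeatureTable, PreprocessReport]:
    """Replace strongly right-skewed continuous columns by log10(x + shift)."""
    df = table.data.copy()
    report = PreprocessReport(n_rows_in=len(df), n_rows_out=len(df))
    cols = list(table.continuous_features)
    if table.target_name is not None:
        cols.append(table.target_name)
    for col in cols:
        x = df[col].to_numpy(float)
        sk = sample_skewness(x)
        rep = report.column(col)
        rep.skewness_before = sk
        if sk > skew_threshold:
            shift = max(0.0, epsilon - np.nanmin(x))
            df[col] = np.log10(x + shift)  # shift guarantees x + shift >= eps > 0
            rep.transform_applied = "log10"
            rep.shift = shift
            rep.skewness_after = sample_skewness(df[col].to_numpy(float))
        else:
            rep.skewness_after = sk
    return table.with_data(df), report


# ------------------------------------------------------------------ encode

def encode_categories(table: FeatureTable) -> tuple[FeatureTable, PreprocessReport]:
    """Map categorical labels to integer codes in order of first appearance."""
    df = table.data.copy()
    report = PreprocessReport(n_rows_in=len(df), n_rows_out=len(df))
    out = table.with_data(df)
    maps = dict(table.category_maps)
    for col in table.categorical_features:
        values = df[col]
        if values.dtype.kind in "iu" and (values.dropna() >= 0).all():
            report.column(col).encoding = maps.get(col)
            continue  # already integer codes
        labels = list(dict.fromkeys(values.dropna().tolist()))
        code_of = {lab: i for i, lab in enumerate(labels)}
        df[col] = values.map(code_of)
        maps[col] = labels
        report.column(col).encoding = labels
    out.category_maps = maps
    return out, report


def decode_categories(table: FeatureTable) -> FeatureTable:
    """Inverse of :func:`encode_categories` using the stored label maps."""
    df = table.data.copy()
    for col, labels in table.category_maps.items():
        df[col] = df[col].map(lambda code: labels[int(code)])
    out = table.with_data(df)
    out.category_maps = {}
    return out


# ---------------------------------------------------------------- pipeline

def preprocess_table(
    table: FeatureTable,
    config: PreprocessConfig | None = None,
    seed: int = 0,
) -> tuple[FeatureTable, list[PreprocessReport]]:
    """Run the fixed pipeline impute -> trim -> transform -> encode."""
    config = config or PreprocessConfig()
    reports = []
    t, rep = impute_missing(
        table, seed=seed, max_rounds=config.imputer_max_rounds,
        n_trees=config.imputer_trees, tol=config.imputer_tol,
    )
    reports.append(rep)
    t, rep = trim_outliers(t)
    reports.append(rep)
    t, rep = transform_skewed(t, skew_threshold=config.skew_threshold, epsilon=config.log_shift_epsilon)
    reports.append(rep)
    t, rep = encode_categories(t)
    reports.append(rep)
    return t, reports
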