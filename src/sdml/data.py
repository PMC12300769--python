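"""Tabular data model, CSV I/O and train/test splitting.

The universal currency of every stage is a :class:`FeatureTable`: a pandas
DataFrame of molecular descriptors (molecular weight, log Kow, pKa, TPSA, ...),
exposure covariates (exposure time, plant-species code) and, usually, the
target column ``logRCF`` — the base-10 log of the root concentration factor.
Columns are typed as ``continuous`` or ``categorical``; categorical columns
hold non-negative integer codes once encoded.

Missing values are represented by NaN, which is distinct from every legal
descriptor value. CSV files are RFC-4180 with a header row, UTF-8, "." decimal
separator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("sdml")

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: provenance column added by augmentation; never treated as a feature
PROVENANCE = "_provenance"


class SchemaError(ValueError):
    """Raised when a table does not satisfy the declared schema."""


class InsufficientDataError(ValueError):
    """Raised when an operation is handed fewer rows than it can work with."""


@dataclass
class FeatureTable:
    """A typed feature table with an optional regression target.

    Parameters
    ----------
    data:
        The underlying DataFrame. One row per chemical–plant exposure record.
    target_name:
        Name of the target column (log RCF, dimensionless log10 scale), or
        ``None`` for unlabeled tables.
    column_kinds:
        Map feature name -> ``"continuous"`` | ``"categorical"``. Columns not
        listed default to continuous.
    category_maps:
        For encoded categorical columns, the original labels in code order
        (code ``i`` decodes to ``category_maps[col][i]``).
    """

    data: pd.DataFrame
    target_name: str | None = None
    column_kinds: dict[str, str] = field(default_factory=dict)
    category_maps: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target_name is not None and self.target_name not in self.data.columns:
            raise SchemaError(f"target column {self.target_name!r} not in table")
        for col, kind in self.column_kinds.items():
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise SchemaError(f"unknown column kind {kind!r} for {col!r}")

    # ------------------------------------------------------------------ views
    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        skip = {self.target_name, PROVENANCE}
        return [c for c in self.data.columns if c not in skip]

    @property
    def continuous_features(self) -> list[str]:
        return [f for f in self.feature_names if self.kind_of(f) == CONTINUOUS]

    @property
    def categorical_features(self) -> list[str]:
        return [f for f in self.feature_names if self.kind_of(f) == CATEGORICAL]

    def kind_of(self, col: str) -> str:
        return self.column_kinds.get(col, CONTINUOUS)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def y(self) -> pd.Series:
        if self.target_name is None:
            raise SchemaError("table has no target column")
        return self.data[self.target_name]

    def copy(self) -> "FeatureTable":
        return replace(
            self,
            data=self.data.copy(),
            column_kinds=dict(self.column_kinds),
            category_maps={k: list(v) for k, v in self.category_maps.items()},
        )

    def with_data(self, data: pd.DataFrame) -> "FeatureTable":
        return replace(self, data=data)

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.target_name == other.target_name
            and list(self.data.columns) == list(other.data.columns)
            and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        )


# ---------------------------------------------------------------------- I/O

def load_table(
    path,
    schema: dict[str, str] | None = None,
    target_name: str | None = None,
) -> FeatureTable:
    """Read a CSV file into a :class:`FeatureTable`.

    ``schema`` maps a subset of column names to kinds; unlisted columns are
    continuous. Unparseable numeric cells (e.g. ``"NA"``) become NaN and the
    row is retained.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty or headerless CSV: {path}") from exc
    schema = dict(schema or {})
    unknown = set(schema) - set(df.columns)
    if unknown:
        raise SchemaError(f"schema names absent columns: {sorted(unknown)}")
    if target_name is not None and target_name not in df.columns:
        raise SchemaError(f"target column {target_name!r} missing from {path}")
    for col in df.columns:
        if col == PROVENANCE:
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    table = FeatureTable(df, target_name=target_name, column_kinds=schema)
    logger.info("load_table: %d rows, %d columns from %s", len(df), df.shape[1], path)
    return table


def write_table(table: FeatureTable, path) -> None:
    """Write the table as UTF-8 CSV with a header row (NaN -> empty cell).

    Floats use 17 significant digits so every double round-trips exactly.
    """
    table.data.to_csv(path, index=False, float_format="%.17g")
    logger.info("write_table: %d rows to %s", table.n_rows, path)


# --------------------------------------------------------------- splitting

@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition: ``train_fraction`` in (0,1), seeded."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_test(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Randomly partition rows into train/test sets.

    ``|train| = round(train_fraction * n)`` with half-up rounding; the split is
    a seeded random permutation partition with no stratification. The same
    (table, seed) always yields the same split.
    """
    n = table.n_rows
    if n < 4:
        raise InsufficientDataError(f"need at least 4 rows to split, got {n}")
    n_train = _round_half_up(spec.train_fraction * n)
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    train = table.with_data(table.data.iloc[train_idx].reset_index(drop=True))
    test = table.with_data(table.data.iloc[test_idx].reset_index(drop=True))
    logger.info("split_train_test: %d -> %d train / %d test (seed=%d)", n, n_train, n - n_train, spec.seed)
    return train, test
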