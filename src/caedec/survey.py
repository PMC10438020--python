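"""Survey microdata ingestion and feature encoding.

Mixed-type survey records (nominal, ordinal, numeric columns) are turned
into the dense ``[0, 1]``-scaled feature matrix the convolutional
autoencoder consumes: nominal columns are one-hot expanded, ordinal
columns are mapped to their declared rank and min-max scaled, numeric
columns are min-max scaled.  Scaling parameters are retained so numeric
columns can be inverted exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

Role = Literal["nominal", "ordinal", "numeric", "binary-outcome"]

__all__ = [
    "ColumnSchema",
    "SurveyTable",
    "FeatureMatrix",
    "SchemaError",
    "ParseError",
    "EncodingError",
    "load_schema",
    "load_survey",
    "encode_features",
    "reshape_for_convolution",
    "inverse_reshape",
]


class SchemaError(ValueError):
    """A declared column is absent or the schema is malformed."""


class ParseError(ValueError):
    """A cell could not be parsed under its declared role."""


class EncodingError(ValueError):
    """A value outside the declared/observed levels met at transform time."""


@dataclass(frozen=True)
class ColumnSchema:
    """Role declaration for one survey column.

    ``levels`` fixes the category order for ordinal columns (rank 0..K-1);
    for nominal columns it may pre-declare levels (unobserved ones keep a
    zero column, observed ones must be covered).
    """

    role: Role
    levels: tuple[str, ...] | None = None


@dataclass
class SurveyTable:
    """Survey records restricted to the declared columns.

    ``levels`` records the per-column observed (or declared) category
    sets; numeric columns map to ``None``.
    """

    data: pd.DataFrame
    schema: dict[str, ColumnSchema]
    levels: dict[str, tuple[str, ...] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.levels:
            self.levels = _observed_levels(self.data, self.schema)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.schema)


@dataclass
class FeatureMatrix:
    """n x d real matrix in [0, 1] with per-output-column provenance.

    ``column_meta`` has one entry per matrix column: the source survey
    column, the encoding rule and, for one-hot columns, the original
    level.  ``scaling`` stores (min, max) per numeric/ordinal source
    column for exact inversion; ``constant_columns`` flags numeric
    columns with zero range (encoded as all zeros).
    """

    values: np.ndarray
    column_meta: list[dict]
    scaling: dict[str, tuple[float, float]]
    constant_columns: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def column_names(self) -> list[str]:
        return [m["name"] for m in self.column_meta]


def _observed_levels(
    df: pd.DataFrame, schema: Mapping[str, ColumnSchema]
) -> dict[str, tuple[str, ...] | None]:
    out: dict[str, tuple[str, ...] | None] = {}
    for col, cs in schema.items():
        if cs.role == "numeric":
            out[col] = None
            continue
        observed = tuple(sorted(df[col].dropna().astype(str).unique()))
        if cs.levels is not None:
            declared = set(cs.levels)
            extra = [v for v in observed if v not in declared]
            if extra:
                raise SchemaError(
                    f"column {col!r}: observed values {extra} not covered by "
                    f"declared levels {list(cs.levels)}"
                )
            out[col] = tuple(cs.levels)
        else:
            out[col] = observed
    return out


def load_schema(path: str | Path) -> dict[str, ColumnSchema]:
    """Read a column-role declaration from a JSON or YAML config file.

    Expected layout::

        columns:
          gender:  {role: nominal}
          ses:     {role: ordinal, levels: ["1", "2", "3"]}
          age:     {role: numeric}
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "columns" not in raw:
        raise SchemaError(f"{path}: schema file must contain a 'columns' mapping")
    schema: dict[str, ColumnSchema] = {}
    for col, decl in raw["columns"].items():
        role = decl.get("role")
        if role not in ("nominal", "ordinal", "numeric", "binary-outcome"):
            raise SchemaError(f"column {col!r}: unknown role {role!r}")
        levels = decl.get("levels")
        if role == "ordinal" and levels is None:
            raise SchemaError(f"ordinal column {col!r} must declare its level order")
        schema[col] = ColumnSchema(
            role=role, levels=tuple(str(v) for v in levels) if levels else None
        )
    return schema


def load_survey(
    path: str | Path,
    schema: Mapping[str, ColumnSchema],
    *,
    delimiter: str = ",",
) -> SurveyTable:
    """Read delimited survey microdata restricted to the schema columns.

    Rows with missing values in any modelling column are dropped (count
    logged).  Numeric cells that fail to parse raise :class:`ParseError`
    naming the offending row and column.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=True)
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"{path}: declared columns {missing_cols} not found in header "
            f"{list(df.columns)}"
        )
    df = df[list(schema)].copy()

    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d record(s) with missing values", n_dropped)

    for col, cs in schema.items():
        if cs.role == "numeric":
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                row = int(df.index[bad][0])
                raise ParseError(
                    f"column {col!r}, row {row}: cannot parse "
                    f"{df[col][bad].iloc[0]!r} as numeric"
                )
            df[col] = parsed.astype(float)
        else:
            df[col] = df[col].astype(str)

    df = df.reset_index(drop=True)
    return SurveyTable(data=df, schema=dict(schema))


def encode_features(table: SurveyTable) -> FeatureMatrix:
    """Encode a survey table into a dense feature matrix scaled to [0, 1].

    Column order follows the schema declaration; one-hot blocks are laid
    out in sorted level order (declared order for ordinals), so the
    encoding is deterministic and independent of record order.  A
    constant numeric column becomes an all-zero column and is flagged
    rather than raising a division by zero.
    """
    blocks: list[np.ndarray] = []
    meta: list[dict] = []
    scaling: dict[str, tuple[float, float]] = {}
    constant: list[str] = []
    n = table.n

    for col, cs in table.schema.items():
        if cs.role == "numeric":
            x = table.data[col].to_numpy(dtype=float)
            lo, hi = (float(x.min()), float(x.max())) if n else (0.0, 0.0)
            scaling[col] = (lo, hi)
            if hi == lo:
                constant.append(col)
                blocks.append(np.zeros((n, 1)))
            else:
                blocks.append(((x - lo) / (hi - lo))[:, None])
            meta.append({"name": col, "source": col, "rule": "minmax"})
        elif cs.role == "ordinal":
            order = table.levels[col]
            assert order is not None
            rank = {lvl: i for i, lvl in enumerate(order)}
            vals = table.data[col].astype(str)
            unseen = sorted(set(vals) - set(order))
            if unseen:
                raise EncodingError(f"column {col!r}: unseen level(s) {unseen}")
            r = vals.map(rank).to_numpy(dtype=float)
            k = len(order)
            scaling[col] = (0.0, float(k - 1))
            if k == 1:
                constant.append(col)
                blocks.append(np.zeros((n, 1)))
            else:
                blocks.append((r / (k - 1))[:, None])
            meta.append({"name": col, "source": col, "rule": "ordinal-rank"})
        else:  # nominal or binary-outcome -> one-hot
            levels = table.levels[col]
            assert levels is not None
            levels = tuple(sorted(levels))
            vals = table.data[col].astype(str)
            unseen = sorted(set(vals) - set(levels))
            if unseen:
                raise EncodingError(f"column {col!r}: unseen level(s) {unseen}")
            onehot = np.zeros((n, len(levels)))
            idx = {lvl: j for j, lvl in enumerate(levels)}
            onehot[np.arange(n), vals.map(idx).to_numpy()] = 1.0
            blocks.append(onehot)
            for lvl in levels:
                meta.append(
                    {"name": f"{col}={lvl}", "source": col, "rule": "onehot", "level": lvl}
                )

    values = np.hstack(blocks) if blocks else np.zeros((n, 0))
    return FeatureMatrix(
        values=values,
        column_meta=meta,
        scaling=scaling,
        constant_columns=tuple(constant),
    )


def decode_numeric(fm: FeatureMatrix, column: str, scaled: np.ndarray) -> np.ndarray:
    """Invert min-max scaling for one numeric/ordinal source column."""
    lo, hi = fm.scaling[column]
    return scaled * (hi - lo) + lo


def reshape_for_convolution(fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Present records as 1-channel, length-d sequences: (n, 1, d)."""
    values = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
    n, d = values.shape
    return values.reshape(n, 1, d)


def inverse_reshape(x: np.ndarray) -> np.ndarray:
    """Invert :func:`reshape_for_convolution` exactly."""
    n, c, d = x.shape
    if c != 1:
        raise ValueError(f"expected a single channel, got {c}")
    return x.reshape(n, d)
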