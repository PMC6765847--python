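"""Tabular cohort container, variable metadata, and min-max normalisation.

Every layout in the package is driven by per-variable min-max scaling

    u = (value - v_min) / (v_max - v_min)         in [0, 1]

where ``v_min``/``v_max`` are declared (or observed) bounds carried on the
:class:`VariableSpec`.  The scaled value is the "attraction weight" of a
record towards that variable's dimensional anchor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSpec",
    "DataTable",
    "NormalizedMatrix",
    "load_table",
    "write_table",
    "load_schema",
    "save_schema",
    "select_variables",
    "normalize",
]


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one column: numeric with bounds, or categorical with levels.

    Parameters
    ----------
    name : str
        Column name.
    kind : {"numeric", "categorical"}
    v_min, v_max : float, optional
        Declared lower/upper bound of a numeric variable.  These are the
        values the normaliser maps to 0 and 1.
    categories : tuple of str, optional
        Ordered levels of a categorical variable.
    """

    name: str
    kind: str
    v_min: float | None = None
    v_max: float | None = None
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "numeric":
            if self.v_min is None or self.v_max is None:
                raise ValueError(f"numeric variable {self.name!r} needs v_min and v_max")
            if self.v_min > self.v_max:
                raise ValueError(
                    f"variable {self.name!r}: v_min ({self.v_min}) > v_max ({self.v_max})"
                )
        else:
            if len(self.categories) < 1:
                raise ValueError(f"categorical variable {self.name!r} needs >=1 category")
            if self.v_min is not None or self.v_max is not None:
                raise ValueError(f"categorical variable {self.name!r} cannot carry bounds")

    @property
    def is_numeric(self) -> bool:
        return self.kind == "numeric"


@dataclass
class DataTable:
    """Patients x variables with per-variable metadata.

    ``df`` holds one row per patient, indexed by a unique row id; ``variables``
    describes every column of ``df`` in order.  Missing values are NaN.
    """

    df: pd.DataFrame
    variables: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dupes = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dupes}")
        names = [v.name for v in self.variables]
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise ValueError(f"variables not present in table: {missing}")
        self.df = self.df[names]

    @property
    def row_ids(self) -> list:
        return list(self.df.index)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"no variable named {name!r}")

    @property
    def numeric_names(self) -> list[str]:
        return [v.name for v in self.variables if v.is_numeric]

    @property
    def categorical_names(self) -> list[str]:
        return [v.name for v in self.variables if not v.is_numeric]

    def subset(self, row_ids) -> "DataTable":
        """Row subset preserving variable metadata and row order."""
        keep = [r for r in self.row_ids if r in set(row_ids)]
        return DataTable(self.df.loc[keep].copy(), list(self.variables))


@dataclass
class NormalizedMatrix:
    """Min-max-scaled values in [0, 1]; the weights that drive the layouts.

    Rows with a missing value in any selected variable are excluded and
    listed in ``dropped_ids``.
    """

    u: np.ndarray
    variable_order: list[str]
    row_ids: list
    dropped_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 2:
            raise ValueError("u must be 2-D")
        if self.u.shape != (len(self.row_ids), len(self.variable_order)):
            raise ValueError("u shape does not match row_ids x variable_order")


def _is_numeric_series(s: pd.Series) -> bool:
    if pd.api.types.is_numeric_dtype(s):
        return True
    try:
        pd.to_numeric(s.dropna())
        return True
    except (ValueError, TypeError):
        return False


def infer_schema(df: pd.DataFrame) -> list[VariableSpec]:
    """Infer a VariableSpec per column: numeric (observed min/max bounds) when
    every non-missing token parses as a number, else categorical with levels
    in order of first appearance."""
    specs = []
    for col in df.columns:
        s = df[col]
        if _is_numeric_series(s):
            vals = pd.to_numeric(s, errors="coerce")
            specs.append(
                VariableSpec(col, "numeric", float(vals.min()), float(vals.max()))
            )
        else:
            cats = tuple(dict.fromkeys(s.dropna().astype(str)))
            specs.append(VariableSpec(col, "categorical", categories=cats))
    return specs


def load_table(path, schema="infer", id_column: str = "id") -> DataTable:
    """Read a CSV (UTF-8, comma, header, '.' decimal) into a :class:`DataTable`.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.  The ``id_column`` column, when present,
        becomes the row index; otherwise the 0-based position is used.
    schema : "infer" or list of VariableSpec
        With "infer", columns whose values all parse as numbers become
        numeric variables with observed min/max as bounds; everything else
        becomes categorical.  An explicit schema may cover a subset of the
        columns; only those are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if id_column in df.columns:
        df = df.set_index(id_column)
        df.index.name = id_column
    if df.index.has_duplicates:
        raise ValueError(f"duplicate row ids in {path}")

    if schema == "infer":
        specs = infer_schema(df)
    else:
        specs = list(schema)
        unknown = [v.name for v in specs if v.name not in df.columns]
        if unknown:
            raise ValueError(f"schema names not in header: {unknown}")
        df = df[[v.name for v in specs]]

    out = pd.DataFrame(index=df.index)
    for spec in specs:
        col = df[spec.name]
        if spec.is_numeric:
            parsed = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & parsed.isna()
            if bad.any():
                tok = col[bad].iloc[0]
                raise ValueError(
                    f"non-numeric token {tok!r} in numeric column {spec.name!r}"
                )
            out[spec.name] = parsed.astype(float)
        else:
            out[spec.name] = col.astype("string").astype(object)
    return DataTable(out, specs)


def write_table(table: DataTable, path, id_column: str = "id") -> Path:
    """Write a DataTable to CSV so that :func:`load_table` round-trips it."""
    path = Path(path)
    df = table.df.copy()
    df.index.name = id_column
    # Render integral floats without a trailing .0 so round-trip is textual too.
    for v in table.variables:
        if v.is_numeric:
            col = df[v.name]
            if col.dropna().apply(float.is_integer).all():
                df[v.name] = col.astype("Int64")
    df.to_csv(path)
    return path


def save_schema(variables: list[VariableSpec], path) -> Path:
    """Write variable metadata as a YAML sidecar."""
    entries = []
    for v in variables:
        e: dict = {"name": v.name, "kind": v.kind}
        if v.is_numeric:
            e["v_min"] = v.v_min
            e["v_max"] = v.v_max
        else:
            e["categories"] = list(v.categories)
        entries.append(e)
    path = Path(path)
    path.write_text(yaml.safe_dump({"variables": entries}, sort_keys=False))
    return path


def load_schema(path) -> list[VariableSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    specs = []
    for e in doc["variables"]:
        if e["kind"] == "numeric":
            specs.append(VariableSpec(e["name"], "numeric", float(e["v_min"]), float(e["v_max"])))
        else:
            specs.append(VariableSpec(e["name"], "categorical", categories=tuple(e["categories"])))
    return specs


def select_variables(table: DataTable, names: list[str], purpose: str = "anchors") -> list[VariableSpec]:
    """Pick variables for a view, in the given order.

    Dimensional anchors must be numeric — categorical variables such as
    gender or the diagnosis stage cannot pull a node and are rejected by
    name.  Parallel-coordinate axes accept either kind.
    """
    if purpose not in ("anchors", "axes"):
        raise ValueError(f"unknown purpose {purpose!r}")
    specs = [table.variable(n) for n in names]
    if purpose == "anchors":
        bad = [v.name for v in specs if not v.is_numeric]
        if bad:
            raise ValueError(
                f"categorical variable(s) cannot be dimensional anchors: {bad}"
            )
    return specs


def normalize(table: DataTable, variables: list[VariableSpec]) -> NormalizedMatrix:
    """Min-max scale the selected numeric variables to [0, 1].

    Values outside the declared bounds are clamped (with a logged warning).
    A constant variable (v_min == v_max) maps to 0.5 everywhere — a neutral
    contribution to every layout — with a warning.  Rows missing any
    selected value are dropped and reported in ``dropped_ids``.
    """
    if not variables:
        raise ValueError("empty variable list")
    bad = [v.name for v in variables if not v.is_numeric]
    if bad:
        raise ValueError(f"normalize requires numeric variables, got {bad}")

    names = [v.name for v in variables]
    raw = table.df[names].to_numpy(dtype=float)
    keep = ~np.isnan(raw).any(axis=1)
    dropped = [r for r, k in zip(table.row_ids, keep) if not k]
    if dropped:
        logger.warning("normalize: dropped %d row(s) with missing values", len(dropped))
    raw = raw[keep]

    u = np.empty_like(raw)
    for j, v in enumerate(variables):
        col = raw[:, j]
        lo, hi = v.v_min, v.v_max
        if np.any((col < lo) | (col > hi)):
            n_out = int(np.sum((col < lo) | (col > hi)))
            msg = f"variable {v.name!r}: clamped {n_out} value(s) outside [{lo}, {hi}]"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            col = np.clip(col, lo, hi)
        if hi == lo:
            msg = f"variable {v.name!r} is constant (v_min == v_max); using u = 0.5"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            u[:, j] = 0.5
        else:
            u[:, j] = (col - lo) / (hi - lo)
    row_ids = [r for r, k in zip(table.row_ids, keep) if k]
    return NormalizedMatrix(u, names, row_ids, dropped)
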