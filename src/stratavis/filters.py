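"""Parallel-coordinates axis model and the multifilter.

Each selected variable becomes a vertical axis: numeric axes span the
declared [v_min, v_max]; categorical axes place their levels at equally
spaced positions in declared order.  The multifilter lets a user brush
*several* ranges on one axis — a record passes an axis if its value lies
in the union of that axis's closed intervals (or selected category set) —
and combines axes conjunctively: a record is kept iff it passes every
axis that has at least one selection.  An empty filter keeps everything.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .data import DataTable, VariableSpec
from .radvis import LayoutPoint

__all__ = ["Axis", "AxisSet", "FilterSet", "build_axes", "apply_filter", "linked_selection"]


@dataclass(frozen=True)
class Axis:
    """One parallel axis: a numeric range or equally spaced category slots."""

    spec: VariableSpec

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def range(self) -> tuple[float, float]:
        if not self.spec.is_numeric:
            raise TypeError(f"axis {self.name!r} is categorical")
        return (self.spec.v_min, self.spec.v_max)

    @property
    def category_positions(self) -> dict:
        """Level -> position in [0, 1], equally spaced in declared order."""
        if self.spec.is_numeric:
            raise TypeError(f"axis {self.name!r} is numeric")
        cats = self.spec.categories
        if len(cats) == 1:
            return {cats[0]: 0.5}
        return {c: i / (len(cats) - 1) for i, c in enumerate(cats)}


@dataclass
class AxisSet:
    axes: list[Axis]

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.axes]

    def __len__(self) -> int:
        return len(self.axes)

    def __getitem__(self, name: str) -> Axis:
        for a in self.axes:
            if a.name == name:
                return a
        raise KeyError(name)


def build_axes(table: DataTable, names: list[str]) -> AxisSet:
    """One axis per name, order preserved; numeric and categorical mix freely."""
    return AxisSet([Axis(table.variable(n)) for n in names])


@dataclass
class FilterSet:
    """Per-axis selections: unions of closed intervals (numeric) or category
    sets (categorical); conjunctive across axes.

    Overlapping intervals on one axis are allowed and behave as their union.
    """

    intervals: dict = field(default_factory=dict)   # name -> list[(lo, hi)]
    categories: dict = field(default_factory=dict)  # name -> set of levels

    def add_interval(self, name: str, lo: float, hi: float) -> "FilterSet":
        if lo > hi:
            raise ValueError(f"malformed interval on {name!r}: [{lo}, {hi}]")
        self.intervals.setdefault(name, []).append((float(lo), float(hi)))
        return self

    def add_categories(self, name: str, levels) -> "FilterSet":
        self.categories.setdefault(name, set()).update(levels)
        return self

    @property
    def constrained_axes(self) -> list[str]:
        return sorted(set(self.intervals) | set(self.categories))

    def is_empty(self) -> bool:
        return not self.intervals and not self.categories

    @classmethod
    def parse(cls, exprs: list[str], table: DataTable) -> "FilterSet":
        """Parse CLI filter expressions.

        Numeric: ``"item_01:0-0,3-3"`` (comma-separated lo-hi ranges; a bare
        number is a point interval).  Categorical: ``"diagnosis:AD|MCI"``.
        """
        fs = cls()
        for expr in exprs:
            if ":" not in expr:
                raise ValueError(f"bad filter expression {expr!r} (want name:selection)")
            name, sel = expr.split(":", 1)
            spec = table.variable(name)
            if spec.is_numeric:
                for part in sel.split(","):
                    m = re.fullmatch(r"(-?[\d.]+)-(-?[\d.]+)", part)
                    if m:
                        lo, hi = float(m.group(1)), float(m.group(2))
                    else:
                        lo = hi = float(part)
                    fs.add_interval(name, lo, hi)
            else:
                fs.add_categories(name, sel.split("|"))
        return fs


def apply_filter(table: DataTable, filters: FilterSet) -> DataTable:
    """Rows passing every constrained axis; unconstrained axes pass freely.

    Numeric: pass iff the value lies in the union of the axis's closed
    intervals (missing values fail a constrained axis).  Categorical: pass
    iff the level is in the selected set.
    """
    for name in filters.constrained_axes:
        table.variable(name)  # raises KeyError for unknown axes
    mask = np.ones(table.n_rows, dtype=bool)
    for name, ivals in filters.intervals.items():
        spec = table.variable(name)
        if not spec.is_numeric:
            raise ValueError(f"interval filter on categorical axis {name!r}")
        vals = table.df[name].to_numpy(dtype=float)
        axis_ok = np.zeros(table.n_rows, dtype=bool)
        for lo, hi in ivals:
            if lo > hi:
                raise ValueError(f"malformed interval on {name!r}: [{lo}, {hi}]")
            axis_ok |= (vals >= lo) & (vals <= hi)
        mask &= axis_ok
    for name, levels in filters.categories.items():
        spec = table.variable(name)
        if spec.is_numeric:
            raise ValueError(f"category filter on numeric axis {name!r}")
        vals = table.df[name]
        mask &= vals.isin(levels).to_numpy()
    keep = [r for r, m in zip(table.row_ids, mask) if m]
    return DataTable(table.df.loc[keep].copy(), list(table.variables))


def linked_selection(points: list[LayoutPoint], row_subset) -> list[LayoutPoint]:
    """The layout points whose ids are in the subset (order of ``points``
    preserved; no mutation).  Unknown ids in the subset are an error."""
    known = {p.row_id for p in points}
    subset = set(row_subset)
    unknown = subset - known
    if unknown:
        raise KeyError(f"unknown row id(s) in selection: {sorted(map(str, unknown))[:5]}")
    return [p for p in points if p.row_id in subset]
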