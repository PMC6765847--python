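"""2D RadVis and the 3D cylindrical RadVis layout.

Each numeric variable is a *dimensional anchor*: a point on a circle (2D)
or a vertical edge of a cylinder (3D).  The per-variable placement rule is
the linear interpolation between position bounds

    Np(i) = (N(i) - Vmin(i)) / (Vmax(i) - Vmin(i)) * (Pmax(i) - Pmin(i)) + Pmin(i)

so a record at the variable's minimum sits at P_min and at the maximum at
P_max.  With the default bounds P_min = 0, P_max = 1 this is exactly the
min-max-normalised value u_i, the attraction weight of anchor i.

Horizontal placement combines the n per-variable weights by the classic
RadVis weighted barycenter, (x, y) = sum_i w_i a_i / sum_i w_i; the higher
a record's value on a variable, the harder that anchor pulls.  In the 3D
variant the vertical coordinate is z = H * mean(u): a record at the
minimum on every variable sits at the bottom-centre of the cylinder
(0, 0, 0); raising any value lifts it.  Two records whose weight vectors
are proportional share (x, y) — where a flat 2D RadVis would overlap them
— but differ in z, which is the point of the cylinder.

The combination of the per-variable rule into one point is this package's
documented reading of the anchor-pull principle: barycentric (x, y) with
weights Np(i) on [0, 1], mean-value height.  Both boundary behaviours
(maximum -> pulled to the anchor, minimum -> pulled to the bottom-centre)
and the locate-by-average-value rule follow from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import NormalizedMatrix, VariableSpec

__all__ = [
    "AnchorLayout",
    "LayoutPoint",
    "make_anchors",
    "eq1_position",
    "project_2d",
    "project_3d",
    "layout_table",
]


@dataclass
class AnchorLayout:
    """n >= 3 equally spaced dimensional anchors on a circle of the given
    radius (2D) / the wall of a cylinder of the given height (3D).

    The first anchor sits at 12 o'clock and anchors proceed clockwise in
    input column order; ``angles[i] = pi/2 - 2*pi*i/n``.  ``p_min``/``p_max``
    are per-variable position bounds of the placement rule (defaults 0/1,
    under which the rule reduces to min-max normalisation).
    """

    variable_order: list[str]
    radius: float = 1.0
    height: float = 1.0
    angles: np.ndarray = field(default=None)  # type: ignore[assignment]
    p_min: np.ndarray = field(default=None)  # type: ignore[assignment]
    p_max: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.variable_order)
        if n < 3:
            raise ValueError(f"need >= 3 anchors, got {n}")
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("radius and height must be positive")
        if self.angles is None:
            self.angles = np.pi / 2 - 2 * np.pi * np.arange(n) / n
        self.angles = np.asarray(self.angles, dtype=float)
        if self.p_min is None:
            self.p_min = np.zeros(n)
        if self.p_max is None:
            self.p_max = np.ones(n)
        self.p_min = np.asarray(self.p_min, dtype=float)
        self.p_max = np.asarray(self.p_max, dtype=float)
        if np.any(self.p_min >= self.p_max):
            raise ValueError("p_min must be < p_max for every variable")

    @property
    def n_anchors(self) -> int:
        return len(self.variable_order)

    @property
    def anchor_xy(self) -> np.ndarray:
        """n x 2 anchor positions on the circle."""
        return self.radius * np.column_stack([np.cos(self.angles), np.sin(self.angles)])


@dataclass(frozen=True)
class LayoutPoint:
    """One record's position; z = 0 for 2D layouts."""

    row_id: object
    x: float
    y: float
    z: float = 0.0

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


def make_anchors(
    variables: list[VariableSpec], radius: float = 1.0, height: float = 1.0
) -> AnchorLayout:
    """Place one anchor per numeric variable at equidistant intervals on the
    circumference, first at 12 o'clock, clockwise in input order."""
    bad = [v.name for v in variables if not v.is_numeric]
    if bad:
        raise ValueError(f"anchors must be numeric variables; categorical: {bad}")
    if len(variables) < 3:
        raise ValueError(f"need >= 3 anchor variables, got {len(variables)}")
    return AnchorLayout([v.name for v in variables], radius=radius, height=height)


def eq1_position(value, v_min, v_max, p_min, p_max):
    """Per-variable placement: linear map of [v_min, v_max] onto [p_min, p_max].

    ``value = v_min -> p_min``; ``value = v_max -> p_max``; affine in between.
    A degenerate variable (v_min == v_max) maps to the midpoint, matching the
    normaliser's u = 0.5 convention.  Accepts scalars or arrays.
    """
    value = np.asarray(value, dtype=float)
    v_min = np.asarray(v_min, dtype=float)
    v_max = np.asarray(v_max, dtype=float)
    p_min = np.asarray(p_min, dtype=float)
    p_max = np.asarray(p_max, dtype=float)
    if np.any(p_min >= p_max):
        raise ValueError("p_min must be < p_max")
    span = v_max - v_min
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(span == 0, 0.5, (value - v_min) / np.where(span == 0, 1.0, span))
    out = u * (p_max - p_min) + p_min
    return out.item() if out.ndim == 0 else out


def _weights(u_row: np.ndarray, anchors: AnchorLayout) -> np.ndarray:
    u_row = np.asarray(u_row, dtype=float)
    if u_row.shape != (anchors.n_anchors,):
        raise ValueError(
            f"row length {u_row.shape} does not match {anchors.n_anchors} anchors"
        )
    # Placement-rule weights on the per-variable position bounds.
    return eq1_position(u_row, 0.0, 1.0, anchors.p_min, anchors.p_max)


def project_2d(u_row, anchors: AnchorLayout, row_id=None) -> LayoutPoint:
    """Classic RadVis: anchor-weighted barycenter of one normalised row.

    The higher u_i, the harder anchor i pulls; an all-zero row sits at the
    circle centre by convention.
    """
    w = _weights(u_row, anchors)
    s = w.sum()
    if s == 0:
        x, y = 0.0, 0.0
    else:
        x, y = (w @ anchors.anchor_xy) / s
    return LayoutPoint(row_id, float(x), float(y), 0.0)


def project_3d(u_row, anchors: AnchorLayout, row_id=None) -> LayoutPoint:
    """Cylindrical RadVis: barycentric (x, y) against the cylinder-wall
    anchors, height z = H * mean(u).

    All-minimum rows land at the bottom-centre (0, 0, 0); all-maximum rows
    reach z = H.  Proportional rows share (x, y) and separate in z.
    """
    p2 = project_2d(u_row, anchors, row_id)
    z = anchors.height * float(np.mean(np.asarray(u_row, dtype=float)))
    return LayoutPoint(row_id, p2.x, p2.y, z)


def layout_table(
    u: NormalizedMatrix, anchors: AnchorLayout, mode: str = "radvis3d"
) -> list[LayoutPoint]:
    """Vectorised layout of every row of a normalised matrix.

    ``mode`` is "radvis2d" or "radvis3d".  The matrix column order must
    match the anchor variable order exactly.
    """
    if mode not in ("radvis2d", "radvis3d"):
        raise ValueError(f"unknown layout mode {mode!r}")
    if u.variable_order != anchors.variable_order:
        raise ValueError(
            "column order mismatch: "
            f"{u.variable_order} vs anchors {anchors.variable_order}"
        )
    U = u.u
    W = eq1_position(U, 0.0, 1.0, anchors.p_min[None, :], anchors.p_max[None, :])
    s = W.sum(axis=1)
    xy = np.zeros((len(U), 2))
    nz = s > 0
    xy[nz] = (W[nz] @ anchors.anchor_xy) / s[nz, None]
    if mode == "radvis3d":
        z = anchors.height * U.mean(axis=1)
    else:
        z = np.zeros(len(U))
    return [
        LayoutPoint(rid, float(x), float(y), float(zz))
        for rid, (x, y), zz in zip(u.row_ids, xy, z)
    ]
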