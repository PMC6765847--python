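"""Static render export: 3D RadVis scatter and parallel coordinates.

Figures are drawn with matplotlib and written either as PNG or as an HTML
page embedding the SVG figure, so the anchor labels and per-record markers
remain inspectable text in the output file.  Rendering is cosmetic: a
render failure never corrupts the CSV/JSON data outputs, callers catch and
warn.
"""

from __future__ import annotations

import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .cluster import ClusterModel
from .data import DataTable
from .filters import AxisSet
from .radvis import AnchorLayout, LayoutPoint

__all__ = ["render_radvis", "render_parallel_coordinates"]

_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title></head>
<body>
<h1>{title}</h1>
{svg}
</body></html>
"""


def _save(fig, out: Path, title: str) -> Path:
    out = Path(out)
    if out.suffix == ".html":
        buf = io.StringIO()
        fig.savefig(buf, format="svg")
        out.write_text(_HTML_TEMPLATE.format(title=title, svg=buf.getvalue()))
    else:
        fig.savefig(out)
    plt.close(fig)
    return out


def _color_values(points, clusters: ClusterModel | None, table: DataTable | None):
    """Cluster index when a non-trivial model is given, else diagnosis
    stage, else a constant."""
    if clusters is not None and len(clusters.assignments) == len(points) > 0:
        return clusters.assignments, "cluster"
    if table is not None and "diagnosis" in table.df.columns:
        df = table.df.loc[[p.row_id for p in points]]
        levels = list(table.variable("diagnosis").categories)
        return np.array([levels.index(v) for v in df["diagnosis"]]), "stage"
    return np.zeros(len(points)), "record"


def render_radvis(
    points: list[LayoutPoint],
    anchors: AnchorLayout,
    out,
    clusters: ClusterModel | None = None,
    table: DataTable | None = None,
    mode: str = "radvis3d",
) -> Path:
    """Scatter the laid-out records inside the anchor polygon/cylinder.

    Anchors are drawn and labelled by variable name (vertical edges in 3D);
    markers are coloured by cluster when a model is given, otherwise by
    diagnosis stage when the table carries one.
    """
    colors, color_label = _color_values(points, clusters, table)
    xy = anchors.anchor_xy
    if mode == "radvis3d":
        fig = plt.figure(figsize=(8, 8))
        ax = fig.add_subplot(projection="3d")
        for (ax_x, ax_y), name in zip(xy, anchors.variable_order):
            ax.plot([ax_x, ax_x], [ax_y, ax_y], [0, anchors.height], color="0.7", lw=1)
            ax.text(ax_x, ax_y, anchors.height * 1.02, name, fontsize=7)
        ax.scatter(
            [p.x for p in points], [p.y for p in points], [p.z for p in points],
            c=colors, cmap="tab10", s=12, depthshade=False,
        )
        ax.set_zlim(0, anchors.height)
        ax.set_title(f"3D RadVis ({len(points)} records, colored by {color_label})")
    else:
        fig, ax = plt.subplots(figsize=(8, 8))
        ring = np.append(np.arange(anchors.n_anchors), 0)
        ax.plot(xy[ring, 0], xy[ring, 1], color="0.7", lw=1)
        for (ax_x, ax_y), name in zip(xy, anchors.variable_order):
            ax.annotate(name, (ax_x, ax_y), fontsize=7)
        ax.scatter([p.x for p in points], [p.y for p in points], c=colors, cmap="tab10", s=12)
        ax.set_aspect("equal")
        ax.set_title(f"2D RadVis ({len(points)} records, colored by {color_label})")
    return _save(fig, out, "RadVis layout")


def render_parallel_coordinates(
    table: DataTable,
    axes: AxisSet,
    out,
    clusters: ClusterModel | None = None,
    max_lines: int = 2000,
) -> Path:
    """One polyline per record across the parallel axes.

    Numeric values are scaled to the axis's [v_min, v_max]; categorical
    levels sit at their equally spaced positions.  Records beyond
    ``max_lines`` are dropped for legibility.
    """
    df = table.df
    positions = np.zeros((len(df), len(axes)))
    for j, axis in enumerate(axes.axes):
        if axis.spec.is_numeric:
            lo, hi = axis.range
            vals = df[axis.name].to_numpy(dtype=float)
            positions[:, j] = 0.5 if hi == lo else (vals - lo) / (hi - lo)
        else:
            pos = axis.category_positions
            positions[:, j] = [pos.get(v, np.nan) for v in df[axis.name]]

    if clusters is not None:
        by_id = dict(zip(clusters.row_ids, clusters.assignments))
        colors = np.array([by_id.get(r, -1) for r in table.row_ids])
    else:
        colors = np.zeros(len(df))
    cmap = plt.get_cmap("tab10")

    fig, ax = plt.subplots(figsize=(max(8, len(axes)), 5))
    xs = np.arange(len(axes))
    for i in range(min(len(df), max_lines)):
        ax.plot(xs, positions[i], color=cmap(int(colors[i]) % 10), alpha=0.3, lw=0.8)
    for j, axis in enumerate(axes.axes):
        ax.axvline(j, color="0.6", lw=1)
    ax.set_xticks(xs)
    ax.set_xticklabels(axes.names, rotation=60, ha="right", fontsize=7)
    ax.set_yticks([])
    ax.set_title(f"Parallel coordinates ({len(axes)} axes, {len(df)} records)")
    fig.tight_layout()
    return _save(fig, out, "Parallel coordinates")
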