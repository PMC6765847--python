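"""k-means patient segmentation (Lloyd iterations, Random / Forgy start).

The segmentation loop is the textbook one: pick k initial centres, assign
every point to its nearest centre by Euclidean distance, recompute each
centre as the mean of its members, and repeat until no centre moves.

Two initialisations are offered.  *Random* draws k pivot points uniformly
inside the data volume — for layouts, uniformly inside the RadVis cylinder
(r x H); otherwise inside the axis-aligned bounding box.  *Forgy* picks k
distinct data points; with a fixed seed the selection, and hence the whole
run, is identical every time.

Clustering can run in layout space (the 3D RadVis coordinates, the
default) or directly in normalised feature space — a documented flag,
since segmenting "nearby nodes" and segmenting "similar test profiles"
are different statements once the layout has projected the data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DataTable, load_table
from .radvis import LayoutPoint

__all__ = [
    "ClusterModel",
    "ClusterSummary",
    "init_centers",
    "kmeans",
    "summarize_clusters",
    "export_clusters",
]


@dataclass
class ClusterModel:
    """Converged (or iteration-capped) k-means state."""

    k: int
    init: str
    seed: int
    centers: np.ndarray           # k x d
    assignments: np.ndarray       # per-row cluster index
    n_iterations: int
    converged: bool
    inertia: float                # within-cluster sum of squared distances
    inertia_history: list[float] = field(default_factory=list)
    space: str = "layout3d"
    row_ids: list = field(default_factory=list)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def _uniform_cylinder(rng: np.random.Generator, k: int, radius: float, height: float) -> np.ndarray:
    # area-uniform radius: r = R * sqrt(U)
    r = radius * np.sqrt(rng.random(k))
    theta = rng.uniform(0.0, 2 * np.pi, k)
    z = rng.uniform(0.0, height, k)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def init_centers(
    points: np.ndarray,
    k: int,
    init: str = "forgy",
    seed: int = 0,
    cylinder: tuple[float, float] | None = None,
) -> np.ndarray:
    """Initial centres: Forgy (k distinct data points, seeded sampling
    without replacement) or Random (uniform in the data volume —
    the cylinder (radius, height) when given, else the bounding box)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be n x d")
    if k <= 0:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    if init == "forgy":
        distinct = np.unique(points, axis=0)
        if k > len(distinct):
            raise ValueError(
                f"forgy needs k <= number of distinct points ({len(distinct)}), got k={k}"
            )
        idx = rng.choice(len(distinct), size=k, replace=False)
        return distinct[idx].copy()
    if init == "random":
        if cylinder is not None:
            if points.shape[1] != 3:
                raise ValueError("cylinder bounds require 3-D points")
            radius, height = cylinder
            return _uniform_cylinder(rng, k, radius, height)
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        return rng.uniform(lo, hi, size=(k, points.shape[1]))
    raise ValueError(f"unknown init {init!r}; choose 'forgy' or 'random'")


def _assign(points: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # squared Euclidean distances; argmin breaks ties toward the lowest index
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    return labels, d2[np.arange(len(points)), labels]


def _lloyd(
    points: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, int, bool, float, list[float]]:
    k = len(centers)
    centers = centers.copy()
    history: list[float] = []
    converged = False
    labels = np.zeros(len(points), dtype=int)
    it = 0
    for it in range(1, max_iter + 1):
        labels, d2 = _assign(points, centers)
        history.append(float(d2.sum()))
        new_centers = centers.copy()
        for j in range(k):
            members = points[labels == j]
            if len(members) > 0:
                new_centers[j] = members.mean(axis=0)
            else:
                # empty-cluster repair: reseed at the point farthest from
                # the dead centre (deterministic, keeps k clusters)
                far = np.argmax(((points - centers[j]) ** 2).sum(axis=1))
                new_centers[j] = points[far]
        if np.max(np.abs(new_centers - centers)) <= tol:
            centers = new_centers
            converged = True
            break
        centers = new_centers
    labels, d2 = _assign(points, centers)
    inertia = float(d2.sum())
    history.append(inertia)
    return centers, labels, it, converged, inertia, history


def kmeans(
    points: np.ndarray,
    k: int,
    init: str = "forgy",
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
    cylinder: tuple[float, float] | None = None,
    restarts: int = 1,
    space: str = "layout3d",
    row_ids=None,
) -> ClusterModel:
    """Lloyd's k-means.  Stops when no centre moves by more than ``tol`` or
    after ``max_iter`` sweeps; the within-cluster sum of squares is
    non-increasing across iterations.  ``restarts`` > 1 reruns with derived
    seeds and keeps the best objective."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be n x d")
    if not 1 <= k <= len(points):
        raise ValueError(f"need 1 <= k <= n ({len(points)}), got k={k}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    best: ClusterModel | None = None
    for r in range(restarts):
        run_seed = seed if restarts == 1 else int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        centers0 = init_centers(points, k, init=init, seed=run_seed, cylinder=cylinder)
        centers, labels, n_it, conv, inertia, hist = _lloyd(points, centers0, max_iter, tol)
        model = ClusterModel(
            k=k,
            init=init,
            seed=run_seed,
            centers=centers,
            assignments=labels,
            n_iterations=n_it,
            converged=conv,
            inertia=inertia,
            inertia_history=hist,
            space=space,
            row_ids=list(row_ids) if row_ids is not None else list(range(len(points))),
        )
        if best is None or model.inertia < best.inertia:
            best = model
    assert best is not None
    return best


@dataclass
class ClusterSummary:
    """Descriptive statistics per cluster: size, per-variable mean and
    median, and the composition of each categorical variable."""

    sizes: dict
    numeric_stats: pd.DataFrame          # index (cluster, variable), cols mean/median
    categorical_shares: dict             # variable -> DataFrame cluster x level

    def to_dict(self) -> dict:
        return {
            "sizes": {str(k): int(v) for k, v in self.sizes.items()},
            "numeric": {
                f"{c}|{v}": {"mean": float(row["mean"]), "median": float(row["median"])}
                for (c, v), row in self.numeric_stats.iterrows()
            },
            "categorical": {
                var: {str(c): {str(l): float(s) for l, s in r.items()} for c, r in df.iterrows()}
                for var, df in self.categorical_shares.items()
            },
        }


def summarize_clusters(model: ClusterModel, table: DataTable) -> ClusterSummary:
    """Exact per-cluster means/medians of numeric variables and level shares
    of categorical variables, over the rows the model clustered."""
    if len(model.assignments) != len(model.row_ids):
        raise ValueError("assignments/row_ids length mismatch")
    df = table.df.loc[model.row_ids].copy()
    if len(df) != len(model.assignments):
        raise ValueError("model rows do not align with the table")
    df["_cluster"] = model.assignments

    sizes = df.groupby("_cluster").size().to_dict()

    num_rows = []
    for c, grp in df.groupby("_cluster"):
        for name in table.numeric_names:
            vals = grp[name].astype(float)
            num_rows.append((c, name, float(vals.mean()), float(vals.median())))
    numeric_stats = pd.DataFrame(
        num_rows, columns=["cluster", "variable", "mean", "median"]
    ).set_index(["cluster", "variable"])

    cat_shares = {}
    for name in table.categorical_names:
        spec = table.variable(name)
        share = (
            df.groupby("_cluster")[name]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=list(spec.categories), fill_value=0.0)
        )
        cat_shares[name] = share
    return ClusterSummary(sizes, numeric_stats, cat_shares)


def export_clusters(
    model: ClusterModel,
    table: DataTable,
    path,
    points: list[LayoutPoint] | None = None,
) -> Path:
    """Write the clustered rows as CSV: original columns + layout
    coordinates (when given) + cluster index.  Re-loadable by the data
    module; labels containing commas are quoted."""
    path = Path(path)
    df = table.df.loc[model.row_ids].copy()
    if points is not None:
        by_id = {p.row_id: p for p in points}
        df["x"] = [by_id[r].x for r in model.row_ids]
        df["y"] = [by_id[r].y for r in model.row_ids]
        df["z"] = [by_id[r].z for r in model.row_ids]
    df["cluster"] = model.assignments
    df.index.name = "id"
    df.to_csv(path, quoting=csv.QUOTE_MINIMAL)
    return path


def load_exported_clusters(path) -> tuple[DataTable, np.ndarray]:
    """Round-trip helper: read an export back, returning the table (all
    columns, inferred schema) and the cluster assignment vector."""
    table = load_table(path, schema="infer")
    assignments = table.df["cluster"].to_numpy(dtype=int)
    return table, assignments
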