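"""Batch pipeline: simulate/load -> filter -> layout -> cluster -> export.

The interactive workflow (pick variables, lay the cohort out, segment it,
inspect the clusters, export) is realised non-interactively: a single
:class:`RunConfig` drives every stage, a JSON manifest records all
parameters and seeds, and identical config + seed yields byte-identical
CSV outputs.  Any stage failure is reported with the stage named and
partially written outputs are removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cluster import export_clusters, kmeans, summarize_clusters
from .data import DataTable, load_schema, load_table, normalize, save_schema, select_variables, write_table
from .filters import FilterSet, apply_filter, build_axes
from .radvis import layout_table, make_anchors
from .simulate import ITEM_NAMES, default_separated_config, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("stratavis")
    except Exception:
        return "unknown"

DEFAULT_AXES = ["diagnosis", "gender", "education_level", "education_years", "age", *ITEM_NAMES]


@dataclass
class RunConfig:
    """Everything one pipeline run needs.  Exactly one of ``input_path`` /
    ``simulate`` must be set."""

    output_dir: str
    input_path: str | None = None
    schema_path: str | None = None
    simulate: dict | None = None                  # {"n": int, "seed": int}
    anchor_variables: list[str] = field(default_factory=lambda: list(ITEM_NAMES))
    axis_variables: list[str] = field(default_factory=lambda: list(DEFAULT_AXES))
    layout_mode: str = "radvis3d"
    cluster: dict | None = None                   # {"k", "init", "seed", "space", "restarts"}
    filters: list[str] = field(default_factory=list)
    render: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be given")
        if self.layout_mode not in ("radvis2d", "radvis3d"):
            raise ValueError(f"unknown layout mode {self.layout_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "input_path": self.input_path,
            "schema_path": self.schema_path,
            "simulate": self.simulate,
            "anchor_variables": list(self.anchor_variables),
            "axis_variables": list(self.axis_variables),
            "layout_mode": self.layout_mode,
            "cluster": self.cluster,
            "filters": list(self.filters),
            "render": self.render,
        }


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_layout_csv(points, table: DataTable, path: Path) -> None:
    df = table.df.loc[[p.row_id for p in points]].copy()
    out = df[[c for c in ("diagnosis", "gender") if c in df.columns]].copy()
    out["x"] = [f"{p.x:.12g}" for p in points]
    out["y"] = [f"{p.y:.12g}" for p in points]
    out["z"] = [f"{p.z:.12g}" for p in points]
    out.index.name = "id"
    out.to_csv(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dict.

    Outputs in ``config.output_dir``: ``cohort.csv`` + ``schema.yaml``
    (simulated inputs), ``filtered.csv`` (when filters are set),
    ``layout.csv``, ``clusters.csv`` + ``cluster_summary.json`` (when a
    cluster block is set), optional HTML renders, and ``manifest.json``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings_log: list[str] = []

    class _Capture(logging.Handler):
        def emit(self, record):  # machine-readable warnings in the manifest
            if record.levelno >= logging.WARNING:
                warnings_log.append(record.getMessage())

    capture = _Capture()
    logging.getLogger("stratavis").addHandler(capture)

    def _track(path: Path) -> Path:
        written.append(path)
        return path

    stage = "init"
    try:
        # --- input -------------------------------------------------------
        stage = "input"
        if config.simulate is not None:
            sim = dict(config.simulate)
            cohort_cfg = default_separated_config(int(sim["n"]), int(sim["seed"]))
            table = generate_cohort(cohort_cfg)
            write_table(table, _track(outdir / "cohort.csv"))
            save_schema(table.variables, _track(outdir / "schema.yaml"))
            sim_params = cohort_cfg.to_dict()
        else:
            schema = "infer" if config.schema_path is None else load_schema(config.schema_path)
            table = load_table(config.input_path, schema=schema)
            sim_params = None

        # --- filtering ---------------------------------------------------
        stage = "filter"
        if config.filters:
            fs = FilterSet.parse(list(config.filters), table)
            table = apply_filter(table, fs)
            write_table(table, _track(outdir / "filtered.csv"))

        # --- layout ------------------------------------------------------
        stage = "layout"
        anchor_specs = select_variables(table, list(config.anchor_variables), "anchors")
        anchors = make_anchors(anchor_specs)
        u = normalize(table, anchor_specs)
        points = layout_table(u, anchors, mode=config.layout_mode)
        _write_layout_csv(points, table, _track(outdir / "layout.csv"))

        # --- clustering --------------------------------------------------
        stage = "cluster"
        model = None
        summary = None
        if config.cluster:
            cl = dict(config.cluster)
            space = cl.get("space", "layout3d")
            if space == "layout3d":
                import numpy as np

                pts = np.array([[p.x, p.y, p.z] for p in points])
                cylinder = (anchors.radius, anchors.height)
            elif space == "feature":
                pts = u.u
                cylinder = None
            else:
                raise ValueError(f"unknown cluster space {space!r}")
            model = kmeans(
                pts,
                k=int(cl["k"]),
                init=cl.get("init", "forgy"),
                seed=int(cl.get("seed", 0)),
                cylinder=cylinder,
                restarts=int(cl.get("restarts", 1)),
                space=space,
                row_ids=u.row_ids,
            )
            export_clusters(model, table, _track(outdir / "clusters.csv"), points=points)
            summary = summarize_clusters(model, table)
            (_track(outdir / "cluster_summary.json")).write_text(
                json.dumps(summary.to_dict(), indent=2, sort_keys=True)
            )

        # --- render ------------------------------------------------------
        stage = "render"
        if config.render:
            try:
                from .render import render_parallel_coordinates, render_radvis

                render_radvis(
                    points, anchors, _track(outdir / "radvis.html"),
                    clusters=model, table=table, mode=config.layout_mode,
                )
                axes = build_axes(table, list(config.axis_variables))
                render_parallel_coordinates(
                    table, axes, _track(outdir / "parallel_coordinates.html"),
                    clusters=model,
                )
            except Exception as exc:  # renders must never corrupt data outputs
                logger.warning("render skipped: %s", exc)

        # --- manifest ----------------------------------------------------
        stage = "manifest"
        manifest = {
            "package": "stratavis",
            "version": _version(),
            "config": config.to_dict(),
            "simulate_params": sim_params,
            "n_rows_input": table.n_rows,
            "n_rows_laid_out": len(points),
            "dropped_rows": list(map(str, u.dropped_ids)),
            "cluster": None
            if model is None
            else {
                "k": model.k,
                "init": model.init,
                "seed": model.seed,
                "space": model.space,
                "n_iterations": model.n_iterations,
                "converged": model.converged,
                "inertia": model.inertia,
                "sizes": {str(c): int(s) for c, s in summary.sizes.items()},
            },
            "warnings": warnings_log,
            "outputs": sorted(p.name for p in written),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        for p in written:  # remove partial outputs so reruns start clean
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    finally:
        logging.getLogger("stratavis").removeHandler(capture)
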