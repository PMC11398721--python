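"""Experiment configuration, presets, and the pipeline runner.

A single :class:`ExperimentConfig` describes the graph source, the
model parameters, and the analysis stages to run; it serializes
losslessly to YAML, and every random draw in a run derives from its
master seed (run *k* of a multi-run stage uses ``seed + k``).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import communities as _communities
from . import scta as _scta
from . import sweeps as _sweeps
from . import transients as _transients
from .dynamics import ModelParams, simulate
from .graph import (NetworkGraph, load_connectome, make_random,
                    make_scale_free, make_small_world,
                    make_synthetic_connectome, save_graph)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "validate_config", "run_experiment", "PRESETS"]

KNOWN_STAGES = ("hysteresis", "bifurcation", "simulate", "transients",
                "communities", "scta", "ratio_sweep")


@dataclass
class ExperimentConfig:
    name: str = "experiment"
    graph: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    seed: int = 0

    # -- serialization --------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_yaml(src) -> "ExperimentConfig":
        p = Path(str(src))
        text = p.read_text() if p.exists() else str(src)
        data = yaml.safe_load(text)
        return ExperimentConfig(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _model_params(cfg: ExperimentConfig, **override) -> ModelParams:
    kw = dict(cfg.model)
    kw.setdefault("seed", cfg.seed)
    kw.update(override)
    if "omega_range" in kw:
        kw["omega_range"] = tuple(kw["omega_range"])
    if kw.get("lambda_o") is not None and kw.get("fixed_lambda") is not None:
        raise ValueError("config sets both lambda_o and fixed_lambda")
    return ModelParams(**kw)


def build_graph(cfg: ExperimentConfig) -> NetworkGraph:
    spec = dict(cfg.graph)
    family = spec.pop("family", None)
    spec.setdefault("seed", cfg.seed)
    if family == "sw":
        return make_small_world(**spec)
    if family == "sf":
        return make_scale_free(**spec)
    if family == "er":
        return make_random(**spec)
    if family == "synthetic":
        return make_synthetic_connectome(**spec)
    if family == "file":
        spec.pop("seed", None)
        path = spec.pop("path", None)
        if not path or not Path(path).exists():
            raise FileNotFoundError(
                "this preset needs an external connectome file; set "
                "graph.path to its location (edge list or dense CSV)")
        return load_connectome(path, **spec)
    raise ValueError(f"unknown graph family {family!r}")


# ---------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------

def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Collect (rather than raise one-by-one) every config problem."""
    errors: list[str] = []
    if cfg.graph.get("family") not in ("sw", "sf", "er", "synthetic", "file"):
        errors.append(f"unknown graph family {cfg.graph.get('family')!r}")
    m = cfg.model
    for key in ("alpha", "beta", "dt"):
        if key in m and not (isinstance(m[key], (int, float)) and m[key] > 0):
            errors.append(f"model.{key} must be positive")
    if m.get("lambda_o") is not None and m.get("fixed_lambda") is not None:
        errors.append("model sets both lambda_o and fixed_lambda")
    for stage, opts in cfg.stages.items():
        if stage not in KNOWN_STAGES:
            errors.append(f"unknown stage {stage!r}")
            continue
        if stage == "ratio_sweep" and not opts.get("beta_list"):
            errors.append("ratio_sweep needs a non-empty beta_list")
        if stage in ("bifurcation", "ratio_sweep"):
            grid = opts.get("lambda_o_grid")
            if grid is not None and len(grid) == 0:
                errors.append(f"{stage} lambda_o_grid is empty")
    if not cfg.stages:
        errors.append("no stages requested")
    return errors


# ---------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------

def _grid(opts: dict) -> np.ndarray:
    if "lambda_o_grid" in opts:
        return np.asarray(opts["lambda_o_grid"], dtype=float)
    return np.arange(opts.get("lambda_o_start", 0.01),
                     opts.get("lambda_o_stop", 0.30) + 1e-12,
                     opts.get("lambda_o_step", 0.01))


def run_experiment(cfg: ExperimentConfig, outdir) -> dict[str, Any]:
    """Execute the configured stages and write results plus a manifest.

    Re-running the same config reproduces identical numeric outputs.
    Returns a summary dict (also written as ``summary.json``).
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    g = build_graph(cfg)
    save_graph(g, out / "graph.edges")
    summary: dict[str, Any] = {}
    windows = None

    for stage, opts in cfg.stages.items():
        opts = dict(opts)
        logger.info("stage %s", stage)
        if stage == "hysteresis":
            p = _model_params(cfg, fixed_lambda=0.0, lambda_o=None)
            curve = _sweeps.hysteresis(
                g, p, opts.get("lambda_start", 0.0),
                opts.get("lambda_end", 0.12), opts.get("delta", 0.003),
                opts.get("dwell", 50.0))
            curve.to_frame().to_csv(out / "hysteresis.csv", index=False)
            summary["hysteresis"] = {
                "tipping_forward": curve.tipping_forward,
                "tipping_backward": curve.tipping_backward,
                "has_hysteresis": curve.has_hysteresis}
        elif stage == "bifurcation":
            grid = _grid(opts)
            p = _model_params(cfg, lambda_o=float(grid[0]), fixed_lambda=None)
            diag = _sweeps.bifurcation_sweep(
                g, p, grid, dwell=opts.get("dwell", 500.0),
                R_low=opts.get("R_low", 0.2), R_high=opts.get("R_high", 0.5))
            diag.to_frame().to_csv(out / "bifurcation.csv", index=False)
            summary["bifurcation"] = {
                "left_boundary": diag.left_boundary,
                "right_boundary": diag.right_boundary,
                "tes_probability": _sweeps.tes_probability(diag)}
        elif stage == "simulate":
            p = _model_params(cfg)
            traj = simulate(g, p, opts.get("duration", 1000.0),
                            record_stride=opts.get("record_stride", 0.2),
                            record_per_node=opts.get("per_node", False))
            traj.save(out / "trajectory")
            summary["simulate"] = {"R_final": float(traj.R[-1])}
        elif stage == "transients":
            p = _model_params(cfg, lambda_o=opts.get("lambda_o",
                                                     cfg.model.get("lambda_o")),
                              fixed_lambda=None)
            windows = _transients.extract_transients(
                g, p, n_runs=opts.get("n_runs", 4),
                run_duration=opts.get("run_duration", 2000.0),
                window=opts.get("window", 50.0),
                seeds=[cfg.seed + k for k in range(opts.get("n_runs", 4))],
                record_stride=opts.get("record_stride", 0.2),
                desync_threshold=opts.get("desync_threshold", 0.1),
                sync_threshold=opts.get("sync_threshold", 0.5))
            _transients.save_windows(windows, out / "transients")
            summary["transients"] = {"n_windows": len(windows)}
        elif stage == "communities":
            part = _communities.detect_communities(
                g, resolution=opts.get("resolution", 1.0), seed=cfg.seed)
            part.to_frame().to_csv(out / "partition.csv", index=False)
            summary["communities"] = {"n_communities": part.n_communities,
                                      "modularity": part.modularity}
            if windows:
                ims = _communities.intramodular_synchrony(windows, part)
                ims.to_csv(out / "intramodular.csv", index=False)
                ims2 = _communities.intermodular_synchrony(windows, part)
                ims2.to_csv(out / "intermodular.csv", index=False)
        elif stage == "scta":
            if not windows:
                logger.warning("scta stage skipped: no transient windows")
                summary["scta"] = {"n_lineages": 0}
                continue
            lineages = [_scta.track_clusters(
                w, g, threshold=opts.get("threshold", 0.5),
                eval_stride=opts.get("eval_stride", 0.2)) for w in windows]
            table = _scta.lineage_stats_table(
                lineages, g, opts.get("min_out_degree", 30),
                opts.get("min_median", 35), opts.get("max_variance", 49))
            table.to_csv(out / "scta_stats.csv", index=False)
            summary["scta"] = {"n_lineages": len(lineages),
                               "n_drivers": int(table["driver"].sum())}
        elif stage == "ratio_sweep":
            grid = _grid(opts)
            p = _model_params(cfg, lambda_o=float(grid[0]), fixed_lambda=None)
            df = _sweeps.ratio_sweep(
                g, alpha=opts.get("alpha", p.alpha),
                beta_list=opts["beta_list"], lambda_o_grid=grid,
                dwell=opts.get("dwell", 500.0), base_params=p)
            df.to_csv(out / "ratio_sweep.csv", index=False)
            summary["ratio_sweep"] = {
                "ratios": df["ratio"].tolist(),
                "widths": df["width"].tolist()}

    manifest = {"config": asdict(cfg), "config_digest": cfg.digest(),
                "seed": cfg.seed, "wall_time_s": round(_time.time() - t0, 3)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    cfg.to_yaml(out / "config.yaml")
    return summary


# ---------------------------------------------------------------------
# presets: the parameter sets of the standard experiment sequence
# ---------------------------------------------------------------------

def _swn_graph() -> dict[str, Any]:
    return {"family": "sw", "n": 400, "mean_degree": 40, "rewire_p": 0.232}


PRESETS: dict[str, ExperimentConfig] = {
    # fixed-resource hysteresis + resource-constrained bifurcation on the
    # benchmark small-world network
    "swn-tes": ExperimentConfig(
        name="swn-tes", graph=_swn_graph(),
        model={"alpha": 0.01, "beta": 0.002, "dt": 0.05},
        stages={
            "hysteresis": {"lambda_start": 0.0, "lambda_end": 0.12,
                           "delta": 0.003, "dwell": 50.0},
            "bifurcation": {"lambda_o_start": 0.01, "lambda_o_stop": 0.30,
                            "lambda_o_step": 0.01, "dwell": 500.0},
        }),
    # recovery-to-consumption ratio analysis on the same network
    "swn-ratio": ExperimentConfig(
        name="swn-ratio", graph=_swn_graph(),
        model={"alpha": 0.01, "beta": 0.002, "dt": 0.05},
        stages={"ratio_sweep": {
            "alpha": 0.01,
            "beta_list": [0.01, 0.005, 0.002, 0.001, 0.0005, 0.00025, 0.0002],
            "lambda_o_start": 0.01, "lambda_o_stop": 0.30,
            "lambda_o_step": 0.01, "dwell": 500.0}}),
    # full propagation pipeline on the built-in synthetic connectome
    "fixture-propagation": ExperimentConfig(
        name="fixture-propagation",
        graph={"family": "synthetic", "n_regions": 60, "n_modules": 3,
               "intra_density": 0.5, "inter_density": 0.05,
               "module_strengths": [1.0, 1.0, 0.1]},
        model={"alpha": 0.01, "beta": 0.002, "dt": 0.05, "lambda_o": 1.0},
        stages={
            "transients": {"n_runs": 4, "run_duration": 2000.0,
                           "window": 50.0, "lambda_o": 1.0,
                           "desync_threshold": 0.2, "sync_threshold": 0.6},
            "communities": {"resolution": 1.0},
            "scta": {"threshold": 0.5, "eval_stride": 0.2},
        }),
    # mesoscale-connectome pipeline; needs a user-supplied file
    "mbn-tes": ExperimentConfig(
        name="mbn-tes",
        graph={"family": "file", "path": ""},
        model={"alpha": 0.01, "beta": 0.002, "dt": 0.05, "lambda_o": 2.87},
        stages={
            "bifurcation": {"lambda_o_start": 2.0, "lambda_o_stop": 3.4,
                            "lambda_o_step": 0.02, "dwell": 2000.0,
                            "R_high": 0.45},
            "transients": {"n_runs": 4, "run_duration": 20000.0,
                           "window": 50.0, "lambda_o": 2.87},
            "communities": {"resolution": 1.0},
            "scta": {"threshold": 0.5, "eval_stride": 0.2},
        }),
}
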