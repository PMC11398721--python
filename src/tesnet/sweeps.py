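"""Adiabatic hysteresis sweeps, bifurcation diagrams over the resource
bath size, tipping-point detection and the recovery-to-consumption
ratio analysis.

Two distinct notions are kept apart deliberately:

* *hysteresis* — forward and backward adiabatic branches of the
  fixed-resource model disagree over an interval of Λ;
* *bistability* — a single resource-constrained run at one λ_o visits
  both the incoherent and the synchronized state within the dwell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dynamics import ModelParams, OscillatorState, Trajectory, init_state, \
    simulate
from .graph import NetworkGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SweepBranch", "HysteresisCurve", "BifurcationDiagram",
    "adiabatic_sweep", "hysteresis", "detect_tipping", "bifurcation_sweep",
    "state_space_trace", "ratio_sweep", "ratio_grid", "tes_probability",
    "sync_time_trend",
]


@dataclass
class SweepBranch:
    """One direction of an adiabatic sweep: stationary R per Λ, in
    traversal order."""

    lambda_grid: np.ndarray
    R_stationary: np.ndarray
    direction: str  # "forward" | "backward"
    final_state: Optional[OscillatorState] = field(default=None, repr=False)


@dataclass
class HysteresisCurve:
    forward: SweepBranch
    backward: SweepBranch
    tipping_forward: Optional[float]
    tipping_backward: Optional[float]

    @property
    def has_hysteresis(self) -> bool:
        if self.tipping_forward is None or self.tipping_backward is None:
            return False
        return self.tipping_backward < self.tipping_forward

    def to_frame(self) -> pd.DataFrame:
        fw = pd.DataFrame({"Lambda": self.forward.lambda_grid,
                           "R": self.forward.R_stationary,
                           "direction": "forward"})
        bw = pd.DataFrame({"Lambda": self.backward.lambda_grid,
                           "R": self.backward.R_stationary,
                           "direction": "backward"})
        return pd.concat([fw, bw], ignore_index=True)


@dataclass
class BifurcationDiagram:
    """Range of the order parameter per λ_o, with a three-way state
    classification and the fraction of time spent synchronized."""

    lambda_o_grid: np.ndarray
    R_min: np.ndarray
    R_max: np.ndarray
    state_class: list[str]          # incoherent | bistable | synchronized
    sync_fraction: np.ndarray       # 〈t_s〉 per λ_o
    left_boundary: Optional[float]  # first λ_o classified bistable
    right_boundary: Optional[float]  # last λ_o classified bistable
    R_low: float = 0.2
    R_high: float = 0.5

    @property
    def grid_step(self) -> float:
        g = self.lambda_o_grid
        return float(g[1] - g[0]) if len(g) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda_o": self.lambda_o_grid,
                             "R_min": self.R_min, "R_max": self.R_max,
                             "state": self.state_class,
                             "sync_fraction": self.sync_fraction})


# ---------------------------------------------------------------------
# fixed-resource (Λ) sweeps
# ---------------------------------------------------------------------

def adiabatic_sweep(g: NetworkGraph, p: ModelParams, lambda_start: float,
                    lambda_end: float, delta: float, dwell: float,
                    direction: str = "forward",
                    state: Optional[OscillatorState] = None,
                    stationary_frac: float = 0.25,
                    record_stride: float = 0.2) -> SweepBranch:
    """Adiabatically sweep the fixed resource Λ and record stationary R.

    The oscillator state is carried over between consecutive Λ values
    (warm start), which is what makes the protocol adiabatic.
    Stationary R is the mean of R over the last ``stationary_frac`` of
    each dwell.
    """
    if p.mode != "fixed":
        raise ValueError("adiabatic_sweep needs fixed-resource mode params")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    lo, hi = sorted((lambda_start, lambda_end))
    grid = np.arange(lo, hi + delta / 2, delta)
    if direction == "backward":
        grid = grid[::-1]

    if state is None:
        state = init_state(g, p.with_(fixed_lambda=float(grid[0])))
    Rs = np.empty(len(grid))
    for k, lam in enumerate(grid):
        pk = p.with_(fixed_lambda=float(lam))
        traj = simulate(g, pk, dwell, record_stride=record_stride, state=state)
        state = traj.final_state
        tail = max(1, int(len(traj.R) * stationary_frac))
        Rs[k] = traj.R[-tail:].mean()
    return SweepBranch(grid, Rs, direction, final_state=state)


def detect_tipping(branch: SweepBranch,
                   jump_threshold: float = 0.2) -> Optional[float]:
    """Λ at the largest single-step jump in stationary R exceeding
    ``jump_threshold`` (the grid value at which the new state is first
    seen, in traversal order); None if no jump qualifies."""
    R = branch.R_stationary
    if len(R) < 2:
        return None
    jumps = np.abs(np.diff(R))
    k = int(np.argmax(jumps))
    if jumps[k] <= jump_threshold:
        return None
    return float(branch.lambda_grid[k + 1])


def hysteresis(g: NetworkGraph, p: ModelParams, lambda_start: float = 0.0,
               lambda_end: float = 0.12, delta: float = 0.003,
               dwell: float = 50.0, jump_threshold: float = 0.2,
               **kw) -> HysteresisCurve:
    """Forward sweep from ``lambda_start`` then backward from
    ``lambda_end``, with the backward branch warm-started from the end
    of the forward branch."""
    fw = adiabatic_sweep(g, p, lambda_start, lambda_end, delta, dwell,
                         "forward", **kw)
    bw = adiabatic_sweep(g, p, lambda_start, lambda_end, delta, dwell,
                         "backward", state=fw.final_state, **kw)
    return HysteresisCurve(fw, bw,
                           tipping_forward=detect_tipping(fw, jump_threshold),
                           tipping_backward=detect_tipping(bw, jump_threshold))


# ---------------------------------------------------------------------
# resource-constrained (λ_o) sweeps
# ---------------------------------------------------------------------

def bifurcation_sweep(g: NetworkGraph, p: ModelParams,
                      lambda_o_grid: Sequence[float], dwell: float = 500.0,
                      R_low: float = 0.2, R_high: float = 0.5,
                      burn_in_frac: float = 0.2, warm_start: bool = True,
                      record_stride: float = 0.2) -> BifurcationDiagram:
    """Classify each λ_o as incoherent, bistable, or synchronized.

    After discarding the first ``burn_in_frac`` of each dwell:
    incoherent if R never exceeds ``R_high``; synchronized if R never
    falls below ``R_low``; bistable if both R < R_low and R > R_high
    are visited.  〈t_s〉 is the fraction of recorded samples with
    R > R_high.  With ``warm_start`` the oscillator state is carried
    across consecutive λ_o values (adiabatic progression).
    """
    if p.mode != "resource":
        raise ValueError("bifurcation_sweep needs resource-mode params")
    if not 0.0 < R_low < R_high < 1.0:
        raise ValueError("thresholds must satisfy 0 < R_low < R_high < 1")
    grid = np.asarray(list(lambda_o_grid), dtype=float)
    R_min = np.empty(len(grid))
    R_max = np.empty(len(grid))
    sync_frac = np.empty(len(grid))
    classes: list[str] = []
    state = None
    for k, lo in enumerate(grid):
        pk = p.with_(lambda_o=float(lo))
        if state is None:
            state = init_state(g, pk)
        else:
            state.lam[:] = np.minimum(state.lam, lo)
        traj = simulate(g, pk, dwell, record_stride=record_stride, state=state)
        if warm_start:
            state = traj.final_state
        else:
            state = None
        body = traj.R[int(len(traj.R) * burn_in_frac):]
        R_min[k], R_max[k] = body.min(), body.max()
        sync_frac[k] = float((body > R_high).mean())
        if R_max[k] < R_high:
            classes.append("incoherent")
        elif R_min[k] > R_low:
            classes.append("synchronized")
        else:
            classes.append("bistable")
    bist = [i for i, c in enumerate(classes) if c == "bistable"]
    left = float(grid[bist[0]]) if bist else None
    right = float(grid[bist[-1]]) if bist else None
    return BifurcationDiagram(grid, R_min, R_max, classes, sync_frac,
                              left, right, R_low=R_low, R_high=R_high)


def state_space_trace(traj: Trajectory,
                      node_subset: Optional[Sequence[int]] = None
                      ) -> np.ndarray:
    """Time-ordered (〈λ〉, R) pairs; restricting to ``node_subset``
    changes only the 〈λ〉 coordinate (requires per-node recording)."""
    if node_subset is None:
        ml = traj.mean_lambda
    else:
        idx = np.asarray(list(node_subset), dtype=int)
        if idx.size == 0:
            raise ValueError("node_subset must not be empty")
        if traj.lam_panel is None:
            raise ValueError("trajectory lacks per-node resource recording")
        ml = traj.lam_panel[:, idx].mean(axis=1)
    return np.column_stack([ml, traj.R])


def tes_probability(diagram: BifurcationDiagram) -> Optional[float]:
    """Probability of tES occurrence: area under 〈t_s〉(λ_o) across the
    bistable region, normalised by the area of the enclosing rectangle
    (width × 1)."""
    if diagram.left_boundary is None:
        logger.info("no bistable region; tES probability undefined")
        return None
    sel = (diagram.lambda_o_grid >= diagram.left_boundary) & \
          (diagram.lambda_o_grid <= diagram.right_boundary)
    x = diagram.lambda_o_grid[sel]
    y = diagram.sync_fraction[sel]
    if len(x) < 2:
        logger.info("bistable region has a single grid point; "
                    "tES probability undefined")
        return None
    area = np.trapezoid(y, x)
    return float(area / (x[-1] - x[0]))


def ratio_grid(alpha: float, beta: float, n_points: int = 30) -> np.ndarray:
    """A λ_o grid adapted to one recovery/consumption ratio.

    The bistable region scales roughly with the consumption-to-recovery
    ratio β/α (consumption depresses the steady resource level by about
    (β/α)·r), so a single fixed grid cannot resolve the boundaries
    across a 50-fold range of ratios.  The grid spans [step, 0.1 +
    1.25 β/α] in ``n_points`` uniform steps.
    """
    stop = 0.1 + 1.25 * beta / alpha
    step = stop / n_points
    return np.arange(step, stop + step / 2, step)


def ratio_sweep(g: NetworkGraph, alpha: float, beta_list: Sequence[float],
                lambda_o_grid: Optional[Sequence[float]] = None,
                dwell: float = 500.0,
                base_params: Optional[ModelParams] = None,
                **kw) -> pd.DataFrame:
    """Bifurcation sweep per consumption rate β at fixed recovery rate α.

    Returns one row per β with the bistable-region boundaries, its
    width, and the tES probability, indexed by the recovery-to-
    consumption ratio α/β.  With ``lambda_o_grid=None`` each β gets a
    ratio-adapted grid from :func:`ratio_grid`.
    """
    if alpha <= 0 or any(b <= 0 for b in beta_list):
        raise ValueError("rates must be positive")
    if base_params is None:
        base_params = ModelParams(alpha=alpha, beta=float(beta_list[0]),
                                  lambda_o=1.0)
    rows = []
    for beta in beta_list:
        grid = (ratio_grid(alpha, beta) if lambda_o_grid is None
                else np.asarray(lambda_o_grid, dtype=float))
        p = base_params.with_(alpha=alpha, beta=float(beta),
                              lambda_o=float(grid[0]))
        diag = bifurcation_sweep(g, p, grid, dwell=dwell, **kw)
        rows.append({
            "alpha": alpha, "beta": beta, "ratio": alpha / beta,
            "left_boundary": diag.left_boundary,
            "right_boundary": diag.right_boundary,
            "width": (None if diag.left_boundary is None
                      else diag.right_boundary - diag.left_boundary),
            "tes_probability": tes_probability(diag),
        })
    return pd.DataFrame(rows).sort_values("ratio").reset_index(drop=True)


def sync_time_trend(diagram: BifurcationDiagram) -> float:
    """Spearman correlation of 〈t_s〉 with λ_o over the bistable region
    (positive when more resources mean more time synchronized)."""
    if diagram.left_boundary is None:
        return float("nan")
    sel = (diagram.lambda_o_grid >= diagram.left_boundary) & \
          (diagram.lambda_o_grid <= diagram.right_boundary)
    if sel.sum() < 3:
        return float("nan")
    rho, _ = spearmanr(diagram.lambda_o_grid[sel], diagram.sync_fraction[sel])
    return float(rho)
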