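"""Detection and extraction of transient synchronization events.

A tES event starts at an *onset index*: the last instant of
near-complete desynchronization before the order parameter rises
abruptly above the synchronized level.  Propagation analyses work on
fixed-length per-node phase windows aligned to that onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dynamics import ModelParams, Trajectory, simulate
from .graph import NetworkGraph

__all__ = ["TransientWindow", "find_onset_indices", "extract_transients",
           "active_nodes"]


@dataclass
class TransientWindow:
    """Per-node phases and local synchrony over one onset-aligned window."""

    onset_time: float
    duration: float
    stride: float
    theta_panel: np.ndarray   # (T, n) phases
    r_panel: np.ndarray       # (T, n) local synchrony
    lam_panel: Optional[np.ndarray] = None
    run_id: int = 0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.theta_panel.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.theta_panel.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Times relative to onset."""
        return np.arange(self.n_samples) * self.stride


def find_onset_indices(traj: Trajectory, desync_threshold: float = 0.1,
                       sync_threshold: float = 0.5,
                       refractory: float = 100.0) -> np.ndarray:
    """Onset times of abrupt transitions in a global-order trace.

    For each upward crossing of ``sync_threshold`` the onset is the
    latest preceding time with R < ``desync_threshold`` (near-complete
    desynchronization).  Crossings within ``refractory`` time units of
    the previous accepted onset are skipped.  Returns an array of
    times, possibly empty.
    """
    R = np.asarray(traj.R)
    t = np.asarray(traj.times)
    up = np.flatnonzero((R[1:] >= sync_threshold) & (R[:-1] < sync_threshold)) + 1
    onsets: list[float] = []
    last = -np.inf
    for k in up:
        if t[k] - last < refractory:
            continue
        below = np.flatnonzero(R[:k] < desync_threshold)
        if below.size == 0:
            continue
        onset = t[below[-1]]
        if onset <= last:
            continue
        onsets.append(float(onset))
        last = onset
    return np.asarray(onsets)


def extract_transients(g: NetworkGraph, p: ModelParams, n_runs: int,
                       run_duration: float, window: float = 50.0,
                       seeds: Optional[Sequence[int]] = None,
                       record_stride: float = 0.2,
                       desync_threshold: float = 0.1,
                       sync_threshold: float = 0.5,
                       refractory: float = 100.0) -> list[TransientWindow]:
    """Run ``n_runs`` independent simulations and cut an onset-aligned
    window of length ``window`` out of every detected transition.

    Each run gets its own seed (``p.seed + run`` unless ``seeds`` is
    given), i.e. distinct initial conditions.  Windows that would cross
    the end of a run are dropped.
    """
    if p.mode != "resource":
        raise ValueError("transient extraction needs resource-mode params")
    if window > run_duration:
        raise ValueError("window longer than the run")
    if seeds is None:
        seeds = [p.seed + k for k in range(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")

    out: list[TransientWindow] = []
    n_win = round(window / record_stride)
    for run, seed in enumerate(seeds):
        traj = simulate(g, p.with_(seed=int(seed)), run_duration,
                        record_stride=record_stride, record_per_node=True)
        onsets = find_onset_indices(traj, desync_threshold, sync_threshold,
                                    refractory)
        for onset in onsets:
            k0 = round(onset / record_stride)
            k1 = k0 + n_win
            if k1 >= len(traj.times):
                continue
            out.append(TransientWindow(
                onset_time=float(onset), duration=window,
                stride=record_stride,
                theta_panel=traj.theta_panel[k0:k1 + 1].copy(),
                r_panel=traj.r_panel[k0:k1 + 1].copy(),
                lam_panel=traj.lam_panel[k0:k1 + 1].copy(),
                run_id=run, seed=int(seed)))
    return out


def active_nodes(window: TransientWindow, r_threshold: float = 0.7,
                 plateau_frac: float = 0.2) -> set[int]:
    """Nodes actively participating in the synchronized state: mean
    local synchrony over the final ``plateau_frac`` of the window above
    ``r_threshold``."""
    n_tail = max(1, int(window.n_samples * plateau_frac))
    mean_r = window.r_panel[-n_tail:].mean(axis=0)
    return set(np.flatnonzero(mean_r > r_threshold).tolist())


# ---------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------

def save_windows(windows: list[TransientWindow], basepath) -> None:
    """Compressed array archive plus a JSON manifest of onsets/seeds."""
    base = Path(basepath)
    arrays = {}
    manifest = []
    for k, w in enumerate(windows):
        arrays[f"theta_{k}"] = w.theta_panel
        arrays[f"r_{k}"] = w.r_panel
        if w.lam_panel is not None:
            arrays[f"lam_{k}"] = w.lam_panel
        manifest.append({"onset_time": w.onset_time, "duration": w.duration,
                         "stride": w.stride, "run_id": w.run_id,
                         "seed": w.seed})
    np.savez_compressed(base.with_suffix(".npz"), **arrays)
    base.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_windows(basepath) -> list[TransientWindow]:
    base = Path(basepath)
    manifest = json.loads(base.with_suffix(".json").read_text())
    out = []
    with np.load(base.with_suffix(".npz")) as z:
        for k, meta in enumerate(manifest):
            out.append(TransientWindow(
                onset_time=meta["onset_time"], duration=meta["duration"],
                stride=meta["stride"], theta_panel=z[f"theta_{k}"],
                r_panel=z[f"r_{k}"],
                lam_panel=z[f"lam_{k}"] if f"lam_{k}" in z else None,
                run_id=meta["run_id"], seed=meta["seed"]))
    return out
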