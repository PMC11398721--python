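"""Shared fixtures: small graphs and the brain-like synthetic
connectome with its transient windows (computed once per session)."""

import numpy as np
import pytest

import tesnet as tn

FIXTURE_LAMBDA_O = 1.0
FIXTURE_STRENGTHS = (1.0, 1.0, 0.1)
# detection thresholds adapted to n=60 (incoherent floor ~ 1/sqrt(n))
FIXTURE_DESYNC = 0.2
FIXTURE_SYNC = 0.6


@pytest.fixture(scope="session")
def swn400():
    return tn.make_small_world(400, 40, 0.232, seed=0)


@pytest.fixture(scope="session")
def connectome():
    """Modular, weighted, directed, mirrored brain-like fixture with one
    weakly coupled module (indices 2 and 5 after mirroring)."""
    return tn.make_synthetic_connectome(
        60, 3, 0.5, 0.05, seed=0, module_strengths=FIXTURE_STRENGTHS)


@pytest.fixture(scope="session")
def fixture_params():
    return tn.ModelParams(alpha=0.01, beta=0.002, dt=0.05,
                          lambda_o=FIXTURE_LAMBDA_O, seed=0)


@pytest.fixture(scope="session")
def fixture_windows(connectome, fixture_params):
    """Onset-aligned transient windows from four runs of the fixture in
    its bistable regime."""
    windows = tn.extract_transients(
        connectome, fixture_params, n_runs=4, run_duration=2000.0,
        window=50.0, record_stride=0.2,
        desync_threshold=FIXTURE_DESYNC, sync_threshold=FIXTURE_SYNC)
    assert windows, "fixture must produce transients in its bistable regime"
    return windows


@pytest.fixture(scope="session")
def fixture_partition(connectome):
    return tn.detect_communities(connectome, resolution=1.0, seed=0)


def planted_partition(g):
    """CommunityPartition built from the generator's planted modules."""
    mapping = dict(g.module_of_node)
    return tn.CommunityPartition(mapping, len(set(mapping.values())),
                                 modularity=float("nan"))


def weak_module_nodes(g):
    """Nodes of the weakly coupled planted module (both hemispheres)."""
    mods = np.array([g.module_of_node[i] for i in range(g.n_nodes)])
    return np.flatnonzero(mods == 2)
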