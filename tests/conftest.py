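"""Shared fixtures.

The expensive fixture is ``trained_reduced``: a reduced-scale training
run (N = 1000, Q = 4 clusters, 2 simulated minutes) followed by 60 s of
stimulus-free ongoing activity.  It is session-scoped so the learning,
metastability and weight-class tests share one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from mpnet import (ExperimentConfig, NetworkConfig, assign_clusters,
                   build_connectivity, make_training_schedule, run_session)
from mpnet.protocols import StimulusSchedule

REDUCED_SEED = 7


@pytest.fixture(scope="session")
def reduced_cfg() -> ExperimentConfig:
    net = NetworkConfig(Q=4, seed=REDUCED_SEED)
    return ExperimentConfig(network=net, seed=REDUCED_SEED)


@pytest.fixture(scope="session")
def trained_reduced(reduced_cfg):
    """(cluster_map, training recording, ongoing recording)."""
    net = reduced_cfg.network
    weights = build_connectivity(net)
    cm = assign_clusters(net.N_E, net.Q, net.f, net.seed)
    schedule = make_training_schedule(cm, 120_000.0, amplitude=net.h_st,
                                      seed=REDUCED_SEED)
    trained, rec_train = run_session(weights, schedule, reduced_cfg,
                                     cluster_map=cm)
    _, rec_ongoing = run_session(
        trained, StimulusSchedule([], 60_000.0), reduced_cfg,
        cluster_map=cm,
        initial_state=rec_train.final_state,
        initial_plasticity=rec_train.final_plasticity)
    return cm, rec_train, rec_ongoing


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
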