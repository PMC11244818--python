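"""Experiment configuration: defaults, YAML round-trip, hashing.

An :class:`ExperimentConfig` aggregates every model and protocol
parameter of a run.  The defaults reproduce the basic network (N = 1000,
Q = 10 overlapping clusters) and its standard training protocol; a
configuration file only needs to list the fields that differ.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .construction import NetworkConfig
from .params import NeuronParams, PlasticityParams

__all__ = ["ExperimentConfig", "load_config", "save_config", "config_hash"]


@dataclass
class ExperimentConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    dt: float = 0.05                  # integration step (ms)
    seed: int = 0                     # master seed; substreams derive from it

    # training protocol
    train_period_ms: float = 2000.0   # one presentation per period
    train_stim_ms: float = 500.0
    train_session_ms: float | None = None  # default: 30 presentations/stimulus
    train_random_intervals: bool = False

    # perturbation protocol
    perturb_mean_interval_ms: float = 10_000.0
    perturb_stim_ms: float = 200.0

    # recorders
    snapshot_interval_ms: float = 60_000.0  # full weight snapshots
    class_interval_ms: float = 1000.0       # w0/w1 class averages

    # rate estimation for overlaps
    rate_window_ms: float = 50.0
    rate_grid_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.train_stim_ms >= self.train_period_ms:
            raise ValueError("stimulus duration must be shorter than the period")
        # master seed propagates into the network config unless set there
        if self.network.seed == 0 and self.seed != 0:
            self.network = dataclasses.replace(self.network, seed=self.seed)

    @property
    def training_session_ms(self) -> float:
        """Training time: 30 presentations per stimulus by default, so it
        scales linearly with the number of stimuli Q."""
        if self.train_session_ms is not None:
            return float(self.train_session_ms)
        return 30.0 * self.network.Q * self.train_period_ms

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key, sub in (("network", NetworkConfig),
                         ("neuron", NeuronParams),
                         ("plasticity", PlasticityParams)):
            if key in d and isinstance(d[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub)}
                sub_unknown = set(d[key]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown keys in section {key!r}: {sorted(sub_unknown)}"
                    )
                d[key] = sub(**d[key])
        return cls(**d)


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a YAML configuration; missing fields take the basic-network
    defaults, unknown keys are a configuration error."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data)}")
    return ExperimentConfig.from_dict(data)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable hash over the semantically meaningful configuration fields."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
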