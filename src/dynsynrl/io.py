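"""Run persistence: episode records, parameter trajectories, manifest.

A run directory contains

* ``episodes.csv`` — one row per episode with the scalar measures;
* ``parameters.csv`` — long table (episode, synapse, pre, post, inhibitory,
  parameter, value) of the eligible-synapse parameter snapshots;
* ``strength.csv`` — long table of per-episode time-averaged dynamic
  strengths <S(t)> per synapse (trained and untrained groups);
* ``config.yaml`` — echo of the full configuration;
* ``manifest.json`` — seed, derived substreams, package version, timestamp.

Rerunning ``run_training`` from the echoed config reproduces the records
bitwise; the readers below round-trip the CSV artifacts losslessly up to
float formatting (full repr precision is written).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import Config, save_config
from .experiment import EpisodeRecord, TrainingResult, records_to_frame

__all__ = ["RunManifest", "write_results", "read_results", "manifest_for"]


@dataclass(frozen=True)
class RunManifest:
    master_seed: int
    substreams: dict
    version: str
    created: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def manifest_for(result: TrainingResult) -> RunManifest:
    ss = np.random.SeedSequence(result.config.seed)
    inputs, topology = ss.spawn(2)
    return RunManifest(
        master_seed=result.config.seed,
        substreams={
            "inputs": [int(x) for x in inputs.generate_state(4)],
            "topology": [int(x) for x in topology.generate_state(4)],
        },
        version=__version__,
        created=datetime.now(timezone.utc).isoformat(),
    )


def _parameters_frame(records: Sequence[EpisodeRecord], network=None) -> pd.DataFrame:
    rows = []
    for rec in records:
        for name, values in rec.params.items():
            for syn, value in enumerate(values):
                rows.append((rec.episode, syn, name, value))
    frame = pd.DataFrame(rows, columns=["episode", "synapse", "parameter", "value"])
    if network is not None and len(frame):
        frame["pre"] = network.ih.pre[frame["synapse"]]
        frame["post"] = network.ih.post[frame["synapse"]]
        frame["inhibitory"] = network.ih.inhibitory[frame["synapse"]]
    return frame


def _strength_frame(records: Sequence[EpisodeRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for group, values in (("trained", rec.mean_S_ih), ("untrained", rec.mean_S_ho)):
            for syn, value in enumerate(values):
                rows.append((rec.episode, group, syn, value))
    return pd.DataFrame(rows, columns=["episode", "group", "synapse", "mean_S"])


def write_results(
    result: TrainingResult, out_dir: str | Path, config: Config | None = None
) -> Path:
    """Persist a training run; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(result.records).to_csv(out / "episodes.csv", index=False)
    _parameters_frame(result.records, result.network).to_csv(
        out / "parameters.csv", index=False
    )
    _strength_frame(result.records).to_csv(out / "strength.csv", index=False)
    if config is None:
        config = Config(
            neuron=result.config.neuron,
            learning=result.learning,
            experiment=result.config,
        )
    save_config(config, out / "config.yaml")
    (out / "manifest.json").write_text(manifest_for(result).to_json())
    return out


def read_results(out_dir: str | Path) -> dict:
    """Load the persisted artifacts of a run directory."""
    out = Path(out_dir)
    return {
        "episodes": pd.read_csv(out / "episodes.csv"),
        "parameters": pd.read_csv(out / "parameters.csv"),
        "strength": pd.read_csv(out / "strength.csv"),
        "manifest": json.loads((out / "manifest.json").read_text()),
    }
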