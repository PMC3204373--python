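"""YAML configuration with full defaults and validation.

A config file holds up to four sections — ``neuron``, ``synapse``,
``learning``, ``experiment`` — each a flat key-value mapping onto the
corresponding dataclass. Missing sections and keys take the built-in
defaults (the standard protocol: 7 hidden neurons, 200-ms episodes at
1 ms, W = 5, 50-Hz inputs, 300 episodes), so an empty file is a valid,
fully specified run. Unknown keys and inconsistent combinations are
rejected with messages naming the offending keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .experiment import ExperimentConfig
from .learning import LearningConfig
from .neurons import LIaFParams

__all__ = ["Config", "load_config", "save_config", "config_to_dict", "config_from_dict"]

# synapse initial values / amplitude live on ExperimentConfig; the `synapse`
# section is sugar mapped onto those fields.
_SYNAPSE_KEYS = {
    "U_SE": "U_SE_init",
    "tau_rec": "tau_rec_init",
    "tau_fac": "tau_fac_init",
    "A": "A",
    "literal_amplitude": "literal_amplitude",
}


@dataclass(frozen=True)
class Config:
    neuron: LIaFParams = field(default_factory=LIaFParams)
    learning: LearningConfig = field(default_factory=LearningConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def __post_init__(self) -> None:
        if self.experiment.neuron != self.neuron:
            object.__setattr__(
                self, "experiment", dataclasses.replace(self.experiment, neuron=self.neuron)
            )


def _build(cls, section: str, data: Mapping[str, Any]):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown keys in [{section}]: {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    try:
        return cls(**data)
    except ConfigurationError as err:
        raise ConfigurationError(f"[{section}] {err}") from None


def config_from_dict(data: Mapping[str, Any] | None) -> Config:
    data = dict(data or {})
    unknown = set(data) - {"neuron", "synapse", "learning", "experiment"}
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

    neuron = _build(LIaFParams, "neuron", data.get("neuron") or {})
    learning = _build(LearningConfig, "learning", data.get("learning") or {})

    exp_data = dict(data.get("experiment") or {})
    syn = dict(data.get("synapse") or {})
    bad = set(syn) - set(_SYNAPSE_KEYS)
    if bad:
        raise ConfigurationError(
            f"unknown keys in [synapse]: {sorted(bad)}; valid keys: {sorted(_SYNAPSE_KEYS)}"
        )
    for key, target in _SYNAPSE_KEYS.items():
        if key in syn:
            exp_data[target] = syn[key]
    exp_data["neuron"] = neuron
    experiment = _build(ExperimentConfig, "experiment", exp_data)
    return Config(neuron=neuron, learning=learning, experiment=experiment)


def config_to_dict(cfg: Config) -> dict:
    exp = dataclasses.asdict(cfg.experiment)
    exp.pop("neuron")
    synapse = {key: exp.pop(target) for key, target in _SYNAPSE_KEYS.items()}
    learning = dataclasses.asdict(cfg.learning)
    learning["trainable_params"] = list(cfg.learning.trainable_params)
    learning["bounds"] = {k: list(v) for k, v in cfg.learning.bounds.items()}
    return {
        "neuron": dataclasses.asdict(cfg.neuron),
        "synapse": synapse,
        "learning": learning,
        "experiment": exp,
    }


def load_config(path: str | Path) -> Config:
    """Read and validate a YAML config; empty file -> full default run."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def save_config(cfg: Config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
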