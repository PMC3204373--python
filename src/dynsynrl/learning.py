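"""Reward, temporal-difference error, and the hidden-parameter update rule.

After every episode the binned network output F is compared with the binned
XOR reference G; the reward is

    Rwd = exp(-alpha * D(F, G))            in (0, 1]

and the temporal-difference error between consecutive trials (trace decay
lambda = 1, i.e. unscaled rewards) is

    delta_Rwd = mu * (Rwd_previous - Rwd_current).

Only the input->hidden synapses are eligible. For each eligible synapse the
hidden Tsodyks-Markram parameters m in {U_SE, tau_rec, tau_fac} are changed
multiplicatively, Delta m = eta * m * (signed error term), and clipped to
bounds; the static weight A is never trained.

How the sign of delta_Rwd maps onto the direction of the parameter change is
the one genuinely open design point, so three readings are implemented
(``LearningConfig.update_rule``):

``fixed``
    Delta m = sign_m * eta * m * delta_Rwd with a fixed per-parameter sign
    table (facilitation parameters rise when the reward improved). Note that
    this rule telescopes: summed over a run, the net change in log m is
    bounded by eta*mu*|Rwd_first - Rwd_last|, so parameters can never move
    far from their initial values.

``adaptive`` (default)
    Direction-memory hill climbing: each synapse keeps a direction state for
    the facilitation axis; when the reward worsened (delta_Rwd > 0) the
    direction is reversed, otherwise it is kept, and the step size is
    eta * m * |delta_Rwd|. Facilitation parameters (U_SE, tau_fac) move with
    the direction, the depression recovery constant tau_rec against it.

``hebbian``
    The fixed rule gated by a per-synapse eligibility sign: presynaptic
    spikes falling in reference-high bins vote +1 (facilitation desired),
    spikes in reference-low bins vote -1, and the sign of the vote total
    multiplies the fixed-rule update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .network import Network, SynapseGroup
from .synapses import TMSynapseParams
from .trains import BinnedTrain, SpikeTrain

__all__ = [
    "TRAINABLE_PARAMS",
    "LearningConfig",
    "RewardState",
    "LearningState",
    "compute_reward",
    "td_error",
    "update_parameters",
    "eligible_synapses",
    "hebbian_eligibility",
    "learning_step",
]

TRAINABLE_PARAMS = ("U_SE", "tau_rec", "tau_fac")

_DEFAULT_SIGNS = {"U_SE": -1.0, "tau_fac": -1.0, "tau_rec": 1.0}
_DEFAULT_BOUNDS = {
    "U_SE": (0.01, 1.0),
    "tau_rec": (1.0, 1000.0),
    "tau_fac": (1.0, 1000.0),
}
_RULES = ("fixed", "adaptive", "hebbian")


@dataclass(frozen=True)
class LearningConfig:
    """Hyperparameters of the episodic update rule.

    ``eta`` — learning rate (|eta| < 1); ``mu`` — TD scaling factor;
    ``alpha`` — reward exponent scale; ``lambda_trace`` — trace decay
    (held at 1: unscaled rewards enter the TD error).

    ``param_signs`` maps each trainable parameter to the direction it takes
    for a positive TD error under the ``fixed``/``hebbian`` readings; under
    ``adaptive`` it sets which parameters ride the facilitation axis
    (negative sign) and which oppose it.
    """

    eta: float = 0.01
    mu: float = 7.0
    alpha: float = 0.01
    lambda_trace: float = 1.0
    trainable_params: Sequence[str] = TRAINABLE_PARAMS
    param_signs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SIGNS)
    )
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )
    update_rule: str = "adaptive"
    flip_inhibitory: bool = False

    def __post_init__(self) -> None:
        # normalize container fields so configs round-trip through YAML
        object.__setattr__(self, "trainable_params", tuple(self.trainable_params))
        object.__setattr__(
            self, "param_signs", {k: float(v) for k, v in dict(self.param_signs).items()}
        )
        object.__setattr__(
            self,
            "bounds",
            {k: (float(v[0]), float(v[1])) for k, v in dict(self.bounds).items()},
        )
        if not abs(self.eta) < 1:
            raise ConfigurationError(f"|eta| must be < 1, got {self.eta}")
        if self.alpha <= 0:
            raise ConfigurationError(f"alpha must be positive, got {self.alpha}")
        if self.mu <= 0:
            raise ConfigurationError(f"mu must be positive, got {self.mu}")
        if self.update_rule not in _RULES:
            raise ConfigurationError(
                f"update_rule must be one of {_RULES}, got {self.update_rule!r}"
            )
        unknown = set(self.trainable_params) - set(TRAINABLE_PARAMS)
        if unknown:
            raise ConfigurationError(f"unknown trainable parameters: {sorted(unknown)}")


@dataclass
class RewardState:
    """Rolling pair of episode rewards feeding the TD error."""

    previous: Optional[float] = None
    current: Optional[float] = None


@dataclass
class LearningState:
    """Mutable state of the learner across episodes."""

    reward: RewardState = field(default_factory=RewardState)
    direction: Optional[np.ndarray] = None  # facilitation axis, adaptive rule


def compute_reward(distance: float, alpha: float) -> float:
    """Map a distance in [0, inf) to a reward in (0, 1]."""
    if distance < 0:
        raise InputError(f"distance must be non-negative, got {distance}")
    return float(np.exp(-alpha * distance))


def td_error(prev: float, curr: float, mu: float) -> float:
    """Scaled temporal difference between consecutive episode rewards."""
    return mu * (prev - curr)


def update_parameters(
    synapse: TMSynapseParams,
    delta: float,
    cfg: LearningConfig,
    eligibility: float = 1.0,
) -> TMSynapseParams:
    """Apply the multiplicative update to one synapse's hidden parameters.

    Delta m = sign_m * eta * m * delta * eligibility, clipped to the
    configured bounds. Multiplicative, so a parameter never changes sign;
    A is untouched.
    """
    if not np.isfinite(delta):
        raise InputError(f"delta must be finite, got {delta}")
    new = {}
    for name in TRAINABLE_PARAMS:
        m = getattr(synapse, name)
        if name in cfg.trainable_params:
            lo, hi = cfg.bounds[name]
            m = float(
                np.clip(m + cfg.param_signs[name] * cfg.eta * m * delta * eligibility, lo, hi)
            )
        new[name] = m
    return TMSynapseParams(A=synapse.A, **new)


def eligible_synapses(network: Network) -> SynapseGroup:
    """The synapses the rule is allowed to train: input->hidden only."""
    return network.ih


def hebbian_eligibility(
    input_trains: tuple[SpikeTrain, SpikeTrain],
    reference: BinnedTrain,
    group: SynapseGroup,
) -> np.ndarray:
    """Signed per-synapse eligibility from the correct-hit correlation.

    Each presynaptic spike votes +1 if it falls in a bin where the reference
    is high (a postsynaptic spike is desired there) and -1 otherwise; the
    eligibility of a synapse is the sign of its presynaptic neuron's vote
    total (0 for a tie or a silent input).
    """
    W = reference.window_ms
    votes = np.zeros(2)
    for i, train in enumerate(input_trains):
        if train.n_spikes:
            bins = train.events // W
            votes[i] = np.sum(2.0 * reference.bits[bins] - 1.0)
    return np.sign(votes)[group.pre]


def _init_direction(group: SynapseGroup, cfg: LearningConfig) -> np.ndarray:
    direction = np.ones(len(group))
    if cfg.flip_inhibitory:
        direction[group.inhibitory] = -1.0
    return direction


def learning_step(
    state: LearningState,
    network: Network,
    cfg: LearningConfig,
    reward: float,
    eligibility: Optional[np.ndarray] = None,
) -> Optional[float]:
    """Roll the reward state and update all eligible synapses in place.

    On the first episode no TD error exists: the reward is only recorded and
    ``None`` is returned. Afterwards the TD error is computed, applied to
    every eligible synapse under the configured rule, and returned.
    """
    group = eligible_synapses(network)
    state.reward.current = reward
    if state.reward.previous is None:
        state.reward.previous = reward
        return None

    delta = td_error(state.reward.previous, reward, cfg.mu)
    state.reward.previous = reward

    if cfg.update_rule == "fixed":
        delta_hat = np.full(len(group), delta)
    elif cfg.update_rule == "hebbian":
        if eligibility is None:
            eligibility = np.ones(len(group))
        delta_hat = delta * np.asarray(eligibility, dtype=float)
    else:  # adaptive: flip the facilitation direction when the reward worsened
        if state.direction is None:
            state.direction = _init_direction(group, cfg)
        if delta > 0:
            state.direction = -state.direction
        # sign table: facilitation parameters carry sign -1, so feed
        # -|delta| * direction through the same signed update as `fixed`.
        delta_hat = -abs(delta) * state.direction

    if cfg.update_rule != "adaptive" and cfg.flip_inhibitory:
        delta_hat = np.where(group.inhibitory, -delta_hat, delta_hat)

    for name in cfg.trainable_params:
        arr = getattr(group, name)
        lo, hi = cfg.bounds[name]
        np.clip(arr * (1.0 + cfg.param_signs[name] * cfg.eta * delta_hat), lo, hi, out=arr)
    return delta
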