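"""The temporally coded XOR learning experiment.

Every episode, two fresh 50-Hz Poisson spike trains drive the input neurons;
the same trains, binned with window W, pass through a per-bin XOR gate whose
output is realized as the reference spike train g (one spike at the centre
of each high bin). The network output f is binned to F, compared with the
binned reference G via the van Rossum distance (filter constant tau_c in bin
units), the reward and TD error are formed, and the eligible input->hidden
synapses are updated. 300 such episodes make one training run; the input
corpus of 600 trains is generated up front from the run seed and consumed
once (no episode ever sees a previously presented train).

Randomness is split into named substreams (input generation vs. inhibitory
assignment) so that topology can be held fixed while inputs vary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .learning import (
    LearningConfig,
    LearningState,
    compute_reward,
    hebbian_eligibility,
    learning_step,
)
from .metrics import DistanceConfig, bin_train, hit_rate, max_crosscorr, van_rossum_distance
from .network import Network, SynapseGroup, simulate_episode
from .neurons import LIaFParams
from .trains import BinnedTrain, SpikeTrain

__all__ = [
    "DEFAULT_A",
    "LITERAL_A",
    "ExperimentConfig",
    "EpisodeRecord",
    "TrainingResult",
    "generate_poisson_train",
    "xor_reference",
    "build_network",
    "run_training",
    "records_to_frame",
    "summarize",
]

#: Magnitude of the static synaptic weight A, calibrated so that under
#: 50-Hz Poisson inputs the untrained hidden and output neurons fire at
#: roughly the input rate (~50 Hz, inside the physiological 10-100 Hz
#: band). The nominal amplitude of the original model parameterization
#: (LITERAL_A = 7e-4) is dimensionally inconsistent with a 50-mV threshold
#: — no spike could ever be emitted — and is kept only behind
#: ``literal_amplitude`` for completeness.
DEFAULT_A = 5500.0
LITERAL_A = 7e-4


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol settings for one training run.

    ``episode_ms`` must be divisible by ``window_ms``; the standard window
    sweep keeps the binned length at 40 (W=4 -> L=160, W=5 -> L=200,
    W=7 -> L=280).
    """

    n_hidden: int = 7
    episode_ms: int = 200
    dt: float = 1.0
    window_ms: int = 5
    input_rate_hz: float = 50.0
    n_episodes: int = 300
    seed: int = 0
    tau_c: float = 15.0
    sigma_bins: float = 1.0
    last_k: int = 50
    A: float = DEFAULT_A
    literal_amplitude: bool = False
    U_SE_init: float = 0.5
    tau_rec_init: float = 100.0
    tau_fac_init: float = 50.0
    neuron: LIaFParams = field(default_factory=LIaFParams)

    def __post_init__(self) -> None:
        if self.episode_ms % self.window_ms != 0:
            raise ConfigurationError(
                f"episode_ms={self.episode_ms} is not divisible by "
                f"window_ms={self.window_ms}"
            )
        if self.n_episodes < 2:
            raise ConfigurationError("n_episodes must be at least 2")
        if self.input_rate_hz * self.dt / 1000.0 >= 1.0:
            raise ConfigurationError(
                "input_rate_hz * dt must correspond to < 1 spike per step"
            )
        if self.tau_c <= 0:
            raise ConfigurationError(f"tau_c must be positive, got {self.tau_c}")

    @property
    def amplitude(self) -> float:
        return LITERAL_A if self.literal_amplitude else self.A

    @property
    def n_bins(self) -> int:
        return self.episode_ms // self.window_ms


@dataclass
class EpisodeRecord:
    """Everything measured in one episode."""

    episode: int
    distance: float
    reward: float
    delta: float  # NaN on the first episode (no TD error yet)
    crosscorr: float
    hit_rate_raw: float
    hit_rate_binned: float
    output_spikes: int
    params: dict[str, np.ndarray]  # eligible-synapse parameter snapshot
    mean_S_ih: np.ndarray
    mean_S_ho: np.ndarray


@dataclass
class TrainingResult:
    records: list[EpisodeRecord]
    network: Network
    config: ExperimentConfig
    learning: LearningConfig


def generate_poisson_train(
    rate_hz: float, length_ms: int, dt: float = 1.0, rng: Optional[np.random.Generator] = None
) -> SpikeTrain:
    """Poisson train on the 1-ms grid: independent Bernoulli(rate*dt) steps."""
    p = rate_hz * dt / 1000.0
    if p >= 1.0:
        raise ConfigurationError(f"rate*dt must be < 1 spike per step, got {p}")
    if rng is None:
        rng = np.random.default_rng()
    n_steps = int(round(length_ms / dt))
    return SpikeTrain.from_binary(rng.random(n_steps) < p)


def xor_reference(
    input_a: SpikeTrain, input_b: SpikeTrain, window_ms: int
) -> tuple[SpikeTrain, BinnedTrain]:
    """Per-bin XOR of the binned inputs, realized as a reference spike train.

    Returns the 1-ms-resolution reference g (one spike at the centre of each
    high bin, so that binning g recovers G exactly) and its binned version G.
    """
    if input_a.length_ms != input_b.length_ms:
        raise InputError("input trains must have equal length")
    bits_a = bin_train(input_a, window_ms).bits
    bits_b = bin_train(input_b, window_ms).bits
    G = BinnedTrain(bits=bits_a ^ bits_b, window_ms=window_ms)
    events = G.events * window_ms + window_ms // 2
    g = SpikeTrain(length_ms=input_a.length_ms, events=events)
    return g, G


def build_network(
    n_hidden: int,
    rng: np.random.Generator,
    *,
    A: float = DEFAULT_A,
    U_SE: float = 0.5,
    tau_rec: float = 100.0,
    tau_fac: float = 50.0,
    neuron: Optional[LIaFParams] = None,
    n_inhibitory_ih: int = 2,
    n_inhibitory_ho: int = 1,
) -> Network:
    """Fully connected feed-forward network with random inhibitory synapses.

    Exactly ``n_inhibitory_ih`` input->hidden and ``n_inhibitory_ho``
    hidden->output synapses get A -> -A; the assignment is drawn once from
    ``rng`` and fixed for the whole simulation.
    """
    if n_hidden < 5:
        warnings.warn(
            f"n_hidden={n_hidden} is below the minimum of five hidden neurons "
            "needed to solve XOR",
            stacklevel=2,
        )

    def group(n_pre: int, n_post: int, n_inhib: int) -> SynapseGroup:
        n_syn = n_pre * n_post
        pre, post = np.divmod(np.arange(n_syn), n_post)
        a = np.full(n_syn, float(abs(A)))
        a[rng.choice(n_syn, size=n_inhib, replace=False)] *= -1.0
        return SynapseGroup(
            pre=pre,
            post=post,
            U_SE=np.full(n_syn, U_SE),
            tau_rec=np.full(n_syn, tau_rec),
            tau_fac=np.full(n_syn, tau_fac),
            A=a,
            n_post=n_post,
        )

    return Network(
        n_hidden=n_hidden,
        ih=group(2, n_hidden, n_inhibitory_ih),
        ho=group(n_hidden, 1, n_inhibitory_ho),
        neuron=neuron or LIaFParams(),
    )


def run_training(
    cfg: ExperimentConfig, learn: Optional[LearningConfig] = None
) -> TrainingResult:
    """Run the full episodic training loop; a pure function of the config."""
    learn = learn if learn is not None else LearningConfig()
    ss = np.random.SeedSequence(cfg.seed)
    ss_inputs, ss_topology = ss.spawn(2)
    rng_inputs = np.random.default_rng(ss_inputs)
    rng_topology = np.random.default_rng(ss_topology)

    # the input corpus: 2 * n_episodes fresh trains, split into two subsets
    corpus = [
        generate_poisson_train(cfg.input_rate_hz, cfg.episode_ms, cfg.dt, rng_inputs)
        for _ in range(2 * cfg.n_episodes)
    ]

    network = build_network(
        cfg.n_hidden,
        rng_topology,
        A=cfg.amplitude,
        U_SE=cfg.U_SE_init,
        tau_rec=cfg.tau_rec_init,
        tau_fac=cfg.tau_fac_init,
        neuron=cfg.neuron,
    )
    dist_cfg = DistanceConfig(tau_c=cfg.tau_c)
    state = LearningState()
    records: list[EpisodeRecord] = []

    for ep in range(cfg.n_episodes):
        train_a = corpus[ep]
        train_b = corpus[cfg.n_episodes + ep]
        g, G = xor_reference(train_a, train_b, cfg.window_ms)

        sim = simulate_episode(network, (train_a, train_b), dt=cfg.dt)
        F = bin_train(sim.output, cfg.window_ms)

        distance = van_rossum_distance(F, G, dist_cfg)
        reward = compute_reward(distance, learn.alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty episodes are legal
            crosscorr = max_crosscorr(F, G, cfg.sigma_bins)

        eligibility = None
        if learn.update_rule == "hebbian":
            eligibility = hebbian_eligibility((train_a, train_b), G, network.ih)
        delta = learning_step(state, network, learn, reward, eligibility)

        records.append(
            EpisodeRecord(
                episode=ep,
                distance=distance,
                reward=reward,
                delta=float("nan") if delta is None else delta,
                crosscorr=crosscorr,
                hit_rate_raw=hit_rate(sim.output, g),
                hit_rate_binned=hit_rate(F, G),
                output_spikes=sim.output.n_spikes,
                params={
                    name: getattr(network.ih, name).copy()
                    for name in ("U_SE", "tau_rec", "tau_fac")
                },
                mean_S_ih=sim.mean_S_ih,
                mean_S_ho=sim.mean_S_ho,
            )
        )
    return TrainingResult(records=records, network=network, config=cfg, learning=learn)


def records_to_frame(records: Sequence[EpisodeRecord]) -> pd.DataFrame:
    """Scalar per-episode measures as a DataFrame (one row per episode)."""
    return pd.DataFrame(
        {
            "episode": [r.episode for r in records],
            "distance": [r.distance for r in records],
            "reward": [r.reward for r in records],
            "delta": [r.delta for r in records],
            "crosscorr": [r.crosscorr for r in records],
            "hit_rate_raw": [r.hit_rate_raw for r in records],
            "hit_rate_binned": [r.hit_rate_binned for r in records],
            "output_spikes": [r.output_spikes for r in records],
        }
    )


def _mean_sd(x: np.ndarray) -> dict[str, float]:
    return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0}


def summarize(
    records: Sequence[EpisodeRecord],
    last_k: int = 50,
    network: Optional[Network] = None,
) -> dict:
    """Converged-performance summary plus the synaptic-strength regime shift.

    Mean +- SD over the final ``last_k`` episodes for distance,
    cross-correlation and hit rates, and the first-half vs second-half
    means of the per-episode time-averaged dynamic strength <S(t)> for the
    trained (input->hidden) and untrained (hidden->output) synapses. When
    the network is supplied, the strength figures are additionally split
    into excitatory and inhibitory groups.
    """
    if len(records) < last_k:
        raise InputError(f"need at least last_k={last_k} records, got {len(records)}")
    tail = records[-last_k:]
    out = {
        "n_episodes": len(records),
        "last_k": last_k,
        "distance": _mean_sd(np.array([r.distance for r in tail])),
        "crosscorr": _mean_sd(np.array([r.crosscorr for r in tail])),
        "hit_rate_raw": _mean_sd(np.array([r.hit_rate_raw for r in tail])),
        "hit_rate_binned": _mean_sd(np.array([r.hit_rate_binned for r in tail])),
        "reward": _mean_sd(np.array([r.reward for r in tail])),
    }

    half = len(records) // 2
    S_ih = np.stack([r.mean_S_ih for r in records])  # (episodes, synapses)
    S_ho = np.stack([r.mean_S_ho for r in records])
    groups: dict[str, np.ndarray] = {"trained": S_ih, "untrained": S_ho}
    if network is not None:
        groups = {
            "trained_exc": S_ih[:, ~network.ih.inhibitory],
            "trained_inh": S_ih[:, network.ih.inhibitory],
            "untrained_exc": S_ho[:, ~network.ho.inhibitory],
            "untrained_inh": S_ho[:, network.ho.inhibitory],
            **groups,
        }
    strength = {}
    for name, S in groups.items():
        if S.shape[1] == 0:
            continue
        first, second = S[:half].mean(axis=1), S[half:].mean(axis=1)
        pooled_sd = float(np.sqrt((first.var(ddof=1) + second.var(ddof=1)) / 2.0))
        strength[name] = {
            "first_half": _mean_sd(first),
            "second_half": _mean_sd(second),
            "shift": float(second.mean() - first.mean()),
            "shift_in_sd": float(
                abs(second.mean() - first.mean()) / pooled_sd if pooled_sd > 0 else 0.0
            ),
        }
    out["strength"] = strength
    return out
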