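"""Feed-forward spiking network and the per-episode simulation loop.

Topology is fixed: two input neurons that relay their assigned spike trains,
one fully connected hidden layer of LIaF neurons, and one LIaF output neuron.
All connections are Tsodyks-Markram dynamic synapses; each synapse carries
its own parameter and state copies so that learning can shape them
individually.

Event ordering within one 1-ms step: all synapse states and membrane
potentials relax exactly over the step; spikes emitted at the previous step
are then delivered (facilitation jump, release, depression), their summed
drive enters the membrane update of the same step, and thresholds are tested
last. Spikes therefore propagate with a one-step (1 ms) latency per synapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InputError
from .neurons import LIaFParams
from .trains import SpikeTrain

__all__ = ["SynapseGroup", "Network", "EpisodeSim", "simulate_episode"]


@dataclass
class SynapseGroup:
    """All synapses projecting from one layer onto the next, as flat arrays.

    ``pre``/``post`` index into the source and target layers. Parameter
    arrays (``U_SE``, ``tau_rec``, ``tau_fac``, ``A``) and state arrays
    (``r``, ``u``) are aligned with them. ``A`` is signed; ``inhibitory``
    is simply ``A < 0``.
    """

    pre: np.ndarray
    post: np.ndarray
    U_SE: np.ndarray
    tau_rec: np.ndarray
    tau_fac: np.ndarray
    A: np.ndarray
    n_post: int
    r: np.ndarray = field(init=False)
    u: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("pre", "post"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.intp))
        for name in ("U_SE", "tau_rec", "tau_fac", "A"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.reset()

    def __len__(self) -> int:
        return int(self.pre.size)

    @property
    def inhibitory(self) -> np.ndarray:
        return self.A < 0

    @property
    def S(self) -> np.ndarray:
        """Dynamic synaptic strength S = r * u, per synapse."""
        return self.r * self.u

    def reset(self) -> None:
        """Return all synapses to rest: full pool, baseline utilization."""
        self.r = np.ones(len(self), dtype=float)
        self.u = self.U_SE.copy()

    def decay(self, dt: float) -> None:
        """Exact inter-spike relaxation of r and u over ``dt`` ms."""
        self.r = 1.0 - (1.0 - self.r) * np.exp(-dt / self.tau_rec)
        self.u = self.U_SE + (self.u - self.U_SE) * np.exp(-dt / self.tau_fac)

    def deliver(self, pre_spiked: np.ndarray) -> np.ndarray:
        """Deliver presynaptic spikes; return summed drive per target neuron.

        ``pre_spiked`` is a boolean vector over the source layer. Synapses
        whose presynaptic neuron fired get the facilitation jump, release,
        and depression applied; the drive ``A * release`` is accumulated on
        their targets.
        """
        epsp = np.zeros(self.n_post, dtype=float)
        fired = pre_spiked[self.pre]
        if not np.any(fired):
            return epsp
        u_plus = self.u[fired] + self.U_SE[fired] * (1.0 - self.u[fired])
        release = u_plus * self.r[fired]
        self.u[fired] = u_plus
        self.r[fired] -= release
        np.add.at(epsp, self.post[fired], self.A[fired] * release)
        return epsp


@dataclass
class Network:
    """Two relay inputs, one hidden LIaF layer, one LIaF output neuron."""

    n_hidden: int
    ih: SynapseGroup  # input -> hidden, 2 * n_hidden synapses
    ho: SynapseGroup  # hidden -> output, n_hidden synapses
    neuron: LIaFParams = field(default_factory=LIaFParams)
    n_input: int = 2
    n_output: int = 1

    @property
    def size(self) -> int:
        """Total neuron count N."""
        return self.n_input + self.n_hidden + self.n_output

    def reset(self) -> None:
        self.ih.reset()
        self.ho.reset()


@dataclass
class EpisodeSim:
    """Result of one simulated episode."""

    output: SpikeTrain
    hidden_spike_counts: np.ndarray
    mean_S_ih: np.ndarray  # per-synapse time average of S over the episode
    mean_S_ho: np.ndarray
    traces: Optional[dict] = None  # S/V time courses when recording is on


def simulate_episode(
    network: Network,
    inputs: tuple[SpikeTrain, SpikeTrain],
    dt: float = 1.0,
    record_traces: bool = False,
) -> EpisodeSim:
    """Run the network for one episode driven by the two input trains.

    Synaptic states and membrane potentials start from rest (episodes are
    independent trials) and evolve freely within the episode.
    """
    train_a, train_b = inputs
    if train_a.length_ms != train_b.length_ms:
        raise InputError(
            f"input trains must have equal length, got "
            f"{train_a.length_ms} and {train_b.length_ms}"
        )
    n_steps = int(round(train_a.length_ms / dt))
    p = network.neuron
    network.reset()

    input_spikes = np.stack(
        [train_a.to_binary().astype(bool), train_b.to_binary().astype(bool)]
    )

    n_h = network.n_hidden
    V_h = np.full(n_h, p.V_rest)
    refr_h = np.zeros(n_h)
    V_o = np.full(1, p.V_rest)
    refr_o = np.zeros(1)

    prev_in = np.zeros(2, dtype=bool)
    prev_hidden = np.zeros(n_h, dtype=bool)

    out_events: list[int] = []
    hidden_counts = np.zeros(n_h, dtype=np.int64)
    sum_S_ih = np.zeros(len(network.ih))
    sum_S_ho = np.zeros(len(network.ho))
    traces: Optional[dict] = None
    if record_traces:
        traces = {
            "S_ih": np.empty((n_steps, len(network.ih))),
            "S_ho": np.empty((n_steps, len(network.ho))),
            "V_hidden": np.empty((n_steps, n_h)),
            "V_output": np.empty(n_steps),
        }

    decay_V = np.exp(-dt / p.tau_V)

    def step_layer(V, refr, epsp):
        refractory = refr > 0
        v_inf = p.V_rest + epsp
        V_new = v_inf + (V - v_inf) * decay_V
        V_new[refractory] = p.V_rest
        refr[refractory] = np.maximum(refr[refractory] - dt, 0.0)
        spiked = ~refractory & (V_new >= p.V_th)
        V_new[spiked] = p.V_rest
        refr[spiked] = p.tau_refr
        return V_new, spiked

    for t in range(n_steps):
        network.ih.decay(dt)
        network.ho.decay(dt)

        epsp_h = network.ih.deliver(prev_in)
        V_h, spiked_h = step_layer(V_h, refr_h, epsp_h)

        epsp_o = network.ho.deliver(prev_hidden)
        V_o, spiked_o = step_layer(V_o, refr_o, epsp_o)

        if spiked_o[0]:
            out_events.append(t)
        hidden_counts += spiked_h

        sum_S_ih += network.ih.S
        sum_S_ho += network.ho.S
        if traces is not None:
            traces["S_ih"][t] = network.ih.S
            traces["S_ho"][t] = network.ho.S
            traces["V_hidden"][t] = V_h
            traces["V_output"][t] = V_o[0]

        prev_in = input_spikes[:, t]
        prev_hidden = spiked_h

    return EpisodeSim(
        output=SpikeTrain(train_a.length_ms, np.asarray(out_events, dtype=np.int64)),
        hidden_spike_counts=hidden_counts,
        mean_S_ih=sum_S_ih / n_steps,
        mean_S_ho=sum_S_ho / n_steps,
        traces=traces,
    )
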