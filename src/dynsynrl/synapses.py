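"""Tsodyks-Markram short-term plasticity: depression and facilitation.

The synapse carries two state variables. ``r`` is the fraction of the
neurotransmitter pool available for release; it recovers toward 1 with time
constant ``tau_rec`` and is depleted by each release (depression). ``u`` is
the utilization fraction (release probability); it relaxes toward its
baseline ``U_SE`` with time constant ``tau_fac`` and is incremented by each
presynaptic spike (facilitation):

    dr/dt = (1 - r)/tau_rec - u * r * delta(t - t_i)
    du/dt = (U_SE - u)/tau_fac + U_SE * (1 - u) * delta(t - t_i)

At a presynaptic spike the utilization jump is applied first and the
release uses the post-facilitation value (the standard convention):

    u+ = u + U_SE * (1 - u);   release = u+ * r;   r+ = r - u+ * r

The postsynaptic drive of the spike is ``A * release`` where ``A`` is the
static synaptic weight (negative for inhibitory synapses). Between spikes
the linear ODEs are solved exactly, so the 1-ms simulation grid carries no
Euler error (exponential integration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "TMSynapseParams",
    "TMSynapseState",
    "initial_state",
    "decay_synapse",
    "spike_synapse",
]


@dataclass(frozen=True)
class TMSynapseParams:
    """Hidden parameters of one dynamic synapse.

    ``U_SE`` in (0, 1]; time constants in ms; ``A`` signed (inhibitory < 0).
    """

    U_SE: float = 0.5
    tau_rec: float = 100.0
    tau_fac: float = 50.0
    A: float = 7e-4

    def __post_init__(self) -> None:
        if not 0.0 < self.U_SE <= 1.0:
            raise ConfigurationError(f"U_SE must be in (0, 1], got {self.U_SE}")
        if self.tau_rec <= 0:
            raise ConfigurationError(f"tau_rec must be positive, got {self.tau_rec}")
        if self.tau_fac <= 0:
            raise ConfigurationError(f"tau_fac must be positive, got {self.tau_fac}")


@dataclass(frozen=True)
class TMSynapseState:
    """Instantaneous synapse state: resources ``r`` and utilization ``u``.

    The dynamic synaptic strength is ``S = r * u``.
    """

    r: float
    u: float

    @property
    def S(self) -> float:
        return self.r * self.u


def initial_state(params: TMSynapseParams) -> TMSynapseState:
    """Resting state: full pool, utilization at its baseline."""
    return TMSynapseState(r=1.0, u=params.U_SE)


def decay_r(r, tau_rec, dt):
    """Exact inter-spike relaxation of the resource pool toward 1."""
    return 1.0 - (1.0 - r) * np.exp(-dt / tau_rec)


def decay_u(u, U_SE, tau_fac, dt):
    """Exact inter-spike relaxation of utilization toward its baseline."""
    return U_SE + (u - U_SE) * np.exp(-dt / tau_fac)


def decay_synapse(
    state: TMSynapseState, params: TMSynapseParams, dt: float
) -> TMSynapseState:
    """Advance the state by ``dt`` ms with no presynaptic spike.

    Solves the linear parts of the state equations exactly, so the result is
    independent of how the interval is subdivided.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    return TMSynapseState(
        r=float(decay_r(state.r, params.tau_rec, dt)),
        u=float(decay_u(state.u, params.U_SE, params.tau_fac, dt)),
    )


def spike_synapse(
    state: TMSynapseState, params: TMSynapseParams
) -> tuple[TMSynapseState, float]:
    """Apply one presynaptic spike; return the new state and the release.

    The utilization is facilitated before release; the returned release
    (``u+ * r``, dimensionless in [0, 1)) multiplied by ``A`` gives the
    postsynaptic potential contribution.
    """
    u_plus = state.u + params.U_SE * (1.0 - state.u)
    release = u_plus * state.r
    return TMSynapseState(r=state.r - release, u=u_plus), float(release)
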