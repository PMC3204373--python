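"""Leaky integrate-and-fire neuron with absolute refractoriness.

    tau_V * dV/dt = V_rest - V + EPSP(t)

The membrane potential is advanced with the exact solution of the linear
equation over each step, treating the summed synaptic drive as constant
within the step. On threshold crossing (V >= V_th) a spike is emitted, the
potential resets to V_rest, and the neuron is clamped at rest for the
absolute refractory period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError

__all__ = ["LIaFParams", "LIaFState", "step_neuron"]


@dataclass(frozen=True)
class LIaFParams:
    tau_V: float = 20.0  # membrane time constant (ms)
    V_rest: float = 0.0  # resting potential (mV)
    V_th: float = 50.0  # firing threshold (mV)
    tau_refr: float = 2.0  # absolute refractory period (ms)

    def __post_init__(self) -> None:
        if self.tau_V <= 0:
            raise ConfigurationError(f"tau_V must be positive, got {self.tau_V}")
        if self.tau_refr < 0:
            raise ConfigurationError(f"tau_refr must be >= 0, got {self.tau_refr}")
        if self.V_th <= self.V_rest:
            raise ConfigurationError(
                f"V_th ({self.V_th}) must exceed V_rest ({self.V_rest})"
            )


@dataclass(frozen=True)
class LIaFState:
    V: float = 0.0
    refr_remaining: float = 0.0


def step_neuron(
    state: LIaFState, params: LIaFParams, epsp_total: float, dt: float
) -> tuple[LIaFState, bool]:
    """Advance the membrane one step under constant drive ``epsp_total``.

    Returns the new state and whether a spike was emitted at this step.
    During refractoriness the potential is clamped at rest and no spike
    can occur.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    if state.refr_remaining > 0:
        return (
            LIaFState(V=params.V_rest, refr_remaining=max(state.refr_remaining - dt, 0.0)),
            False,
        )
    v_inf = params.V_rest + epsp_total
    v = v_inf + (state.V - v_inf) * math.exp(-dt / params.tau_V)
    if v >= params.V_th:
        return LIaFState(V=params.V_rest, refr_remaining=params.tau_refr), True
    return LIaFState(V=v, refr_remaining=0.0), False
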