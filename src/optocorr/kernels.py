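"""Synaptic conductance kernel and voltage-clamp current conversion.

The excitatory postsynaptic conductance evoked by a single presynaptic
spike is an alpha-like waveform

    g(t) = gmax * (t - tspike)/tau * exp(-(t - tspike - tau)/tau)

which rises from 0 at the spike time to its peak ``gmax`` exactly at
``t - tspike = tau`` and decays exponentially thereafter. Under voltage
clamp the recorded current is ohmic,

    i = g * (v - e),

so with the default holding potential v = -70 mV and reversal e = 0 mV an
excitatory event appears as an inward (negative) current. With g in µS and
voltages in mV the product is in nA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SynapticKernelParams", "conductance_kernel", "synaptic_current",
           "sampled_kernel", "ipsc_params"]

#: kernel support truncated here; beyond it the waveform is < 1e-4 of peak
KERNEL_SUPPORT_TAUS = 13.0


@dataclass(frozen=True)
class SynapticKernelParams:
    """Parameters of the unitary synaptic event.

    gmax_us : peak conductance in µS (default 1).
    tau_ms  : time from spike to conductance peak in ms (default 1).
    v_mv    : holding potential in mV (default -70).
    e_mv    : reversal potential of the transmitter-gated event in mV
              (default 0, i.e. a glutamatergic EPSC recorded at -70 mV).
    """

    gmax_us: float = 1.0
    tau_ms: float = 1.0
    v_mv: float = -70.0
    e_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.gmax_us <= 0:
            raise ValueError("gmax must be positive")
        if self.tau_ms <= 0:
            raise ValueError("tau must be positive")

    @property
    def driving_force_mv(self) -> float:
        return self.v_mv - self.e_mv

    @property
    def unitary_peak_na(self) -> float:
        """Peak current of a single event (signed, nA)."""
        return self.gmax_us * self.driving_force_mv


def ipsc_params(gmax_us: float = 1.0, tau_ms: float = 1.0) -> SynapticKernelParams:
    """Preset for inhibitory events recorded in a principal cell.

    Holding above the chloride reversal makes the event an outward
    (positive) current, as for GABA-A responses clamped at -40 mV with a
    low-chloride internal solution.
    """
    return SynapticKernelParams(gmax_us=gmax_us, tau_ms=tau_ms,
                                v_mv=-40.0, e_mv=-70.0)


def conductance_kernel(t_rel_ms, params: SynapticKernelParams) -> np.ndarray:
    """Conductance (µS) at time ``t_rel_ms`` after a presynaptic spike.

    Zero for negative times; peaks at ``gmax_us`` when ``t_rel_ms`` equals
    ``tau_ms``; decays to zero as t grows.
    """
    t = np.asarray(t_rel_ms, dtype=float)
    tau = params.tau_ms
    g = params.gmax_us * (t / tau) * np.exp(-(t - tau) / tau)
    return np.where(t >= 0, g, 0.0)


def synaptic_current(g_us, params: SynapticKernelParams) -> np.ndarray:
    """Ohmic voltage-clamp current i = g (v - e), in nA for g in µS."""
    return np.asarray(g_us, dtype=float) * params.driving_force_mv


def sampled_kernel(params: SynapticKernelParams, dt_ms: float) -> np.ndarray:
    """Unitary current waveform (nA) sampled at ``dt_ms``, truncated at
    ``KERNEL_SUPPORT_TAUS * tau`` where the residual is < 1e-4 of peak."""
    n = int(np.ceil(KERNEL_SUPPORT_TAUS * params.tau_ms / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    return synaptic_current(conductance_kernel(t, params), params)
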