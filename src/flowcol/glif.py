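"""Generalized leaky integrate-and-fire neurons with after-spike currents (GLIF3).

The model augments the classic LIF membrane with two internal after-spike
currents (ASC) on fast/slow timescales, a hard threshold, and a refractory
hold.  All updates are exact exponential-Euler discretizations on a fixed
grid of step ``dt`` (1 ms by default), so that with constant input and no
spikes the simulated membrane matches the continuous closed form at every
grid point to machine precision.

Units: capacitance pF, conductance nS, voltage mV, current pA, time ms.
With these units pA / nS = mV and pF / nS = ms, so no conversion factors
appear anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GLIFParams", "membrane_update", "asc_update", "apply_reset", "synapse_update"]

#: default simulation step (ms)
DT_MS = 1.0

#: synaptic time constants (ms) keyed by (presynaptic E/I, postsynaptic E/I)
TAU_SYN_MS = {
    ("E", "E"): 5.5,
    ("I", "E"): 8.5,
    ("E", "I"): 2.8,
    ("I", "I"): 5.8,
}


@dataclass(frozen=True)
class GLIFParams:
    """Per-type GLIF3 constants.

    Parameters
    ----------
    C:
        Membrane capacitance (pF).
    g:
        Membrane (leak) conductance (nS).
    E_L:
        Resting potential (mV).
    v_th:
        Firing threshold (mV); the neuron spikes when ``v >= v_th``
        (Heaviside convention ``H(0) = 1``).
    v_reset:
        Post-spike reset potential (mV).
    t_ref:
        Refractory period (ms); must lie in [2, 8].
    asc_k:
        Decay rates of the two after-spike currents (1/ms).
    asc_amp:
        Additive after-spike constants A_m (pA), applied at each spike and
        again (after the R_m multiplication) at the end-of-refractory reset.
    asc_r:
        Multiplicative reset constants R_m (dimensionless), typically 1.
    """

    C: float
    g: float
    E_L: float
    v_th: float
    v_reset: float
    t_ref: float = 2.0
    asc_k: tuple[float, float] = (0.03, 0.3)
    asc_amp: tuple[float, float] = (0.0, 0.0)
    asc_r: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g <= 0:
            raise ValueError(f"C and g must be positive (got C={self.C}, g={self.g})")
        if not (2.0 <= self.t_ref <= 8.0):
            raise ValueError(f"refractory period must lie in [2, 8] ms, got {self.t_ref}")
        if any(k <= 0 for k in self.asc_k):
            raise ValueError(f"ASC decay rates must be positive, got {self.asc_k}")

    @property
    def tau(self) -> float:
        """Membrane time constant C/g (ms)."""
        return self.C / self.g

    def alpha(self, dt: float = DT_MS) -> float:
        """Membrane decay factor exp(-dt/tau) for step ``dt``."""
        return float(np.exp(-dt / self.tau))

    @property
    def rheobase_analytic(self) -> float:
        """Infinite-pulse rheobase g*(v_th - E_L) of the ASC-free membrane (pA)."""
        return self.g * (self.v_th - self.E_L)


def membrane_update(v, i_ext, i_int, params: GLIFParams, dt: float = DT_MS):
    """One exponential-Euler membrane step for a non-refractory neuron.

    v(t+dt) = a*v(t) + (1-a) * ((I_ext + I_int)/g + E_L),  a = exp(-dt/tau).

    Returns ``(v_new, spiked)`` where ``spiked = v_new >= v_th`` (H(0)=1).
    Accepts scalars or aligned arrays.
    """
    v = np.asarray(v, dtype=float)
    drive = np.asarray(i_ext, dtype=float) + np.asarray(i_int, dtype=float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(drive))):
        raise FloatingPointError("non-finite membrane state or input current")
    a = params.alpha(dt)
    v_new = a * v + (1.0 - a) * (drive / params.g + params.E_L)
    return v_new, v_new >= params.v_th


def asc_update(i_asc, spiked, params: GLIFParams, dt: float = DT_MS):
    """One step of the after-spike currents: I_m <- exp(-k_m dt) I_m + z A_m."""
    i_asc = np.atleast_1d(np.asarray(i_asc, dtype=float))
    k = np.asarray(params.asc_k, dtype=float)
    amp = np.asarray(params.asc_amp, dtype=float)
    return np.exp(-k * dt) * i_asc + (1.0 if spiked else 0.0) * amp


def apply_reset(v, i_asc, params: GLIFParams):
    """End-of-refractory reset: v <- v_reset, I_m <- R_m I_m + A_m."""
    i_asc = np.atleast_1d(np.asarray(i_asc, dtype=float))
    r = np.asarray(params.asc_r, dtype=float)
    amp = np.asarray(params.asc_amp, dtype=float)
    return params.v_reset, r * i_asc + amp


@dataclass
class SynapseChannel:
    """State pair (I, C) of one alpha-function postsynaptic current source.

    The continuous alpha kernel of a unit spike with weight W is
    ``W * (t/tau) * exp(1 - t/tau)`` (peak W at t = tau); the discrete
    recursion below reproduces it exactly at grid points.
    """

    tau: float
    i_syn: float = 0.0
    c_syn: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"synaptic time constant must be positive, got {self.tau}")


def synapse_update(channel: SynapseChannel, weighted_spikes: float, dt: float = DT_MS) -> SynapseChannel:
    """Advance one alpha-synapse channel by one step.

    I(t+dt) = e^(-dt/tau) I(t) + dt e^(-dt/tau) C(t)
    C(t+dt) = e^(-dt/tau) C(t) + (sum_i W_i z_i) e / tau

    ``weighted_spikes`` is the already-delayed, weighted presynaptic spike
    sum arriving on this step (pA).
    """
    d = np.exp(-dt / channel.tau)
    i_new = d * channel.i_syn + dt * d * channel.c_syn
    c_new = d * channel.c_syn + weighted_spikes * np.e / channel.tau
    return SynapseChannel(tau=channel.tau, i_syn=i_new, c_syn=c_new)
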