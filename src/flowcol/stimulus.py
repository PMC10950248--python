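"""Visual stimulus protocols and the simplified LGN front-end.

Two protocols are supported, mirroring classic visual-flow perturbation
experiments:

* **gratings** -- full-field sinusoidal gratings (0.04 cycles/deg, contrast
  0.8 by default) shown static for 500 ms, drifting for 1000 ms, then
  static again for 1000 ms.  The *halt* variant reverses the epochs
  (drift, static, drift) so the perturbation is a sudden stop of flow.
* **flashes** -- full-field luminance steps: black 500 ms, white 1000 ms,
  black 1000 ms (black/white mapped to -1/+1 in normalized units).

Each LGN unit is an ON or OFF half-rectified sinusoidal filter at a fixed
retinotopic position with a biphasic temporal kernel (difference of two
exponentials, zero DC gain, unit peak).  For gratings the kernel acts as a
temporal-frequency gain ``|k(tf)|`` on the drift modulation, so drifting
gratings drive the population harder than static ones -- the transient
thalamic amplification that the downstream perturbation responses feed on.
Rates are converted to spikes by an inhomogeneous Poisson process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glif import DT_MS

__all__ = [
    "Epoch",
    "StimulusProtocol",
    "LGNUnit",
    "grating_protocol",
    "halt_protocol",
    "flash_protocol",
    "direction_sweep",
    "frequency_sweep",
    "default_lgn_units",
    "lgn_rates",
    "lgn_spikes",
    "biphasic_kernel",
    "temporal_gain",
]


@dataclass(frozen=True)
class Epoch:
    label: str
    duration_ms: float
    drifting: bool = False  # gratings: drift on/off
    luminance: float = 0.0  # flashes: normalized level in [-1, 1]

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise ValueError("epoch durations must be non-negative")


@dataclass(frozen=True)
class StimulusProtocol:
    """A stimulus kind plus its epoch sequence and grating parameters."""

    kind: str  # "grating" | "flash"
    epochs: tuple[Epoch, ...]
    spatial_freq: float = 0.04  # cycles/degree
    contrast: float = 0.8
    direction: float = 0.0  # degrees; 0 = vertical gratings drifting rightward
    temporal_freq: float = 2.0  # Hz

    def __post_init__(self) -> None:
        if self.kind not in ("grating", "flash"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not 0.0 <= self.direction < 360.0:
            raise ValueError("direction must lie in [0, 360)")
        if self.temporal_freq < 0:
            raise ValueError("temporal frequency must be non-negative")

    @property
    def duration_ms(self) -> float:
        return sum(e.duration_ms for e in self.epochs)

    def n_steps(self, dt: float = DT_MS) -> int:
        return int(round(self.duration_ms / dt))

    def epoch_edges_ms(self) -> list[float]:
        edges, t = [0.0], 0.0
        for e in self.epochs:
            t += e.duration_ms
            edges.append(t)
        return edges

    @property
    def onset_ms(self) -> float:
        """Start of the second epoch: the perturbation onset."""
        return self.epochs[0].duration_ms


def grating_protocol(
    direction: float = 0.0,
    tf: float = 2.0,
    sf: float = 0.04,
    contrast: float = 0.8,
    epoch_ms: tuple[float, float, float] = (500.0, 1000.0, 1000.0),
) -> StimulusProtocol:
    """Static -> drifting -> static grating (visual-flow *onset* experiment)."""
    e0, e1, e2 = epoch_ms
    return StimulusProtocol(
        kind="grating",
        epochs=(
            Epoch("static", e0, drifting=False),
            Epoch("drift", e1, drifting=True),
            Epoch("static", e2, drifting=False),
        ),
        spatial_freq=sf,
        contrast=contrast,
        direction=direction,
        temporal_freq=tf,
    )


def halt_protocol(
    direction: float = 0.0,
    tf: float = 2.0,
    sf: float = 0.04,
    contrast: float = 0.8,
    epoch_ms: tuple[float, float, float] = (500.0, 1000.0, 1000.0),
) -> StimulusProtocol:
    """Drifting -> static -> drifting grating (visual-flow *halt* experiment)."""
    e0, e1, e2 = epoch_ms
    return StimulusProtocol(
        kind="grating",
        epochs=(
            Epoch("drift", e0, drifting=True),
            Epoch("static", e1, drifting=False),
            Epoch("drift", e2, drifting=True),
        ),
        spatial_freq=sf,
        contrast=contrast,
        direction=direction,
        temporal_freq=tf,
    )


def flash_protocol(epoch_ms: tuple[float, float, float] = (500.0, 1000.0, 1000.0)) -> StimulusProtocol:
    """Black -> white -> black full-field flash."""
    e0, e1, e2 = epoch_ms
    return StimulusProtocol(
        kind="flash",
        epochs=(
            Epoch("black", e0, luminance=-1.0),
            Epoch("white", e1, luminance=+1.0),
            Epoch("black", e2, luminance=-1.0),
        ),
    )


def direction_sweep(tf: float = 2.0, **kwargs) -> list[StimulusProtocol]:
    """Eight onset protocols at 45-degree spacing (0 to 315 degrees)."""
    return [grating_protocol(direction=d, tf=tf, **kwargs) for d in np.arange(0.0, 360.0, 45.0)]


def frequency_sweep(direction: float = 0.0, tfs=range(1, 10), **kwargs) -> list[StimulusProtocol]:
    """Onset protocols over a 1-9 Hz temporal-frequency sweep."""
    return [grating_protocol(direction=direction, tf=float(f), **kwargs) for f in tfs]


# ---------------------------------------------------------------------------
# LGN units


@dataclass(frozen=True)
class LGNUnit:
    """One ON/OFF half-rectified sinusoidal LGN filter."""

    x: float  # retinotopic position, degrees
    y: float
    polarity: int = 1  # +1 ON, -1 OFF
    phase_deg: float = 0.0
    r0: float = 10.0  # baseline rate, 1/s
    r1: float = 80.0  # gain, 1/s per unit contrast
    tau_fast: float = 15.0  # biphasic kernel time constants, ms
    tau_slow: float = 60.0

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 (ON) or -1 (OFF)")
        if self.r0 < 0 or self.r1 < 0:
            raise ValueError("rates must be non-negative")


def default_lgn_units(
    positions: np.ndarray,
    seed: int,
    r0: float = 10.0,
    r1: float = 80.0,
    tau_fast: float = 15.0,
    tau_slow: float = 60.0,
) -> list[LGNUnit]:
    """Alternating ON/OFF units at the given positions with random spatial phases."""
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 360.0, size=len(positions))
    return [
        LGNUnit(
            x=float(p[0]),
            y=float(p[1]),
            polarity=1 if i % 2 == 0 else -1,
            phase_deg=float(phases[i]),
            r0=r0,
            r1=r1,
            tau_fast=tau_fast,
            tau_slow=tau_slow,
        )
        for i, p in enumerate(positions)
    ]


def biphasic_kernel(tau_fast: float, tau_slow: float, dt: float = DT_MS, n_taus: float = 8.0):
    """Difference-of-exponentials temporal kernel, zero DC gain, unit peak.

    The two lobes are separately normalized to unit discrete sum before
    subtraction, so the kernel sums to exactly zero on the simulation grid:
    sustained (DC) input produces no response and flash transients decay
    back to baseline.
    """
    t = np.arange(0.0, n_taus * tau_slow, dt)
    fast = np.exp(-t / tau_fast)
    slow = np.exp(-t / tau_slow)
    k = fast / fast.sum() - slow / slow.sum()
    return k / np.max(np.abs(k))


def temporal_gain(tf_hz, tau_fast: float, tau_slow: float) -> np.ndarray:
    """Fourier amplitude of the biphasic kernel at ``tf_hz``, peak-normalized.

    |k(f)| for k(t) = e^(-t/tau_fast) - (tau_fast/tau_slow) e^(-t/tau_slow);
    zero at DC, band-pass with a peak near 1/(2 pi sqrt(tau_fast tau_slow)).
    Normalized so the gain at the best frequency is 1.
    """

    def raw(f):
        w = 2.0 * np.pi * np.asarray(f, dtype=float) / 1000.0  # rad/ms
        h = tau_fast / (1.0 + 1j * w * tau_fast) - (tau_fast / tau_slow) * tau_slow / (
            1.0 + 1j * w * tau_slow
        )
        return np.abs(h)

    fgrid = np.linspace(0.0, 50.0, 2001)
    peak = raw(fgrid).max()
    return raw(tf_hz) / peak


# ---------------------------------------------------------------------------
# rates and spikes


def lgn_rates(protocol: StimulusProtocol, units: list[LGNUnit], dt: float = DT_MS) -> np.ndarray:
    """Instantaneous firing rate (1/s) of every unit at every step.

    Gratings: rate = max(0, r0 + pol * r1 * contrast * gain * sin(arg - psi))
    with spatial argument 2 pi sf (x cos th + y sin th) + phase; the drift
    phase psi advances only during drifting epochs and the temporal gain is
    the kernel amplitude at the drift frequency (sustained gain, i.e. zero,
    during static epochs).  Flashes: the luminance trace convolved with the
    biphasic kernel, scaled by r1, rectified around r0.

    Fully deterministic; shape (n_units, n_steps).
    """
    n_steps = protocol.n_steps(dt)
    edges = protocol.epoch_edges_ms()
    for e in edges:
        if abs(e / dt - round(e / dt)) > 1e-9:
            raise ValueError("epoch boundaries must land on grid steps")

    if protocol.kind == "grating":
        # accumulated drift phase per step (cycles), frozen during static epochs
        drifting = np.zeros(n_steps, dtype=bool)
        for ep, (t0, t1) in zip(protocol.epochs, zip(edges, edges[1:])):
            drifting[int(round(t0 / dt)) : int(round(t1 / dt))] = ep.drifting
        dphase = np.where(drifting, protocol.temporal_freq * dt / 1000.0, 0.0)
        psi = 2.0 * np.pi * np.cumsum(dphase)

        th = np.deg2rad(protocol.direction)
        rates = np.empty((len(units), n_steps))
        for i, u in enumerate(units):
            gain = temporal_gain(protocol.temporal_freq, u.tau_fast, u.tau_slow)
            amp = np.where(drifting, gain, 0.0) * u.r1 * protocol.contrast
            arg = (
                2.0 * np.pi * protocol.spatial_freq * (u.x * np.cos(th) + u.y * np.sin(th))
                + np.deg2rad(u.phase_deg)
            )
            rates[i] = np.maximum(0.0, u.r0 + u.polarity * amp * np.sin(arg - psi))
        return rates

    if protocol.kind == "flash":
        lum = np.zeros(n_steps)
        for ep, (t0, t1) in zip(protocol.epochs, zip(edges, edges[1:])):
            lum[int(round(t0 / dt)) : int(round(t1 / dt))] = ep.luminance
        rates = np.empty((len(units), n_steps))
        for i, u in enumerate(units):
            k = biphasic_kernel(u.tau_fast, u.tau_slow, dt)
            k = k / np.max(np.abs(np.cumsum(k)))  # unit peak step response
            resp = np.convolve(lum, k, mode="full")[:n_steps]
            rates[i] = np.maximum(0.0, u.r0 + u.polarity * u.r1 * resp)
        return rates

    raise ValueError(f"unknown stimulus kind {protocol.kind!r}")


def lgn_spikes(rates: np.ndarray, seed: int, dt: float = DT_MS) -> np.ndarray:
    """Inhomogeneous Poisson spike counts per unit and step (mean rate*dt)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(rates * dt / 1000.0).astype(np.int32)
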