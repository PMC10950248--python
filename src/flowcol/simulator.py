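"""Discrete-time simulation of the GLIF3 column with alpha-function synapses.

The engine advances the whole network on a fixed 1 ms grid using exact
exponential-Euler updates (membrane, after-spike currents and synaptic
state pairs are all linear between spikes, so grid-point values match the
continuous solutions to machine precision).  Every postsynaptic current is
bookkept by source -- thalamic (``in``), shared Poisson background
(``noise``), recurrent (``rec``, split internally into excitatory and
inhibitory receptor channels with their own time constants) and the
internal after-spike currents (``asc``) -- so that the analysis stage can
decompose each neuron's response exactly:  I_ext = I_in + I_noise + I_rec.

Trials run back to back: state variables are zeroed only at the very start
(the literal zero-state initialization, including v = 0 mV) and the first
trial is flagged as a discarded warm-up; per-trial stochastic drive (LGN
and background Poisson draws) is derived deterministically from the master
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .glif import DT_MS, TAU_SYN_MS
from .network import Network

__all__ = ["SimResult", "poisson_source", "run_simulation", "single_neuron_response"]

SOURCES = ("in", "noise", "rec", "asc", "ext")


@dataclass
class SimResult:
    """Recorded output of one trial."""

    trial: int
    discarded: bool
    n_steps: int
    spikes: np.ndarray  # (n_spikes, 2) int array of [step, neuron]
    currents: dict[str, np.ndarray] | None = None  # source -> (n_steps, N) pA
    voltage: np.ndarray | None = None  # (n_steps, N) mV
    windows: tuple = ()
    window_currents: np.ndarray | None = None  # (n_windows, N, 5) mean pA, SOURCES order
    window_spike_counts: np.ndarray | None = None  # (n_windows, N)

    def raster(self) -> np.ndarray:
        return self.spikes


def poisson_source(rate_hz: float, T_ms: float, dt: float = DT_MS, seed: int = 0) -> np.ndarray:
    """Spike counts per step of a homogeneous Poisson source (mean rate*dt)."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    n = int(round(T_ms / dt))
    rng = np.random.default_rng(seed)
    return rng.poisson(rate_hz * dt / 1000.0, size=n).astype(np.int32)


# ---------------------------------------------------------------------------
# compiled network


class _Engine:
    """Array-compiled network state and update kernels."""

    def __init__(self, network: Network, dt: float):
        self.dt = dt
        neurons = network.neurons
        self.n = len(neurons)
        types = network.types
        tname = neurons["type"].to_numpy()

        def per_neuron(fn):
            vals = {name: fn(spec) for name, spec in types.items()}
            return np.array([vals[t] for t in tname], dtype=float)

        g = per_neuron(lambda s: s.glif.g)
        tau = per_neuron(lambda s: s.glif.tau)
        self.inv_g = 1.0 / g
        self.alpha = np.exp(-dt / tau)
        self.E_L = per_neuron(lambda s: s.glif.E_L)
        self.v_th = per_neuron(lambda s: s.glif.v_th)
        self.v_reset = per_neuron(lambda s: s.glif.v_reset)
        self.ref_steps = np.maximum(1, np.round(per_neuron(lambda s: s.glif.t_ref) / dt)).astype(int)
        self.asc_decay = np.stack(
            [per_neuron(lambda s, m=m: np.exp(-s.glif.asc_k[m] * dt)) for m in (0, 1)], axis=1
        )
        self.asc_amp = np.stack([per_neuron(lambda s, m=m: s.glif.asc_amp[m]) for m in (0, 1)], axis=1)
        self.asc_r = np.stack([per_neuron(lambda s, m=m: s.glif.asc_r[m]) for m in (0, 1)], axis=1)

        # synaptic channels: 0 = LGN, 1 = background, 2 = recurrent-E, 3 = recurrent-I
        post_ei = neurons["ei"].to_numpy()
        tau_e = np.where(post_ei == "E", TAU_SYN_MS[("E", "E")], TAU_SYN_MS[("E", "I")])
        tau_i = np.where(post_ei == "E", TAU_SYN_MS[("I", "E")], TAU_SYN_MS[("I", "I")])
        tau_ch = np.stack([tau_e, tau_e, tau_e, tau_i], axis=1)
        self.ch_decay = np.exp(-dt / tau_ch)
        self.ch_inj = np.e / tau_ch

        # recurrent adjacency in CSR-by-presynaptic layout
        rec = network.recurrent
        if len(rec):
            order = np.argsort(rec["pre"].to_numpy(), kind="stable")
            pre = rec["pre"].to_numpy()[order]
            self.syn_w = rec["weight"].to_numpy()[order]
            self.syn_delay = rec["delay"].to_numpy()[order].astype(int)
            post = rec["post"].to_numpy()[order]
            chan = np.where(rec["receptor"].to_numpy()[order] == 0, 2, 3)
            self.syn_slot = post * 2 + (chan - 2)  # index into (N, 2) rec block
            self.indptr = np.searchsorted(pre, np.arange(self.n + 1))
        else:
            self.syn_w = np.zeros(0)
            self.syn_delay = np.zeros(0, dtype=int)
            self.syn_slot = np.zeros(0, dtype=int)
            self.indptr = np.zeros(self.n + 1, dtype=int)
        self.max_delay = int(self.syn_delay.max()) if len(self.syn_delay) else 1

        # LGN delivery: one stacked matrix, column blocks keyed by delay
        self.lgn_delays: list[int] = []
        self.lgn_mat: sp.csr_matrix | None = None
        lgn = network.lgn
        n_units = network.n_lgn_units
        if len(lgn):
            blocks = []
            for d in np.unique(lgn["delay"].to_numpy()):
                rows = lgn[lgn["delay"] == d]
                blocks.append(
                    sp.csr_matrix(
                        (
                            rows["weight"].to_numpy(),
                            (rows["post"].to_numpy(), rows["unit"].to_numpy()),
                        ),
                        shape=(self.n, n_units),
                    )
                )
                self.lgn_delays.append(int(d))
                self.max_delay = max(self.max_delay, int(d))
            self.lgn_mat = sp.hstack(blocks, format="csr")
        self.n_units = n_units
        self.bkg_w = np.asarray(network.bkg_weight, dtype=float)

    def zero_state(self, init_at_rest: bool):
        st = {
            "v": np.full(self.n, 0.0) if not init_at_rest else self.E_L.copy(),
            "asc": np.zeros((self.n, 2)),
            "ich": np.zeros((self.n, 4)),
            "cch": np.zeros((self.n, 4)),
            "ref": np.zeros(self.n, dtype=int),
            "z": np.zeros(self.n, dtype=bool),
        }
        return st

    def lgn_arrival(self, counts_ext_t: np.ndarray, u: int) -> np.ndarray | None:
        """Weighted LGN spike sum feeding the update that produces local step u.

        ``counts_ext_t`` is (max_delay + T, n_units): this trial's unit
        spike counts with the previous trial's last ``max_delay`` rows
        prepended, so emissions late in one trial arrive (with their
        synaptic delay) early in the next.
        """
        if self.lgn_mat is None:
            return None
        off = self.max_delay  # row index of this trial's emission step 0
        vec = counts_ext_t[[off + u - d for d in self.lgn_delays]].ravel()
        return self.lgn_mat @ vec


# ---------------------------------------------------------------------------
# main loop


def run_simulation(
    network: Network,
    lgn_rates: np.ndarray | None = None,
    *,
    lgn_counts: np.ndarray | None = None,
    T_ms: float | None = None,
    n_trials: int = 20,
    seed: int = 0,
    dt: float = DT_MS,
    bkg_rate_hz: float = 1000.0,
    record_traces: bool = False,
    record_voltage: bool = False,
    windows: tuple[tuple[int, int], ...] = (),
    init_at_rest: bool = False,
) -> list[SimResult]:
    """Simulate ``n_trials`` analyzed trials plus one discarded warm-up.

    ``lgn_rates`` (n_units, T) generates fresh Poisson LGN spike trains per
    trial; alternatively ``lgn_counts`` fixes one spike train reused on
    every trial, or both may be omitted (T_ms then sets the trial length).
    Trials are contiguous in time; per-trial seeds derive from ``seed``.

    Within a step the order is: delayed spike delivery -> synaptic state
    update -> membrane/ASC update -> threshold test -> refractory
    bookkeeping (spikes fire when v >= v_th; the membrane holds at v_reset
    through the refractory period while synapses and ASC keep evolving).
    """
    if lgn_rates is not None:
        T = lgn_rates.shape[1]
    elif lgn_counts is not None:
        T = lgn_counts.shape[1]
    elif T_ms is not None:
        T = int(round(T_ms / dt))
    else:
        raise ValueError("provide lgn_rates, lgn_counts or T_ms")
    if lgn_rates is not None and np.any(np.asarray(lgn_rates) < 0):
        raise ValueError("LGN rates must be non-negative")

    eng = _Engine(network, dt)
    n = eng.n
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.spawn(n_trials + 1)

    st = eng.zero_state(init_at_rest)
    results: list[SimResult] = []
    lgn_tail: np.ndarray | None = None  # last max_delay count columns of the previous trial
    win = tuple((int(a), int(b)) for a, b in windows)

    for trial in range(n_trials + 1):
        s_lgn, s_noise = trial_seeds[trial].spawn(2)
        if lgn_rates is not None:
            counts = np.random.default_rng(s_lgn).poisson(
                np.asarray(lgn_rates) * dt / 1000.0
            ).astype(np.float64)
        elif lgn_counts is not None:
            counts = np.asarray(lgn_counts, dtype=np.float64)
        else:
            counts = np.zeros((max(eng.n_units, 1), T))
        if lgn_tail is None:
            lgn_tail = np.zeros((eng.max_delay, counts.shape[0]))
        counts_ext = np.concatenate([lgn_tail, np.ascontiguousarray(counts.T)], axis=0)
        lgn_tail = counts_ext[T:].copy()
        noise_counts = np.random.default_rng(s_noise).poisson(
            bkg_rate_hz * dt / 1000.0, size=T
        ).astype(np.float64)

        D = eng.max_delay + 1
        if trial == 0:
            ring = np.zeros((D, n, 2))
            ring_flat = ring.reshape(-1)  # contiguous view for scatter-adds

        tr_cur = (
            {src: np.zeros((T, n)) for src in SOURCES} if record_traces else None
        )
        tr_v = np.zeros((T, n)) if record_voltage else None
        # per-window accumulators of raw channel / ASC states
        w_ich = np.zeros((len(win), n, 4))
        w_asc = np.zeros((len(win), n))
        w_spk = np.zeros((len(win), n), dtype=int)
        spikes_t: list[np.ndarray] = []
        spikes_i: list[np.ndarray] = []

        def record(s_local: int) -> None:
            if tr_cur is not None:
                ich = st["ich"]
                i_rec = ich[:, 2] + ich[:, 3]
                tr_cur["in"][s_local] = ich[:, 0]
                tr_cur["noise"][s_local] = ich[:, 1]
                tr_cur["rec"][s_local] = i_rec
                tr_cur["asc"][s_local] = st["asc"][:, 0] + st["asc"][:, 1]
                tr_cur["ext"][s_local] = ich[:, 0] + ich[:, 1] + i_rec
            if tr_v is not None:
                tr_v[s_local] = st["v"]
            for w, (a, b) in enumerate(win):
                if a <= s_local < b:
                    w_ich[w] += st["ich"]
                    w_asc[w] += st["asc"][:, 0] + st["asc"][:, 1]

        record(0)  # state at trial start (zeros for the warm-up trial)

        ich, cch = st["ich"], st["cch"]
        asc = st["asc"]
        v = st["v"]
        ref = st["ref"]
        bkg_inj = eng.bkg_w * eng.ch_inj[:, 1]
        one_minus_alpha = 1.0 - eng.alpha
        oma_inv_g = one_minus_alpha * eng.inv_g
        oma_el = one_minus_alpha * eng.E_L
        dt_cch = np.empty_like(cch)
        inj_in = eng.ch_inj[:, 0]
        for u in range(1, T + 1):
            # previous-step currents drive this membrane update
            i_drive = ich.sum(axis=1)
            i_drive += asc[:, 0]
            i_drive += asc[:, 1]
            z_prev = st["z"]

            # synaptic states (alpha recursion; I uses the previous C):
            # I <- decay (I + dt C), then C <- decay C + injections
            np.multiply(cch, dt, out=dt_cch)
            ich += dt_cch
            ich *= eng.ch_decay
            cch *= eng.ch_decay
            arr_in = eng.lgn_arrival(counts_ext, u)
            if arr_in is not None:
                arr_in *= inj_in
                cch[:, 0] += arr_in
            if noise_counts[u - 1]:
                cch[:, 1] += noise_counts[u - 1] * bkg_inj
            slot = u % D
            cch[:, 2:4] += ring[slot] * eng.ch_inj[:, 2:4]
            ring[slot] = 0.0

            # after-spike currents (previous step's spikes inject A_m)
            asc *= eng.asc_decay
            if z_prev is not None:
                asc[z_prev] += eng.asc_amp[z_prev]

            # refractory bookkeeping and membrane integration
            held = np.flatnonzero(ref)
            v_held = v[held]
            v *= eng.alpha
            i_drive *= oma_inv_g
            v += i_drive
            v += oma_el
            v[held] = v_held
            spike = v >= eng.v_th
            spike[held] = False
            idx = np.flatnonzero(spike)
            if len(idx):
                v[idx] = eng.v_reset[idx]
                ref[idx] = eng.ref_steps[idx]
                chunks = [
                    np.arange(eng.indptr[i], eng.indptr[i + 1])
                    for i in idx
                    if eng.indptr[i + 1] > eng.indptr[i]
                ]
                if chunks:
                    sidx = np.concatenate(chunks)
                    flat = ((u + eng.syn_delay[sidx]) % D) * (n * 2) + eng.syn_slot[sidx]
                    np.add.at(ring_flat, flat, eng.syn_w[sidx])
            # release: countdown ends -> reset rule (v -> v_reset, asc -> R asc + A)
            if len(held):
                ref[held] -= 1
                rel = held[ref[held] == 0]
                if len(rel):
                    v[rel] = eng.v_reset[rel]
                    asc[rel] = eng.asc_r[rel] * asc[rel] + eng.asc_amp[rel]

            st["z"] = idx if len(idx) else None

            if u < T:
                record(u)
                if len(idx):
                    spikes_t.append(np.full(len(idx), u, dtype=np.int64))
                    spikes_i.append(idx.astype(np.int64))
                    for w, (a, b) in enumerate(win):
                        if a <= u < b:
                            w_spk[w, idx] += 1

        spikes = (
            np.stack([np.concatenate(spikes_t), np.concatenate(spikes_i)], axis=1)
            if spikes_t
            else np.zeros((0, 2), dtype=np.int64)
        )
        wc = None
        if win:
            lengths = np.array([b - a for a, b in win], dtype=float)
            wc = np.empty((len(win), n, 5))
            wc[:, :, 0] = w_ich[:, :, 0]
            wc[:, :, 1] = w_ich[:, :, 1]
            wc[:, :, 2] = w_ich[:, :, 2] + w_ich[:, :, 3]
            wc[:, :, 3] = w_asc
            wc[:, :, 4] = wc[:, :, 0] + wc[:, :, 1] + wc[:, :, 2]
            wc /= lengths[:, None, None]
        results.append(
            SimResult(
                trial=trial,
                discarded=(trial == 0),
                n_steps=T,
                spikes=spikes,
                currents=tr_cur,
                voltage=tr_v,
                windows=win,
                window_currents=wc,
                window_spike_counts=w_spk if win else None,
            )
        )
    return results


# ---------------------------------------------------------------------------
# single-neuron utility (used by the rheobase procedure and unit tests)


def single_neuron_response(
    params,
    i_inj: np.ndarray,
    dt: float = DT_MS,
    v0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one isolated GLIF3 neuron under an injected current trace.

    Returns ``(v_trace, spike_steps)`` with ``v_trace[k]`` the membrane at
    time k*dt (``v_trace[0]`` is the initial condition; resting potential
    unless ``v0`` is given) and the injected sample ``i_inj[k-1]`` driving
    the update from k-1 to k.  Same update semantics as the network engine.
    """
    i_inj = np.asarray(i_inj, dtype=float)
    T = len(i_inj)
    a = params.alpha(dt)
    ref_steps = max(1, int(round(params.t_ref / dt)))
    asc_decay = np.exp(-np.asarray(params.asc_k) * dt)
    amp = np.asarray(params.asc_amp, dtype=float)
    r = np.asarray(params.asc_r, dtype=float)

    v = params.E_L if v0 is None else float(v0)
    asc = np.zeros(2)
    ref = 0
    z = False
    trace = np.empty(T + 1)
    trace[0] = v
    spikes = []
    for k in range(1, T + 1):
        i_tot = i_inj[k - 1] + asc.sum()
        asc = asc_decay * asc + (amp if z else 0.0)
        z = False
        if ref > 0:
            ref -= 1
            if ref == 0:
                v = params.v_reset
                asc = r * asc + amp
        else:
            v = a * v + (1.0 - a) * (i_tot / params.g + params.E_L)
            if v >= params.v_th:
                z = True
                spikes.append(k)
                v = params.v_reset
                ref = ref_steps
        trace[k] = v
    return trace, np.asarray(spikes, dtype=int)
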