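"""End-to-end experiment orchestration: build -> stimulate -> simulate -> analyze.

Reproduces the study design at toy-column scale: a network is built from a
configuration and seed, driven through grating / flash protocols via the
LGN front-end, simulated for 20 analyzed trials after a discarded warm-up,
and every neuron is labeled dVf / hVf / unclassified from its
baseline-subtracted total input current against +/-0.05 of its type's
rheobase.  Sweep helpers cover the 8-direction and 1-9 Hz protocols, the
onset-vs-halt comparison, and the effective-weight and Ripley summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis, spatial, stimulus
from .config import ExperimentConfig
from .network import Network
from .simulator import SimResult, run_simulation

__all__ = [
    "OnsetResult",
    "rheobase_by_type",
    "run_protocol",
    "summarize_response",
    "run_onset_experiment",
    "run_direction_sweep",
    "run_frequency_sweep",
    "run_onset_halt_pair",
    "effective_weight_summary",
    "ripley_by_class",
]

BASELINE_WINDOW = (0, 500)  # steps (1 ms) before perturbation onset
RESPONSE_WINDOW = (500, 1500)  # the 1000 ms perturbation window
PRE_WINDOW = (0, 500)  # effective-weight windows around the onset
POST_WINDOW = (500, 1000)


def rheobase_by_type(cfg: ExperimentConfig) -> dict[str, float]:
    """Rheobase of each neuron type via the incremental-pulse procedure."""
    return {name: analysis.rheobase(spec.glif) for name, spec in cfg.types.items()}


def _lgn_units(cfg: ExperimentConfig, network: Network) -> list[stimulus.LGNUnit]:
    unit_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1, dtype=np.uint64)[0] >> 33)
    return stimulus.default_lgn_units(
        network.lgn_positions,
        seed=unit_seed,
        r0=cfg.lgn_r0,
        r1=cfg.lgn_r1,
        tau_fast=cfg.lgn_tau_fast,
        tau_slow=cfg.lgn_tau_slow,
    )


def run_protocol(
    cfg: ExperimentConfig,
    network: Network,
    protocol: stimulus.StimulusProtocol,
    seed: int,
    windows=(BASELINE_WINDOW, RESPONSE_WINDOW),
    **sim_kwargs,
) -> list[SimResult]:
    """Drive the column through one stimulus protocol (n_trials + warm-up)."""
    units = _lgn_units(cfg, network)
    rates = stimulus.lgn_rates(protocol, units)
    return run_simulation(
        network,
        lgn_rates=rates,
        n_trials=cfg.n_trials,
        seed=seed,
        bkg_rate_hz=cfg.bkg_rate_hz,
        windows=windows,
        init_at_rest=cfg.init_at_rest,
        **sim_kwargs,
    )


def summarize_response(
    results: list[SimResult],
    network: Network,
    theta_by_type: dict[str, float],
    factor: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron response table (I0, DeltaI with decomposition, label)."""
    analyzed = [r for r in results if not r.discarded]
    if not analyzed:
        raise ValueError("no analyzed trials")
    comp_resp = np.stack([r.window_currents[1, :, :4] for r in analyzed])
    comp_base = np.stack([r.window_currents[0, :, :4] for r in analyzed])
    i0 = comp_base.sum(axis=2).mean(axis=0)
    table = analysis.delta_current(comp_resp, i0)
    neurons = network.neurons
    table.insert(0, "id", neurons["id"].to_numpy())
    table["type"] = neurons["type"].to_numpy()
    table["layer"] = neurons["layer"].to_numpy()
    table["cell_class"] = neurons["cell_class"].to_numpy()
    table["theta_rheo"] = neurons["type"].map(theta_by_type).to_numpy()
    table["label"] = analysis.classify(
        table["dI"].to_numpy(), table["theta_rheo"].to_numpy(), factor
    )
    return table


@dataclass
class OnsetResult:
    """One onset experiment: the per-neuron summary plus raw trial output."""

    summary: pd.DataFrame
    results: list[SimResult]
    protocol: stimulus.StimulusProtocol

    def labels(self) -> np.ndarray:
        return self.summary["label"].to_numpy()


def run_onset_experiment(
    cfg: ExperimentConfig,
    network: Network,
    seed: int,
    protocol: stimulus.StimulusProtocol | None = None,
    theta_by_type: dict[str, float] | None = None,
) -> OnsetResult:
    """The reference experiment: 2 Hz visual-flow onset at direction 0."""
    protocol = protocol or stimulus.grating_protocol(tf=cfg.tf, sf=cfg.sf, contrast=cfg.contrast)
    theta = theta_by_type or rheobase_by_type(cfg)
    results = run_protocol(
        cfg,
        network,
        protocol,
        seed,
        windows=(BASELINE_WINDOW, RESPONSE_WINDOW, PRE_WINDOW, POST_WINDOW),
    )
    summary = summarize_response(results, network, theta, cfg.classification_factor)
    return OnsetResult(summary=summary, results=results, protocol=protocol)


def run_direction_sweep(
    cfg: ExperimentConfig,
    network: Network,
    seed: int,
    theta_by_type: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Labels across the 8 drift directions plus the sweep-level category.

    Returns one row per neuron with label_0 ... label_315 and ``category``
    (perturbation-sensitive / direction-selective / other).
    """
    theta = theta_by_type or rheobase_by_type(cfg)
    protos = stimulus.direction_sweep(tf=cfg.tf, sf=cfg.sf, contrast=cfg.contrast)
    seeds = np.random.SeedSequence(seed).spawn(len(protos))
    cols = {}
    for proto, s in zip(protos, seeds):
        res = run_protocol(cfg, network, proto, int(s.generate_state(1, dtype=np.uint64)[0] >> 33))
        summ = summarize_response(res, network, theta, cfg.classification_factor)
        cols[f"label_{int(proto.direction)}"] = summ["label"].to_numpy()
        cols[f"dI_{int(proto.direction)}"] = summ["dI"].to_numpy()
    out = pd.DataFrame(cols)
    label_cols = [c for c in cols if c.startswith("label_")]
    out.insert(0, "id", network.neurons["id"].to_numpy())
    out["category"] = [
        analysis.classify_across_directions(row) for row in out[label_cols].to_numpy()
    ]
    return out


def run_frequency_sweep(
    cfg: ExperimentConfig,
    network: Network,
    seed: int,
    tfs=range(1, 10),
    theta_by_type: dict[str, float] | None = None,
) -> pd.DataFrame:
    """DeltaI across the temporal-frequency sweep and the preferred frequency.

    The preferred frequency is reported for neurons labeled dVf/hVf in the
    reference (2 Hz) experiment column ``label_ref`` included in the output.
    """
    theta = theta_by_type or rheobase_by_type(cfg)
    tfs = list(tfs)
    seeds = np.random.SeedSequence(seed).spawn(len(tfs))
    d_i = np.zeros((network.n_neurons, len(tfs)))
    for j, (tf, s) in enumerate(zip(tfs, seeds)):
        proto = stimulus.grating_protocol(tf=float(tf), sf=cfg.sf, contrast=cfg.contrast)
        res = run_protocol(cfg, network, proto, int(s.generate_state(1, dtype=np.uint64)[0] >> 33))
        summ = summarize_response(res, network, theta, cfg.classification_factor)
        d_i[:, j] = summ["dI"].to_numpy()
    out = pd.DataFrame(d_i, columns=[f"dI_{tf}Hz" for tf in tfs])
    out.insert(0, "id", network.neurons["id"].to_numpy())
    ref_idx = tfs.index(2) if 2 in tfs else 0
    out["label_ref"] = analysis.classify(
        d_i[:, ref_idx],
        network.neurons["type"].map(theta).to_numpy(),
        cfg.classification_factor,
    )
    fpref = np.full(network.n_neurons, np.nan)
    for i, lab in enumerate(out["label_ref"]):
        if lab in ("dVf", "hVf"):
            fpref[i] = analysis.preferred_frequency(d_i[i], lab, tfs=tfs)
    out["f_pref"] = fpref
    return out


def run_onset_halt_pair(
    cfg: ExperimentConfig,
    network: Network,
    seed: int,
    theta_by_type: dict[str, float] | None = None,
) -> tuple[OnsetResult, OnsetResult, pd.DataFrame]:
    """Onset and halt experiments plus the confusion matrix between labelings."""
    theta = theta_by_type or rheobase_by_type(cfg)
    s_on, s_halt = np.random.SeedSequence(seed).spawn(2)
    onset = run_onset_experiment(
        cfg, network, int(s_on.generate_state(1, dtype=np.uint64)[0] >> 33), theta_by_type=theta
    )
    halt_proto = stimulus.halt_protocol(tf=cfg.tf, sf=cfg.sf, contrast=cfg.contrast)
    halt = run_onset_experiment(
        cfg,
        network,
        int(s_halt.generate_state(1, dtype=np.uint64)[0] >> 33),
        protocol=halt_proto,
        theta_by_type=theta,
    )
    conf = analysis.confusion_matrix(onset.labels(), halt.labels())
    return onset, halt, conf


def effective_weight_summary(
    onset: OnsetResult, network: Network
) -> pd.DataFrame:
    """Trial-averaged effective weights per presynaptic type onto each neuron,
    500 ms before vs after the perturbation onset."""
    analyzed = [r for r in onset.results if not r.discarded]
    frames = []
    for epoch, widx, (a, b) in (("pre", 2, PRE_WINDOW), ("post", 3, POST_WINDOW)):
        counts = np.stack([r.window_spike_counts[widx] for r in analyzed]).mean(axis=0)
        tab = analysis.effective_weight_table(
            network.recurrent, network.neurons, counts, b - a
        )
        tab["epoch"] = epoch
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def ripley_by_class(
    summary: pd.DataFrame,
    network: Network,
    radii: np.ndarray | None = None,
    layer: str = "L2/3",
) -> dict[str, spatial.RipleyResult]:
    """Ripley's K of each response class among a layer's excitatory cells."""
    R = network.geometry.radius
    radii = np.linspace(0.0, 0.5 * R, 11) if radii is None else radii
    sel = (summary["layer"] == layer) & (summary["cell_class"] == "Exc")
    out = {}
    for label in ("dVf", "hVf", "unclassified"):
        ids = summary.loc[sel & (summary["label"] == label), "id"].to_numpy()
        if len(ids) == 0:
            continue
        pts = network.neurons.loc[network.neurons["id"].isin(ids), ["x", "y"]].to_numpy()
        out[label] = spatial.ripley_k(pts, radii, R)
    return out
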