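"""Serialization: HDF5 containers for networks and simulation output,
CSV mirrors for summaries, and the JSON run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import ExperimentConfig, config_to_dict
from .network import Geometry, Network
from .simulator import SOURCES, SimResult

__all__ = [
    "save_network",
    "load_network",
    "save_results",
    "load_spikes",
    "write_manifest",
    "network_summary",
]

_NEURON_COLS = ("id", "type", "layer", "cell_class", "ei", "x", "y", "z", "tuning")


def _write_frame(group: h5py.Group, frame: pd.DataFrame) -> None:
    for col in frame.columns:
        data = frame[col].to_numpy()
        if data.dtype == object:
            data = data.astype("S")
        group.create_dataset(col, data=data)


def _read_frame(group: h5py.Group, columns) -> pd.DataFrame:
    out = {}
    for col in columns:
        data = group[col][...]
        if data.dtype.kind == "S":
            data = data.astype(str)
        out[col] = data
    return pd.DataFrame(out)


def save_network(network: Network, cfg: ExperimentConfig, path: str | Path) -> None:
    """Write a wired column to an HDF5 container.

    Layout: /neurons, /synapses/recurrent, /synapses/lgn, /background,
    /lgn_positions plus the geometry attributes needed to rebuild the
    domain.  Type specs (GLIF constants etc.) travel in the config TOML,
    not the network file; loading requires the same config.
    """
    with h5py.File(path, "w") as fh:
        _write_frame(fh.create_group("neurons"), network.neurons)
        syn = fh.create_group("synapses")
        _write_frame(syn.create_group("recurrent"), network.recurrent)
        _write_frame(syn.create_group("lgn"), network.lgn)
        fh.create_dataset("background", data=network.bkg_weight)
        fh.create_dataset("lgn_positions", data=network.lgn_positions)
        geo = fh.create_group("geometry")
        geo.attrs["radius"] = network.geometry.radius
        geo.attrs["lgn_field_deg"] = network.geometry.lgn_field_deg
        for layer, (a, b) in network.geometry.layer_depths.items():
            geo.attrs[f"layer:{layer}"] = (a, b)


def load_network(path: str | Path, cfg: ExperimentConfig) -> Network:
    with h5py.File(path, "r") as fh:
        neurons = _read_frame(fh["neurons"], _NEURON_COLS)
        recurrent = _read_frame(
            fh["synapses/recurrent"], ("pre", "post", "weight", "delay", "receptor")
        )
        lgn = _read_frame(fh["synapses/lgn"], ("unit", "post", "weight", "delay"))
        bkg = fh["background"][...]
        lgn_pos = fh["lgn_positions"][...]
        geo = fh["geometry"]
        layers = {
            k.split(":", 1)[1]: tuple(v) for k, v in geo.attrs.items() if k.startswith("layer:")
        }
        geometry = Geometry(
            radius=float(geo.attrs["radius"]),
            layer_depths=layers,
            lgn_field_deg=float(geo.attrs["lgn_field_deg"]),
        )
    for col in ("pre", "post", "delay", "receptor"):
        recurrent[col] = recurrent[col].astype(int)
    for col in ("unit", "post", "delay"):
        lgn[col] = lgn[col].astype(int)
    neurons["id"] = neurons["id"].astype(int)
    return Network(
        neurons=neurons,
        recurrent=recurrent,
        lgn=lgn,
        bkg_weight=bkg,
        types=cfg.types,
        geometry=geometry,
        lgn_positions=lgn_pos,
    )


def save_results(results: list[SimResult], path: str | Path, metadata: dict | None = None) -> None:
    """Write trial results: /trial<k>/spikes plus current/voltage traces when recorded."""
    with h5py.File(path, "w") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.attrs[k] = v
        for r in results:
            grp = fh.create_group(f"trial{r.trial:02d}")
            grp.attrs["discarded"] = r.discarded
            grp.attrs["n_steps"] = r.n_steps
            grp.create_dataset("spikes", data=r.spikes)
            if r.currents is not None:
                cur = grp.create_group("currents")
                for src in SOURCES:
                    cur.create_dataset(src, data=r.currents[src])
            if r.voltage is not None:
                grp.create_dataset("voltage", data=r.voltage)
            if r.window_currents is not None:
                grp.create_dataset("window_currents", data=r.window_currents)
                grp.create_dataset("window_spike_counts", data=r.window_spike_counts)
                grp.attrs["windows"] = np.asarray(r.windows)


def load_spikes(path: str | Path) -> dict[int, np.ndarray]:
    out = {}
    with h5py.File(path, "r") as fh:
        for name in fh:
            if name.startswith("trial"):
                out[int(name[5:])] = fh[name]["spikes"][...]
    return out


def export_raster_csv(result: SimResult, path: str | Path, dt: float = 1.0) -> None:
    pd.DataFrame(
        {"neuron_id": result.spikes[:, 1], "time_ms": result.spikes[:, 0] * dt}
    ).to_csv(path, index=False)


def export_network_csv(network: Network, outdir: str | Path) -> None:
    """CSV mirrors of the network tables (neurons, synapses, background)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network.neurons.to_csv(outdir / "neurons.csv", index=False)
    network.recurrent.to_csv(outdir / "synapses_recurrent.csv", index=False)
    network.lgn.to_csv(outdir / "synapses_lgn.csv", index=False)
    pd.DataFrame(
        {"id": network.neurons["id"], "bkg_weight": network.bkg_weight}
    ).to_csv(outdir / "background.csv", index=False)


def load_currents(path: str | Path) -> dict[int, dict[str, np.ndarray]]:
    """Per-trial recorded current traces (analysis-only input path)."""
    out: dict[int, dict[str, np.ndarray]] = {}
    with h5py.File(path, "r") as fh:
        for name in fh:
            if name.startswith("trial") and "currents" in fh[name]:
                out[int(name[5:])] = {
                    src: fh[name]["currents"][src][...] for src in fh[name]["currents"]
                }
    return out


def network_summary(network: Network) -> str:
    """Human-readable counts: neurons per type, synapses, degree tables."""
    lines = ["neuron counts per type:"]
    counts = network.neurons.groupby(["layer", "cell_class"]).size()
    for (layer, cls), n in counts.items():
        lines.append(f"  {layer:5s} {cls:6s} {n:6d}")
    lines.append(f"total neurons:            {network.n_neurons}")
    lines.append(f"recurrent synapses:       {len(network.recurrent)}")
    lines.append(f"LGN synapses:             {len(network.lgn)}")
    indeg = network.lgn_indegree()
    lines.append("mean LGN in-degree per type:")
    for tname in network.types:
        ids = network.neurons.loc[network.neurons["type"] == tname, "id"].to_numpy()
        lines.append(f"  {tname:10s} {indeg[ids].mean():7.2f}")
    if len(network.recurrent):
        out_deg = network.recurrent.groupby("pre").size()
        in_deg = network.recurrent.groupby("post").size()
        lines.append(f"mean recurrent out-degree: {out_deg.mean():.1f}")
        lines.append(f"mean recurrent in-degree:  {in_deg.mean():.1f}")
    return "\n".join(lines)


def config_hash(cfg: ExperimentConfig) -> str:
    doc = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, cfg: ExperimentConfig, seed: int, **extra) -> None:
    """Record what produced a run: config hash, seed, package version."""
    from . import __version__

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": int(seed),
        "flowcol_version": __version__,
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
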