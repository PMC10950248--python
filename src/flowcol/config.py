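"""Column configuration: defaults, TOML loading and validation.

A configuration fully describes an experiment: the neuron-type catalog
(counts, GLIF constants, background and thalamic weights), the cylinder
geometry, the pairwise connectivity rules, the LGN front-end and the
stimulus/trial protocol.  The shipped defaults describe a ~5,000-neuron
toy column whose wiring preserves the qualitative structure the
perturbation mechanism rests on -- dense thalamic drive to L4, sparse and
overdispersed drive to L2/3 excitatory cells, strong reciprocal
excitatory-Pvalb coupling, and Pvalb-dominated intralayer inhibition.
The numeric values are illustrative defaults for a scaled-down synthetic
column, not measurements.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .glif import GLIFParams
from .network import (
    ConfigurationError,
    ConnectivityRules,
    Geometry,
    NeuronTypeSpec,
    Network,
    build_network,
)

__all__ = ["ExperimentConfig", "default_config", "load_config", "config_from_dict", "dump_toml"]

# ---------------------------------------------------------------------------
# default column

_GLIF_DEFAULTS = {
    "Exc": dict(C=120.0, g=5.0, E_L=-70.0, v_th=-50.0, v_reset=-70.0, t_ref=4.0,
                asc_k=(0.03, 0.3), asc_amp=(-12.0, -35.0)),
    "Pvalb": dict(C=80.0, g=8.0, E_L=-70.0, v_th=-52.0, v_reset=-70.0, t_ref=2.0,
                  asc_k=(0.1, 0.5), asc_amp=(-3.0, -8.0)),
    "Sst": dict(C=100.0, g=4.0, E_L=-65.0, v_th=-48.0, v_reset=-65.0, t_ref=3.0,
                asc_k=(0.03, 0.3), asc_amp=(-8.0, -15.0)),
    "Htr3a": dict(C=90.0, g=5.0, E_L=-65.0, v_th=-48.0, v_reset=-65.0, t_ref=3.0,
                  asc_k=(0.03, 0.3), asc_amp=(-6.0, -12.0)),
}

# name, layer, class, count, bkg weight, lgn weight, lgn mean in-degree, lgn NB dispersion
_TYPE_DEFAULTS = [
    ("L1_Htr3a", "L1", "Htr3a", 80, 9.0, 2.0, 4.0, 2.0),
    ("L23_Exc", "L2/3", "Exc", 1000, 5.0, 8.0, 5.0, 0.5),
    ("L23_Pvalb", "L2/3", "Pvalb", 130, 15.0, 8.0, 10.0, 2.0),
    ("L23_Sst", "L2/3", "Sst", 90, 7.0, None, 0.0, 2.0),
    ("L23_Htr3a", "L2/3", "Htr3a", 100, 9.0, None, 0.0, 2.0),
    ("L4_Exc", "L4", "Exc", 1200, 5.0, 5.0, 18.0, 4.0),
    ("L4_Pvalb", "L4", "Pvalb", 160, 15.0, 8.0, 20.0, 3.0),
    ("L4_Sst", "L4", "Sst", 100, 7.0, None, 0.0, 2.0),
    ("L4_Htr3a", "L4", "Htr3a", 60, 9.0, None, 0.0, 2.0),
    ("L5_Exc", "L5", "Exc", 800, 5.2, 6.0, 8.0, 2.0),
    ("L5_Pvalb", "L5", "Pvalb", 110, 15.0, 4.0, 6.0, 2.0),
    ("L5_Sst", "L5", "Sst", 80, 7.0, None, 0.0, 2.0),
    ("L5_Htr3a", "L5", "Htr3a", 40, 9.0, None, 0.0, 2.0),
    ("L6_Exc", "L6", "Exc", 900, 5.0, 4.5, 6.0, 2.0),
    ("L6_Pvalb", "L6", "Pvalb", 110, 15.0, 4.0, 4.0, 2.0),
    ("L6_Sst", "L6", "Sst", 70, 7.0, None, 0.0, 2.0),
    ("L6_Htr3a", "L6", "Htr3a", 40, 9.0, None, 0.0, 2.0),
]

# same-layer base connection probabilities at 75 um, by (src class, trg class)
_P_SAME = {
    ("Exc", "Exc"): 0.13, ("Exc", "Pvalb"): 0.40, ("Exc", "Sst"): 0.25, ("Exc", "Htr3a"): 0.10,
    ("Pvalb", "Exc"): 0.45, ("Pvalb", "Pvalb"): 0.35, ("Pvalb", "Sst"): 0.05, ("Pvalb", "Htr3a"): 0.05,
    ("Sst", "Exc"): 0.25, ("Sst", "Pvalb"): 0.25, ("Sst", "Sst"): 0.05, ("Sst", "Htr3a"): 0.10,
    ("Htr3a", "Exc"): 0.10, ("Htr3a", "Pvalb"): 0.10, ("Htr3a", "Sst"): 0.30, ("Htr3a", "Htr3a"): 0.10,
}
# mean synaptic weights (pA), same-layer, signed by the source class
_W_SAME = {
    ("Exc", "Exc"): 0.35, ("Exc", "Pvalb"): 2.0, ("Exc", "Sst"): 0.7, ("Exc", "Htr3a"): 0.6,
    ("Pvalb", "Exc"): -2.0, ("Pvalb", "Pvalb"): -2.0, ("Pvalb", "Sst"): -0.8, ("Pvalb", "Htr3a"): -0.8,
    ("Sst", "Exc"): -1.6, ("Sst", "Pvalb"): -1.2, ("Sst", "Sst"): -0.3, ("Sst", "Htr3a"): -1.0,
    ("Htr3a", "Exc"): -0.8, ("Htr3a", "Pvalb"): -0.6, ("Htr3a", "Sst"): -1.2, ("Htr3a", "Htr3a"): -0.6,
}
_SIGMA_DEFAULT = {
    ("Exc", "Exc"): 130.0, ("Exc", "Pvalb"): 110.0, ("Exc", "Sst"): 110.0, ("Exc", "Htr3a"): 110.0,
    ("Pvalb", "Exc"): 100.0, ("Pvalb", "Pvalb"): 90.0, ("Pvalb", "Sst"): 90.0, ("Pvalb", "Htr3a"): 90.0,
    ("Sst", "Exc"): 100.0, ("Sst", "Pvalb"): 90.0, ("Sst", "Sst"): 90.0, ("Sst", "Htr3a"): 90.0,
    ("Htr3a", "Exc"): 100.0, ("Htr3a", "Pvalb"): 90.0, ("Htr3a", "Sst"): 90.0, ("Htr3a", "Htr3a"): 90.0,
}
# attenuation of same-layer values with layer distance
_CROSS_FACTOR = {1: 0.15, 2: 0.05, 3: 0.03}
# named interlaminar pathways (probability overrides, then weight overrides)
_P_PATHWAYS = {
    ("L4_Exc", "L23_Exc"): 0.25,
    ("L4_Exc", "L23_Pvalb"): 0.15,
    ("L23_Exc", "L5_Exc"): 0.15,
    ("L4_Exc", "L5_Exc"): 0.08,
    ("L5_Exc", "L6_Exc"): 0.08,
    ("L6_Exc", "L4_Exc"): 0.03,
    ("L4_Pvalb", "L23_Exc"): 0.10,
}
_W_PATHWAYS = {
    ("L4_Exc", "L23_Exc"): 0.4,
    ("L4_Exc", "L23_Pvalb"): 2.0,
    ("L4_Pvalb", "L23_Exc"): -2.0,
}
_LAYER_INDEX = {"L1": 0, "L2/3": 1, "L4": 2, "L5": 3, "L6": 4}


def _default_connectivity(type_names: dict[str, tuple[str, str]]) -> tuple[dict, dict]:
    """Build full type-pair p_base and weight matrices from the class rules."""
    p, w = {}, {}
    for src, (sl, sc) in type_names.items():
        for trg, (tl, tc) in type_names.items():
            if sl == "L1" or tl == "L1":
                # apical Htr3a pathway: broad weak inhibition to excitatory cells
                if sl == "L1" and sc == "Htr3a":
                    if tl == "L1":
                        pv, wv = 0.10, _W_SAME[("Htr3a", "Htr3a")]
                    elif tc == "Exc":
                        pv, wv = 0.06, -0.8
                    else:
                        pv, wv = 0.02, -0.4
                elif tl == "L1":
                    pv = 0.05 if sc == "Exc" else 0.02
                    wv = _W_SAME[(sc, "Htr3a")]
                else:  # pragma: no cover - exhausted above
                    pv, wv = 0.0, 0.0
            else:
                dist = abs(_LAYER_INDEX[sl] - _LAYER_INDEX[tl])
                factor = 1.0 if dist == 0 else _CROSS_FACTOR[dist]
                pv = _P_SAME[(sc, tc)] * factor
                wv = _W_SAME[(sc, tc)] * (1.0 if dist == 0 else 0.8)
            pv = _P_PATHWAYS.get((src, trg), pv)
            wv = _W_PATHWAYS.get((src, trg), wv)
            if pv > 0:
                p[(src, trg)] = pv
                w[(src, trg)] = wv
    return p, w


@dataclass
class ExperimentConfig:
    """Everything needed to build, drive and analyze one column."""

    types: dict[str, NeuronTypeSpec]
    geometry: Geometry
    rules: ConnectivityRules
    n_lgn_units: int = 200
    lgn_r0: float = 10.0
    lgn_r1: float = 80.0
    lgn_tau_fast: float = 15.0
    lgn_tau_slow: float = 60.0
    bkg_rate_hz: float = 1000.0
    tf: float = 2.0
    sf: float = 0.04
    contrast: float = 0.8
    n_trials: int = 20
    classification_factor: float = 0.05
    init_at_rest: bool = False
    seed: int = 1234

    def build(self, seed: int | None = None) -> Network:
        return build_network(
            self.types,
            self.geometry,
            self.rules,
            self.n_lgn_units,
            self.seed if seed is None else seed,
        )


def default_config(seed: int = 1234) -> ExperimentConfig:
    """The shipped ~5,000-neuron toy column."""
    types = {}
    for name, layer, cls, count, bw, lw, lmean, lr in _TYPE_DEFAULTS:
        types[name] = NeuronTypeSpec(
            name=name,
            layer=layer,
            cell_class=cls,
            count=count,
            glif=GLIFParams(**_GLIF_DEFAULTS[cls]),
            bkg_weight=bw,
            lgn_weight=lw,
            lgn_mean_indegree=lmean,
            lgn_nb_r=lr,
        )
    p, w = _default_connectivity({n: (s.layer, s.cell_class) for n, s in types.items()})
    rules = ConnectivityRules(p_base=p, sigma=dict(_SIGMA_DEFAULT), weight=w)
    return ExperimentConfig(
        types=types, geometry=Geometry(radius=150.0), rules=rules, seed=seed
    )


# ---------------------------------------------------------------------------
# TOML interface


def _require(table: dict, key: str, path: str):
    if key not in table:
        raise ConfigurationError(f"missing required config key [{path}]")
    return table[key]


def config_from_dict(doc: dict) -> ExperimentConfig:
    """Validate a parsed TOML document and construct the configuration.

    Unknown keys raise with their full key path; a missing [types] or
    [geometry] section raises naming the section.
    """
    known = {"geometry", "types", "connectivity", "lgn", "background", "protocol", "seed"}
    for key in doc:
        if key not in known:
            raise ConfigurationError(f"unknown config section [{key}]")

    geo_tab = _require(doc, "geometry", "geometry")
    layers = {
        lay: tuple(map(float, iv)) for lay, iv in geo_tab.get("layers", {}).items()
    } or None
    geometry = Geometry(
        radius=float(_require(geo_tab, "radius", "geometry.radius")),
        **({"layer_depths": layers} if layers else {}),
        lgn_field_deg=float(geo_tab.get("lgn_field_deg", 60.0)),
    )

    types_tab = _require(doc, "types", "types")
    types = {}
    for name, t in types_tab.items():
        path = f"types.{name}"
        glif_tab = dict(_require(t, "glif", f"{path}.glif"))
        for k in ("asc_k", "asc_amp", "asc_r"):
            if k in glif_tab:
                glif_tab[k] = tuple(glif_tab[k])
        lw = t.get("lgn_weight")
        types[name] = NeuronTypeSpec(
            name=name,
            layer=_require(t, "layer", f"{path}.layer"),
            cell_class=_require(t, "cell_class", f"{path}.cell_class"),
            count=int(_require(t, "count", f"{path}.count")),
            glif=GLIFParams(**glif_tab),
            bkg_weight=float(t.get("bkg_weight", 0.0)),
            lgn_weight=None if lw is None else float(lw),
            lgn_mean_indegree=float(t.get("lgn_mean_indegree", 0.0)),
            lgn_nb_r=float(t.get("lgn_nb_r", 2.0)),
        )

    conn = doc.get("connectivity", {})

    def pairs(tab: dict) -> dict:
        out = {}
        for key, val in tab.items():
            if "->" not in key:
                raise ConfigurationError(f"connectivity key {key!r} must be 'src->trg'")
            src, trg = (s.strip() for s in key.split("->", 1))
            out[(src, trg)] = float(val)
        return out

    base = default_config()
    p = pairs(conn["p_base"]) if "p_base" in conn else dict(base.rules.p_base)
    w = pairs(conn["weight"]) if "weight" in conn else dict(base.rules.weight)
    sig = pairs(conn["sigma"]) if "sigma" in conn else dict(_SIGMA_DEFAULT)
    rules = ConnectivityRules(
        p_base=p,
        sigma=sig,
        weight=w,
        kappa=float(conn.get("kappa", 0.3)),
        delay_range=tuple(conn.get("delay_range", (1, 4))),
        ee_probability_bias=bool(conn.get("ee_probability_bias", False)),
    )

    lgn = doc.get("lgn", {})
    bkg = doc.get("background", {})
    proto = doc.get("protocol", {})
    return ExperimentConfig(
        types=types,
        geometry=geometry,
        rules=rules,
        n_lgn_units=int(lgn.get("n_units", 200)),
        lgn_r0=float(lgn.get("r0", 10.0)),
        lgn_r1=float(lgn.get("r1", 80.0)),
        lgn_tau_fast=float(lgn.get("tau_fast", 15.0)),
        lgn_tau_slow=float(lgn.get("tau_slow", 60.0)),
        bkg_rate_hz=float(bkg.get("rate_hz", 1000.0)),
        tf=float(proto.get("tf", 2.0)),
        sf=float(proto.get("sf", 0.04)),
        contrast=float(proto.get("contrast", 0.8)),
        n_trials=int(proto.get("n_trials", 20)),
        classification_factor=float(proto.get("classification_factor", 0.05)),
        init_at_rest=bool(proto.get("init_at_rest", False)),
        seed=int(doc.get("seed", {}).get("master", 1234)),
    )


def load_config(path: str | Path | None) -> ExperimentConfig:
    """Load a TOML config file, or return the shipped defaults for None."""
    if path is None:
        return default_config()
    with open(path, "rb") as fh:
        return config_from_dict(tomllib.load(fh))


def config_to_dict(cfg: ExperimentConfig) -> dict:
    """Round-trippable plain-dict form of a configuration."""
    doc: dict = {
        "seed": {"master": cfg.seed},
        "geometry": {
            "radius": cfg.geometry.radius,
            "lgn_field_deg": cfg.geometry.lgn_field_deg,
            "layers": {k: list(v) for k, v in cfg.geometry.layer_depths.items()},
        },
        "types": {},
        "connectivity": {
            "kappa": cfg.rules.kappa,
            "delay_range": list(cfg.rules.delay_range),
            "ee_probability_bias": cfg.rules.ee_probability_bias,
            "p_base": {f"{s}->{t}": v for (s, t), v in cfg.rules.p_base.items()},
            "weight": {f"{s}->{t}": v for (s, t), v in cfg.rules.weight.items()},
            "sigma": {f"{s}->{t}": v for (s, t), v in cfg.rules.sigma.items()},
        },
        "lgn": {
            "n_units": cfg.n_lgn_units,
            "r0": cfg.lgn_r0,
            "r1": cfg.lgn_r1,
            "tau_fast": cfg.lgn_tau_fast,
            "tau_slow": cfg.lgn_tau_slow,
        },
        "background": {"rate_hz": cfg.bkg_rate_hz},
        "protocol": {
            "tf": cfg.tf,
            "sf": cfg.sf,
            "contrast": cfg.contrast,
            "n_trials": cfg.n_trials,
            "classification_factor": cfg.classification_factor,
            "init_at_rest": cfg.init_at_rest,
        },
    }
    for name, t in cfg.types.items():
        entry = {
            "layer": t.layer,
            "cell_class": t.cell_class,
            "count": t.count,
            "bkg_weight": t.bkg_weight,
            "lgn_mean_indegree": t.lgn_mean_indegree,
            "lgn_nb_r": t.lgn_nb_r,
            "glif": {
                "C": t.glif.C,
                "g": t.glif.g,
                "E_L": t.glif.E_L,
                "v_th": t.glif.v_th,
                "v_reset": t.glif.v_reset,
                "t_ref": t.glif.t_ref,
                "asc_k": list(t.glif.asc_k),
                "asc_amp": list(t.glif.asc_amp),
                "asc_r": list(t.glif.asc_r),
            },
        }
        if t.lgn_weight is not None:
            entry["lgn_weight"] = t.lgn_weight
        doc["types"][name] = entry
    return doc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_toml(doc: dict, path: str | Path) -> None:
    """Write a nested dict of plain values as a TOML document.

    Covers exactly the schema produced by :func:`config_to_dict` (nested
    tables of scalars and flat arrays); the stdlib parses but does not
    emit TOML.
    """

    def emit(table: dict, prefix: str, out: list[str]) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, dict)}
        subs = {k: v for k, v in table.items() if isinstance(v, dict)}
        if prefix and (scalars or not subs):
            out.append(f"[{prefix}]")
        for k, v in scalars.items():
            key = k if k.replace("_", "").replace("-", "").isalnum() and "->" not in k and "/" not in k else _toml_value(k)
            out.append(f"{key} = {_toml_value(v)}")
        if scalars:
            out.append("")
        for k, v in subs.items():
            safe = k if k.replace("_", "").isalnum() else _toml_value(k)
            emit(v, f"{prefix}.{safe}" if prefix else safe, out)

    lines: list[str] = []
    emit(doc, "", lines)
    Path(path).write_text("\n".join(lines) + "\n")
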