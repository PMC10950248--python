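"""Synthetic laminar-column generator.

Builds a seeded, scaled-down cortical column with the statistical wiring
structure that the visual-flow perturbation mechanism depends on:

* neurons of one excitatory and three inhibitory classes (Pvalb, Sst,
  Htr3a) placed uniformly inside a cylinder, layer by layer (L1 holds
  Htr3a only);
* pairwise connection probabilities that are Gaussian in planar
  intersomatic distance, anchored so the base probability is attained at
  75 um;
* "like-to-like" weight modulation by preferred-direction similarity;
* thalamic (LGN) afferents restricted to excitatory and Pvalb targets in
  L2/3-L6 and Htr3a in L1, with an overdispersed in-degree law (strictly
  positive mass at zero) onto L2/3 excitatory cells;
* a single shared 1 kHz Poisson background source with a per-type weight.

All sampling is reproducible: identical (config, seed) gives bitwise
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NeuronTypeSpec",
    "Geometry",
    "ConnectivityRules",
    "Network",
    "place_neurons",
    "connection_probability",
    "like_to_like_weight",
    "sample_recurrent_synapses",
    "wire_lgn",
    "wire_background",
    "build_network",
]

PROB_ANCHOR_UM = 75.0  # distance at which the base probability applies

LAYERS = ("L1", "L2/3", "L4", "L5", "L6")
CLASSES = ("Exc", "Pvalb", "Sst", "Htr3a")
#: target types permitted to receive LGN synapses, by (layer, class)
LGN_TARGET_CLASSES = {"Exc", "Pvalb"}


class ConfigurationError(ValueError):
    """Invalid column configuration."""


@dataclass(frozen=True)
class NeuronTypeSpec:
    """One neuron type: a (layer, class) population sharing GLIF parameters."""

    name: str
    layer: str
    cell_class: str
    count: int
    glif: "object"  # GLIFParams; kept loose to avoid a circular import in type checking
    bkg_weight: float = 0.0
    lgn_weight: float | None = None
    lgn_mean_indegree: float = 0.0
    lgn_nb_r: float = 2.0  # negative-binomial dispersion of the LGN in-degree law

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ConfigurationError(f"unknown layer {self.layer!r}")
        if self.cell_class not in CLASSES:
            raise ConfigurationError(f"unknown cell class {self.cell_class!r}")
        if self.layer == "L1" and self.cell_class != "Htr3a":
            raise ConfigurationError("L1 contains only Htr3a neurons")
        if self.count <= 0:
            raise ConfigurationError(f"type {self.name!r} has non-positive count")
        if self.bkg_weight < 0:
            raise ConfigurationError("background weights are excitatory (>= 0)")

    @property
    def ei(self) -> str:
        return "E" if self.cell_class == "Exc" else "I"

    @property
    def lgn_allowed(self) -> bool:
        if self.layer == "L1":
            return self.cell_class == "Htr3a"
        return self.cell_class in LGN_TARGET_CLASSES


@dataclass(frozen=True)
class Geometry:
    """Cylindrical column geometry and the visual field seen by the LGN."""

    radius: float  # um
    layer_depths: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "L1": (0.0, 100.0),
            "L2/3": (100.0, 310.0),
            "L4": (310.0, 430.0),
            "L5": (430.0, 640.0),
            "L6": (640.0, 850.0),
        }
    )
    lgn_field_deg: float = 60.0  # side of the square patch of visual space (degrees)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("column radius must be positive")
        intervals = sorted(self.layer_depths.values())
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if a1 > b0 or a0 >= a1 or b0 >= b1:
                raise ConfigurationError("layer depth intervals must be disjoint and ordered")


@dataclass
class ConnectivityRules:
    """Pairwise wiring rules between neuron types.

    ``p_base[(src, trg)]`` is the connection probability at 75 um planar
    distance, ``sigma[(src_class, trg_class)]`` the Gaussian width (um),
    ``weight[(src, trg)]`` the mean synaptic weight (pA, signed by the
    presynaptic class).  ``kappa`` sets the like-to-like modulation depth,
    applied to weights of every connected pair; the optional probability
    bias (E-to-E only) is off by default.
    """

    p_base: dict[tuple[str, str], float]
    sigma: dict[tuple[str, str], float]
    weight: dict[tuple[str, str], float]
    kappa: float = 0.3
    delay_range: tuple[int, int] = (1, 4)  # inclusive, integer steps at 1 ms
    ee_probability_bias: bool = False

    def __post_init__(self) -> None:
        for key, p in self.p_base.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"p_base{key} = {p} outside [0, 1]")
        for key, s in self.sigma.items():
            if s <= 0:
                raise ConfigurationError(f"sigma{key} must be positive")
        if not 0.0 <= self.kappa < 1.0:
            raise ConfigurationError("kappa must lie in [0, 1) to preserve weight signs")
        lo, hi = self.delay_range
        if not (1 <= lo <= hi <= 4):
            raise ConfigurationError("delay range must be within [1, 4] steps")


@dataclass
class Network:
    """A fully wired column.

    ``neurons``: one row per neuron (id, type, layer, class, E/I flag,
    position, tuning angle).  ``recurrent``: one row per recurrent synapse
    (pre, post, weight pA, delay steps, receptor 0 = excitatory source /
    1 = inhibitory source).  ``lgn``: one row per thalamic synapse.
    ``bkg_weight``: per-neuron weight of the shared Poisson source.
    """

    neurons: pd.DataFrame
    recurrent: pd.DataFrame
    lgn: pd.DataFrame
    bkg_weight: np.ndarray
    types: dict[str, NeuronTypeSpec]
    geometry: Geometry
    lgn_positions: np.ndarray  # (n_units, 2) degrees of visual angle

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_lgn_units(self) -> int:
        return len(self.lgn_positions)

    def lgn_indegree(self) -> np.ndarray:
        """Number of LGN synapses onto each neuron."""
        counts = np.zeros(self.n_neurons, dtype=int)
        if len(self.lgn):
            np.add.at(counts, self.lgn["post"].to_numpy(), 1)
        return counts


# ---------------------------------------------------------------------------
# placement


def place_neurons(catalog: list[NeuronTypeSpec], geometry: Geometry, seed: int) -> pd.DataFrame:
    """Place every neuron uniformly in its layer's slab of the cylinder.

    (x, y) is uniform in the disk (area-correct radial sampling), z uniform
    in the layer's depth interval, and each neuron gets an independent
    uniform preferred direction in [0, 360).
    """
    if not catalog:
        raise ConfigurationError("empty neuron catalog")
    rng = np.random.default_rng(seed)
    rows = []
    for spec in catalog:
        z0, z1 = geometry.layer_depths[spec.layer]
        n = spec.count
        r = geometry.radius * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        rows.append(
            pd.DataFrame(
                {
                    "type": spec.name,
                    "layer": spec.layer,
                    "cell_class": spec.cell_class,
                    "ei": spec.ei,
                    "x": r * np.cos(phi),
                    "y": r * np.sin(phi),
                    "z": rng.uniform(z0, z1, size=n),
                    "tuning": rng.uniform(0.0, 360.0, size=n),
                }
            )
        )
    neurons = pd.concat(rows, ignore_index=True)
    neurons.insert(0, "id", np.arange(len(neurons)))
    return neurons


# ---------------------------------------------------------------------------
# pairwise rules


def connection_probability(p_base, d, sigma):
    """Distance-scaled connection probability  p_base * G(d),  G(75 um) = 1.

    G is a Gaussian in planar distance, normalized to 1 at the 75 um anchor
    (so ``p_base`` is the probability at that distance) and the product is
    clamped to [0, 1] for shorter distances.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ConfigurationError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    scale = np.exp(-(d**2 - PROB_ANCHOR_UM**2) / (2.0 * np.asarray(sigma, dtype=float) ** 2))
    return np.clip(p_base * scale, 0.0, 1.0)


def like_to_like_weight(w_mean, dtheta_deg, kappa):
    """Direction-similarity weight modulation  w(dtheta) = w_mean (1 + kappa cos dtheta).

    ``dtheta_deg`` is the circular difference of preferred directions in
    [0, 180].  The modulation is maximal for aligned pairs, minimal for
    opposed ones, averages to ``w_mean`` over a uniform dtheta, and with
    ``kappa`` in [0, 1) never flips the sign of ``w_mean``.
    """
    if not 0.0 <= kappa < 1.0:
        raise ConfigurationError("kappa must lie in [0, 1)")
    return np.asarray(w_mean) * (1.0 + kappa * np.cos(np.deg2rad(dtheta_deg)))


def circular_difference_deg(a, b):
    """Circular difference of two angles in degrees, folded into [0, 180]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


# ---------------------------------------------------------------------------
# synapse sampling

_EMPTY_REC = pd.DataFrame(
    {
        "pre": pd.Series(dtype=int),
        "post": pd.Series(dtype=int),
        "weight": pd.Series(dtype=float),
        "delay": pd.Series(dtype=int),
        "receptor": pd.Series(dtype=int),
    }
)


def sample_recurrent_synapses(
    neurons: pd.DataFrame,
    types: dict[str, NeuronTypeSpec],
    rules: ConnectivityRules,
    seed: int,
) -> pd.DataFrame:
    """Draw every ordered pair independently under the distance-scaled rule.

    Weights carry the like-to-like modulation for all pairs; the optional
    probability bias applies to E-to-E pairs only when enabled.  Delays are
    uniform over the configured integer-step range; the receptor class
    records the presynaptic E/I identity (which fixes the synaptic time
    constant at the target).
    """
    rng = np.random.default_rng(seed)
    xy = neurons[["x", "y"]].to_numpy()
    tuning = neurons["tuning"].to_numpy()
    ids = neurons["id"].to_numpy()
    by_type = {t: np.flatnonzero(neurons["type"].to_numpy() == t) for t in types}

    lo, hi = rules.delay_range
    chunks = []
    for src_name, src in types.items():
        si = by_type[src_name]
        if len(si) == 0:
            continue
        for trg_name, trg in types.items():
            p0 = rules.p_base.get((src_name, trg_name), 0.0)
            if p0 <= 0.0:
                continue
            ti = by_type[trg_name]
            sig = rules.sigma[(src.cell_class, trg.cell_class)]
            w0 = rules.weight.get((src_name, trg_name), 0.0)
            if (src.ei == "E" and w0 < 0) or (src.ei == "I" and w0 > 0):
                raise ConfigurationError(
                    f"weight sign of {src_name}->{trg_name} ({w0}) contradicts the "
                    f"{'excitatory' if src.ei == 'E' else 'inhibitory'} source class"
                )
            dx = xy[si, 0][:, None] - xy[ti, 0][None, :]
            dy = xy[si, 1][:, None] - xy[ti, 1][None, :]
            d = np.sqrt(dx * dx + dy * dy)
            p = connection_probability(p0, d, sig)
            dth = circular_difference_deg(tuning[si][:, None], tuning[ti][None, :])
            if rules.ee_probability_bias and src.ei == "E" and trg.ei == "E":
                p = np.clip(p * (1.0 + rules.kappa * np.cos(np.deg2rad(dth))), 0.0, 1.0)
            conn = rng.random(p.shape) < p
            if src_name == trg_name:  # no self-synapses
                np.fill_diagonal(conn, False)
            ii, jj = np.nonzero(conn)
            if len(ii) == 0:
                continue
            w = like_to_like_weight(w0, dth[ii, jj], rules.kappa)
            chunks.append(
                pd.DataFrame(
                    {
                        "pre": ids[si[ii]],
                        "post": ids[ti[jj]],
                        "weight": w,
                        "delay": rng.integers(lo, hi + 1, size=len(ii)),
                        "receptor": 0 if src.ei == "E" else 1,
                    }
                )
            )
    if not chunks:
        return _EMPTY_REC.copy()
    table = pd.concat(chunks, ignore_index=True)
    return table.sort_values(["pre", "post"], kind="stable", ignore_index=True)


def wire_lgn(
    neurons: pd.DataFrame,
    types: dict[str, NeuronTypeSpec],
    n_lgn_units: int,
    seed: int,
    delay_range: tuple[int, int] = (1, 4),
) -> pd.DataFrame:
    """Draw per-neuron LGN in-degrees and attach uniformly chosen units.

    The in-degree of each permitted target follows a negative-binomial law
    with the type's mean and dispersion ``r`` (variance mean + mean^2/r),
    which is overdispersed and places strictly positive mass at zero -- the
    property that lets some L2/3 excitatory cells escape direct thalamic
    drive.  Forbidden types (Sst everywhere, Htr3a outside L1, all L1
    non-Htr3a) receive nothing.
    """
    rng = np.random.default_rng(seed)
    lo, hi = delay_range
    pres, posts, weights, delays = [], [], [], []
    for name, spec in types.items():
        idx = neurons.loc[neurons["type"] == name, "id"].to_numpy()
        mean = spec.lgn_mean_indegree
        if mean <= 0:
            continue
        if not spec.lgn_allowed:
            raise ConfigurationError(
                f"type {name!r} ({spec.layer} {spec.cell_class}) may not receive LGN synapses"
            )
        if spec.lgn_weight is None:
            raise ConfigurationError(f"type {name!r} has LGN in-degree but no LGN weight")
        r = spec.lgn_nb_r
        # negative binomial via gamma-Poisson mixture
        lam = rng.gamma(shape=r, scale=mean / r, size=len(idx))
        k = rng.poisson(lam)
        total = int(k.sum())
        if total == 0:
            continue
        posts.append(np.repeat(idx, k))
        pres.append(rng.integers(0, n_lgn_units, size=total))
        weights.append(np.full(total, float(spec.lgn_weight)))
        delays.append(rng.integers(lo, hi + 1, size=total))
    if not posts:
        return pd.DataFrame(
            {
                "unit": pd.Series(dtype=int),
                "post": pd.Series(dtype=int),
                "weight": pd.Series(dtype=float),
                "delay": pd.Series(dtype=int),
            }
        )
    return pd.DataFrame(
        {
            "unit": np.concatenate(pres),
            "post": np.concatenate(posts),
            "weight": np.concatenate(weights),
            "delay": np.concatenate(delays),
        }
    )


def wire_background(neurons: pd.DataFrame, types: dict[str, NeuronTypeSpec]) -> np.ndarray:
    """One excitatory weight per neuron for the shared 1 kHz Poisson source."""
    wmap = {name: spec.bkg_weight for name, spec in types.items()}
    w = neurons["type"].map(wmap).to_numpy(dtype=float)
    if np.any(w < 0):
        raise ConfigurationError("background weights must be non-negative")
    return w


def build_network(
    types: dict[str, NeuronTypeSpec],
    geometry: Geometry,
    rules: ConnectivityRules,
    n_lgn_units: int,
    seed: int,
) -> Network:
    """Place, wire and assemble a full column from one master seed."""
    ss = np.random.SeedSequence(seed)
    s_place, s_rec, s_lgn, s_units = (int(c.generate_state(1, dtype=np.uint64)[0] >> 33) for c in ss.spawn(4))
    neurons = place_neurons(list(types.values()), geometry, s_place)
    recurrent = sample_recurrent_synapses(neurons, types, rules, s_rec)
    lgn = wire_lgn(neurons, types, n_lgn_units, s_lgn)
    bkg = wire_background(neurons, types)
    half = geometry.lgn_field_deg / 2.0
    lgn_pos = np.random.default_rng(s_units).uniform(-half, half, size=(n_lgn_units, 2))
    return Network(
        neurons=neurons,
        recurrent=recurrent,
        lgn=lgn,
        bkg_weight=bkg,
        types=types,
        geometry=geometry,
        lgn_positions=lgn_pos,
    )
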