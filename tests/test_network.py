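"""Tests of the synthetic column generator: placement, wiring rules, laws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flowcol.glif import GLIFParams
from flowcol.network import (
    ConfigurationError,
    ConnectivityRules,
    Geometry,
    NeuronTypeSpec,
    build_network,
    connection_probability,
    like_to_like_weight,
    place_neurons,
    sample_recurrent_synapses,
    wire_background,
    wire_lgn,
)

GLIF = GLIFParams(C=100.0, g=10.0, E_L=-70.0, v_th=-60.0, v_reset=-70.0, t_ref=2.0)


def _spec(name="L23_Exc", layer="L2/3", cls="Exc", count=10, **kw):
    return NeuronTypeSpec(name=name, layer=layer, cell_class=cls, count=count, glif=GLIF, **kw)


class TestPlacement:
    def test_single_neuron_inside_disk(self):
        geo = Geometry(radius=50.0)
        tab = place_neurons([_spec(count=1)], geo, seed=0)
        assert len(tab) == 1
        assert tab.x[0] ** 2 + tab.y[0] ** 2 <= 50.0**2

    def test_determinism(self):
        geo = Geometry(radius=100.0)
        a = place_neurons([_spec(count=500)], geo, seed=42)
        b = place_neurons([_spec(count=500)], geo, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_disk_moments(self):
        """10,000 placements: centered mean and quarter mass inside half radius."""
        R, n = 100.0, 10_000
        tab = place_neurons([_spec(count=n)], Geometry(radius=R), seed=1)
        se = R / 2.0 / np.sqrt(n)  # sd of x for uniform disk is R/2
        assert abs(tab.x.mean()) < 3 * se
        assert abs(tab.y.mean()) < 3 * se
        frac = np.mean(tab.x**2 + tab.y**2 <= (R / 2) ** 2)
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_layer_containment_and_tuning_range(self):
        geo = Geometry(radius=80.0)
        specs = [_spec(count=200), _spec(name="L4_Exc", layer="L4", count=200)]
        tab = place_neurons(specs, geo, seed=5)
        for layer, (z0, z1) in geo.layer_depths.items():
            sel = tab.layer == layer
            if sel.any():
                assert tab.z[sel].between(z0, z1).all()
        assert ((tab.tuning >= 0) & (tab.tuning < 360)).all()

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            place_neurons([], Geometry(radius=10.0), seed=0)
        with pytest.raises(ConfigurationError):
            Geometry(radius=0.0)
        with pytest.raises(ConfigurationError):
            _spec(layer="L1", cls="Exc")  # L1 is Htr3a-only


class TestConnectionProbability:
    def test_anchor_distance_returns_base(self):
        assert connection_probability(0.3, 75.0, 100.0) == pytest.approx(0.3, rel=1e-12)

    def test_gaussian_tail_vanishes(self):
        assert connection_probability(1.0, 6 * 80.0, 80.0) < 1e-6

    @settings(derandomize=True, max_examples=50)
    @given(
        d1=st.floats(0.0, 400.0),
        d2=st.floats(0.0, 400.0),
        sigma=st.floats(20.0, 200.0),
    )
    def test_ratio_identity(self, d1, d2, sigma):
        """p(d1)/p(d2) = exp(-(d1^2 - d2^2)/(2 sigma^2)) away from the clamp."""
        p0 = 1e-5  # small enough that the [0, 1] clamp never engages
        p1 = connection_probability(p0, d1, sigma)
        p2 = connection_probability(p0, d2, sigma)
        expected = np.exp(-(d1**2 - d2**2) / (2 * sigma**2))
        assert p1 / p2 == pytest.approx(expected, rel=1e-9)

    def test_invalid_sigma(self):
        with pytest.raises(ConfigurationError):
            connection_probability(0.5, 10.0, 0.0)


class TestLikeToLike:
    def test_modulation_off(self):
        for dth in (0.0, 90.0, 180.0):
            assert like_to_like_weight(2.0, dth, 0.0) == 2.0

    def test_cosine_extremes(self):
        assert like_to_like_weight(2.0, 0.0, 0.5) == pytest.approx(3.0)
        assert like_to_like_weight(2.0, 180.0, 0.5) == pytest.approx(1.0)

    def test_mean_over_uniform_angle_is_base_weight(self):
        dth = np.linspace(0.0, 180.0, 20001)
        w = like_to_like_weight(1.7, dth, 0.4)
        assert np.trapezoid(w, dth) / 180.0 == pytest.approx(1.7, rel=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(
        w=st.floats(-5.0, 5.0).filter(lambda x: abs(x) > 1e-6),
        kappa=st.floats(0.0, 0.99),
    )
    def test_monotone_and_sign_preserving(self, w, kappa):
        dth = np.linspace(0.0, 180.0, 181)
        vals = like_to_like_weight(w, dth, kappa)
        steps = np.diff(vals) * np.sign(w)
        assert np.all(steps <= 1e-12)  # non-increasing in |w| direction
        assert np.all(np.sign(vals) == np.sign(w))

    def test_kappa_bounds(self):
        with pytest.raises(ConfigurationError):
            like_to_like_weight(1.0, 0.0, 1.0)


class TestRecurrentSampling:
    def _two_pop(self, n=100, d=75.0):
        """Source cluster at the origin, target cluster at distance d."""
        rng = np.random.default_rng(0)
        half = pd.DataFrame(
            {
                "type": "A", "layer": "L2/3", "cell_class": "Exc", "ei": "E",
                "x": 0.0, "y": 0.0, "z": 200.0,
                "tuning": rng.uniform(0, 360, n),
            },
            index=range(n),
        )
        other = half.copy()
        other["type"] = "B"
        other["x"] = d
        tab = pd.concat([half, other], ignore_index=True)
        tab.insert(0, "id", np.arange(len(tab)))
        types = {
            "A": _spec(name="A", count=n),
            "B": _spec(name="B", count=n),
        }
        return tab, types

    def test_zero_probability_gives_empty_table(self):
        tab, types = self._two_pop()
        rules = ConnectivityRules(p_base={}, sigma={("Exc", "Exc"): 100.0}, weight={})
        out = sample_recurrent_synapses(tab, types, rules, seed=0)
        assert len(out) == 0

    def test_complete_digraph_without_self_loops(self):
        tab, types = self._two_pop(n=20)
        pairs = {(a, b): 1.0 for a in types for b in types}
        rules = ConnectivityRules(
            p_base=pairs, sigma={("Exc", "Exc"): 1e9}, weight={k: 1.0 for k in pairs}
        )
        out = sample_recurrent_synapses(tab, types, rules, seed=0)
        n = len(tab)
        assert len(out) == n * (n - 1)
        assert (out.pre != out.post).all()

    def test_empirical_frequency_matches_distance_law(self):
        """Connection frequency over 10^4 fixed-distance pairs vs p_base G(d)."""
        d, sigma, p0 = 120.0, 100.0, 0.25
        tab, types = self._two_pop(n=100, d=d)
        rules = ConnectivityRules(
            p_base={("A", "B"): p0},
            sigma={("Exc", "Exc"): sigma},
            weight={("A", "B"): 1.0},
        )
        out = sample_recurrent_synapses(tab, types, rules, seed=7)
        p_expected = p0 * np.exp(-(d**2 - 75.0**2) / (2 * sigma**2))
        n_pairs = 100 * 100
        se = np.sqrt(p_expected * (1 - p_expected) / n_pairs)
        assert abs(len(out) / n_pairs - p_expected) < 3 * se

    def test_delays_and_receptor_classes(self):
        tab, types = self._two_pop(n=30)
        pairs = {(a, b): 0.5 for a in types for b in types}
        rules = ConnectivityRules(
            p_base=pairs, sigma={("Exc", "Exc"): 200.0}, weight={k: 0.5 for k in pairs}
        )
        out = sample_recurrent_synapses(tab, types, rules, seed=1)
        assert out.delay.between(1, 4).all()
        assert (out.receptor == 0).all()  # all-excitatory populations


class TestLGNWiring:
    def _neurons(self):
        specs = [
            _spec(name="L23_Exc", count=1000, lgn_weight=5.0, lgn_mean_indegree=5.0, lgn_nb_r=0.5),
            _spec(name="L23_Sst", cls="Sst", count=50),
            _spec(name="L1_Htr3a", layer="L1", cls="Htr3a", count=20,
                  lgn_weight=2.0, lgn_mean_indegree=3.0),
        ]
        tab = place_neurons(specs, Geometry(radius=100.0), seed=0)
        return tab, {s.name: s for s in specs}

    def test_forbidden_targets_get_nothing(self):
        tab, types = self._neurons()
        out = wire_lgn(tab, types, n_lgn_units=50, seed=0)
        sst_ids = tab.loc[tab.cell_class == "Sst", "id"]
        assert not out.post.isin(sst_ids).any()

    def test_rule_violation_raises(self):
        bad = _spec(name="L4_Sst", layer="L4", cls="Sst", count=10,
                    lgn_weight=1.0, lgn_mean_indegree=2.0)
        tab = place_neurons([bad], Geometry(radius=100.0), seed=0)
        with pytest.raises(ConfigurationError):
            wire_lgn(tab, {"L4_Sst": bad}, n_lgn_units=10, seed=0)

    def test_zero_law_gives_empty_table(self):
        spec = _spec(count=100, lgn_weight=5.0, lgn_mean_indegree=0.0)
        tab = place_neurons([spec], Geometry(radius=100.0), seed=0)
        out = wire_lgn(tab, {spec.name: spec}, n_lgn_units=10, seed=0)
        assert len(out) == 0

    def test_l23_exc_indegree_overdispersed_with_mass_at_zero(self):
        tab, types = self._neurons()
        out = wire_lgn(tab, types, n_lgn_units=50, seed=3)
        exc_ids = tab.loc[tab.type == "L23_Exc", "id"].to_numpy()
        indeg = np.zeros(len(tab), dtype=int)
        np.add.at(indeg, out.post.to_numpy(), 1)
        k = indeg[exc_ids]
        assert k.var() > k.mean()  # overdispersion beyond Poisson
        assert (k == 0).mean() > 0.05  # strictly positive mass at zero


class TestBackground:
    def test_per_type_lookup_and_shape(self):
        specs = [_spec(count=5, bkg_weight=3.0), _spec(name="B", count=7, bkg_weight=1.5)]
        tab = place_neurons(specs, Geometry(radius=50.0), seed=0)
        w = wire_background(tab, {s.name: s for s in specs})
        assert len(w) == 12
        assert set(w[tab.type == "L23_Exc"]) == {3.0}
        assert set(w[tab.type == "B"]) == {1.5}

    def test_zero_weights_give_zero_vector(self):
        specs = [_spec(count=5, bkg_weight=0.0)]
        tab = place_neurons(specs, Geometry(radius=50.0), seed=0)
        assert np.all(wire_background(tab, {s.name: s for s in specs}) == 0.0)


class TestFullBuild:
    def test_build_is_deterministic(self, tiny_cfg):
        a = tiny_cfg.build(seed=99)
        b = tiny_cfg.build(seed=99)
        pd.testing.assert_frame_equal(a.neurons, b.neurons)
        pd.testing.assert_frame_equal(a.recurrent, b.recurrent)
        pd.testing.assert_frame_equal(a.lgn, b.lgn)
        assert np.array_equal(a.bkg_weight, b.bkg_weight)

    def test_sign_discipline_and_lgn_exclusion(self, tiny_cfg):
        net = tiny_cfg.build(seed=11)
        ei = net.neurons.set_index("id")["ei"]
        src_ei = ei.loc[net.recurrent.pre].to_numpy()
        w = net.recurrent.weight.to_numpy()
        assert np.all(w[src_ei == "E"] >= 0)
        assert np.all(w[src_ei == "I"] <= 0)
        # thalamic exclusion: no Sst targets anywhere, no Htr3a outside L1
        meta = net.neurons.set_index("id")
        targets = meta.loc[net.lgn.post]
        assert not (targets.cell_class == "Sst").any()
        assert not ((targets.cell_class == "Htr3a") & (targets.layer != "L1")).any()

    def test_no_self_synapses_and_positive_delays(self, tiny_cfg):
        net = tiny_cfg.build(seed=11)
        assert (net.recurrent.pre != net.recurrent.post).all()
        assert (net.recurrent.delay >= 1).all()
        r = np.hypot(net.neurons.x, net.neurons.y)
        assert (r <= net.geometry.radius + 1e-9).all()
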