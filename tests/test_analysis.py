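"""Tests of the response-analysis chain: rheobase, classification, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flowcol import analysis
from flowcol.glif import GLIFParams


def _lif(g=10.0, e_l=-70.0, v_th=-60.0, tau=10.0):
    return GLIFParams(C=g * tau, g=g, E_L=e_l, v_th=v_th, v_reset=e_l, t_ref=2.0)


class TestRheobase:
    def test_recovers_analytic_value(self):
        """g=10 nS, 10 mV to threshold: result in [100.00, 100.01] pA."""
        theta = analysis.rheobase(_lif())
        assert 100.0 <= theta <= 100.01

    def test_degenerate_threshold_fires_on_first_pulse(self):
        theta = analysis.rheobase(_lif(v_th=-70.0))
        assert theta == 1.0

    def test_within_one_increment_of_finite_pulse_bound(self):
        """Across a parameter sweep the grid search brackets the closed form."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = rng.uniform(3.0, 15.0)
            dv = rng.uniform(5.0, 30.0)
            tau = rng.uniform(5.0, 40.0)
            p = _lif(g=g, v_th=-70.0 + dv, tau=tau)
            bound = g * dv / (1.0 - np.exp(-1000.0 / tau))
            theta = analysis.rheobase(p)
            assert bound <= theta <= bound + 0.01 + 1e-9

    def test_coarser_increment_only_rounds_upward(self):
        p = _lif()
        fine = analysis.rheobase(p, increment=0.01)
        coarse = analysis.rheobase(p, increment=0.02)
        assert coarse >= fine >= 100.0

    def test_non_excitable_raises(self):
        with pytest.raises(analysis.NonExcitableError):
            analysis.rheobase(_lif(v_th=1000.0), ceiling=500.0)


class TestCurrents:
    def test_constant_trace_baseline(self):
        assert analysis.baseline_current(np.full(600, 10.0))[0] == 10.0

    def test_baseline_averages_trials(self):
        traces = np.stack([np.full((600, 3), 8.0), np.full((600, 3), 12.0)])
        assert np.allclose(analysis.baseline_current(traces), 10.0)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            analysis.baseline_current(np.full(100, 1.0), window=(0, 500))

    def test_delta_current_identity(self):
        """DeltaI equals the sum of its components minus I0 to 1e-12."""
        rng = np.random.default_rng(1)
        comp = rng.normal(size=(5, 40, 4))
        i0 = rng.normal(size=40)
        out = analysis.delta_current(comp, i0)
        recon = out.dI_in + out.dI_noise + out.dI_rec + out.dI_asc - out.I0
        assert np.allclose(out.dI, recon, atol=1e-12)

    def test_flat_response_is_zero(self):
        comp = np.full((3, 10, 4), 2.5)
        out = analysis.delta_current(comp, np.full(10, 10.0))
        assert np.allclose(out.dI, 0.0, atol=1e-12)

    def test_step_response(self):
        comp = np.zeros((1, 1, 4))
        comp[..., 0] = 15.0
        out = analysis.delta_current(comp, np.array([10.0]))
        assert out.dI[0] == pytest.approx(5.0)


class TestClassification:
    def test_threshold_cases(self):
        assert analysis.classify(6.0, 100.0) == "dVf"
        assert analysis.classify(-5.2, 100.0) == "hVf"
        # boundary is strict: exactly +/- 5 pA stays unclassified
        assert analysis.classify(5.0, 100.0) == "unclassified"
        assert analysis.classify(-5.0, 100.0) == "unclassified"

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_and_sign_symmetry(self, seed):
        """Labels partition the population; negating responses swaps classes."""
        rng = np.random.default_rng(seed)
        d_i = rng.normal(0.0, 8.0, size=300)
        theta = rng.uniform(50.0, 200.0, size=300)
        lab = analysis.classify(d_i, theta)
        assert set(np.unique(lab)) <= {"dVf", "hVf", "unclassified"}
        flipped = analysis.classify(-d_i, theta)
        assert np.sum(lab == "dVf") == np.sum(flipped == "hVf")
        assert np.sum(lab == "hVf") == np.sum(flipped == "dVf")
        assert np.array_equal(lab == "unclassified", flipped == "unclassified")

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            analysis.classify(np.nan, 100.0)
        with pytest.raises(ValueError):
            analysis.classify(1.0, 0.0)


class TestSmoothing:
    def test_empty_train_is_zero(self):
        _, rate = analysis.smooth_firing_rate(np.array([]), T_ms=1000.0)
        assert np.all(rate == 0.0)

    def test_single_spike_integrates_to_one(self):
        t, rate = analysis.smooth_firing_rate(np.array([5000.0]), T_ms=10_000.0)
        bin_s = (t[1] - t[0]) / 1000.0
        assert np.sum(rate) * bin_s == pytest.approx(1.0, rel=1e-6)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(2)
        T = 60_000.0
        spikes = np.sort(rng.uniform(0, T, rng.poisson(20.0 * T / 1000.0)))
        _, rate = analysis.smooth_firing_rate(spikes, T_ms=T)
        se = np.sqrt(20.0 / (T / 1000.0))
        assert abs(rate.mean() - 20.0) < 3 * se + 0.5  # slack for edge truncation


class TestEffectiveWeights:
    def test_simple_cases(self):
        assert analysis.effective_weight_pair(2.0, np.zeros(100)) == 0.0
        x = np.zeros(100)
        x[:5] = 1
        assert analysis.effective_weight_pair(2.0, x) == pytest.approx(0.1)
        assert analysis.effective_weight_type([0.1, 0.2, 0.3]) == pytest.approx(0.6)

    def test_matches_brute_force_on_random_instances(self):
        """Vectorized table equals an explicit loop over synapses and steps."""
        rng = np.random.default_rng(3)
        n, steps = 40, 200
        neurons = pd.DataFrame(
            {"id": np.arange(n), "type": rng.choice(["A", "B", "C"], size=n)}
        )
        syn = pd.DataFrame(
            {
                "pre": rng.integers(0, n, 150),
                "post": rng.integers(0, n, 150),
                "weight": rng.normal(size=150),
            }
        )
        x = rng.random((n, steps)) < 0.05  # spike indicators
        counts = x.sum(axis=1)
        table = analysis.effective_weight_table(syn, neurons, counts, steps)
        # brute force: per (pre_type, post), sum over synapses of W/steps per spike
        expect = {}
        for _, row in syn.iterrows():
            key = (neurons.type[row.pre], row.post)
            val = sum(row.weight * x[int(row.pre), t] for t in range(steps)) / steps
            expect[key] = expect.get(key, 0.0) + val
        for _, r in table.iterrows():
            assert r.w_eff == pytest.approx(expect[(r.pre_type, r.post)], rel=1e-10, abs=1e-12)


class TestSweeps:
    def test_across_direction_categories(self):
        assert analysis.classify_across_directions(["dVf"] * 8) == "perturbation-sensitive dVf"
        assert analysis.classify_across_directions(["hVf"] * 8) == "perturbation-sensitive hVf"
        labels = ["unclassified"] * 8
        labels[2] = "dVf"
        assert analysis.classify_across_directions(labels) == "direction-selective dVf"
        assert analysis.classify_across_directions(["dVf"] * 4 + ["hVf"] * 4) == "other"
        with pytest.raises(ValueError):
            analysis.classify_across_directions(["dVf"] * 7)

    def test_preferred_frequency(self):
        d_i = np.array([0.0, 1.0, 2.0, 3.0, 9.0, 3.0, 2.0, 1.0, 0.0])
        assert analysis.preferred_frequency(d_i, "dVf") == 5.0
        decreasing = -np.arange(9.0)
        assert analysis.preferred_frequency(decreasing, "hVf") == 9.0
        # sign flip swaps the dVf/hVf answers
        assert analysis.preferred_frequency(-d_i, "hVf") == 5.0
        with pytest.raises(ValueError):
            analysis.preferred_frequency(d_i, "unclassified")

    def test_preferred_frequency_tie_breaks_low(self):
        assert analysis.preferred_frequency(np.array([1.0, 3.0, 3.0, 1.0]), "dVf",
                                            tfs=[1, 2, 3, 4]) == 2.0


class TestStatistics:
    def test_identical_groups_close_the_gate(self):
        v = np.tile(np.arange(10.0), 3)
        labels = np.repeat(["a", "b", "c"], 10)
        rep = analysis.compare_classes(v, labels)
        assert rep["anova_p"] > 0.99
        assert rep["pairwise"] == []

    def test_two_groups_use_welch_directly(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(0.2, 2, 50)])
        labels = np.repeat(["a", "b"], 50)
        rep = analysis.compare_classes(v, labels)
        assert rep["anova_p"] is None
        assert len(rep["pairwise"]) == 1

    def test_shifted_groups_detected(self):
        """1 SD mean shift at n=200 per group is found at p < 0.01."""
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200), rng.normal(2, 1, 200)])
        labels = np.repeat(["a", "b", "c"], 200)
        rep = analysis.compare_classes(v, labels)
        assert rep["anova_p"] < 0.01
        assert all(p["p"] < 0.01 for p in rep["pairwise"])
        assert all(p["stars"] != "ns" for p in rep["pairwise"])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            analysis.compare_classes(np.arange(3.0), np.array(["a", "a", "b"]))


class TestConfusionMatrix:
    def test_identity_for_identical_labelings(self):
        labels = np.array(["dVf", "hVf", "unclassified"] * 5)
        mat = analysis.confusion_matrix(labels, labels)
        assert np.allclose(mat.to_numpy(), np.eye(3))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        ref = rng.choice(["dVf", "hVf", "unclassified"], 200)
        new = rng.choice(["dVf", "hVf", "unclassified"], 200)
        mat = analysis.confusion_matrix(ref, new)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_random_relabeling_approaches_class_frequencies(self):
        rng = np.random.default_rng(7)
        n = 30_000
        ref = rng.choice(["dVf", "hVf", "unclassified"], n)
        new = rng.permutation(ref)
        mat = analysis.confusion_matrix(ref, new)
        assert np.allclose(mat.to_numpy(), 1.0 / 3.0, atol=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            analysis.confusion_matrix(np.array(["dVf"]), np.array(["dVf", "hVf"]))
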