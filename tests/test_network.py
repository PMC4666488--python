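"""Unit and property tests for the network model."""

import numpy as np
import pytest

from critrange import (
    ModelConfig,
    NetworkState,
    WeightMatrix,
    apply_inhibitory_modulation,
    build_weight_matrix,
    depression_divisor,
    simulate_ongoing,
    simulate_stimulus_trials,
    step,
)

from _oracles import naive_simulate


class TestWeightMatrix:
    def test_leading_eigenvalue_is_one(self, default_weights):
        assert abs(default_weights.leading_eigenvalue_magnitude() - 1.0) < 1e-9

    def test_inhibitory_column_count_and_sign(self, default_weights):
        W = default_weights.weights
        inh = default_weights.inhibitory_columns
        assert inh.size == 200
        assert np.all(W[:, inh] <= 0)
        exc = np.setdiff1d(np.arange(1000), inh)
        assert np.all(W[:, exc] >= 0)
        # non-positive columns are exactly the designated ones
        nonpos = np.flatnonzero((W <= 0).all(axis=0))
        assert np.array_equal(nonpos, np.sort(inh))

    def test_zero_diagonal(self, default_weights):
        assert np.all(np.diag(default_weights.weights) == 0)

    def test_two_neuron_closed_form(self):
        # leading eigenvalue of [[0, a], [b, 0]] is sqrt(a*b)
        cfg = ModelConfig(n_neurons=2, inhibitory_fraction=0.0)
        rng_check = np.random.default_rng(3)
        raw = rng_check.uniform(0, 1, (2, 2))
        wm = build_weight_matrix(cfg, seed=3)
        a, b = raw[0, 1], raw[1, 0]
        expected_scale = 1.0 / np.sqrt(a * b)
        assert wm.weights[0, 0] == 0 and wm.weights[1, 1] == 0
        assert wm.weights[0, 1] == pytest.approx(a * expected_scale)
        assert wm.weights[1, 0] == pytest.approx(b * expected_scale)
        assert abs(wm.leading_eigenvalue_magnitude() - 1.0) < 1e-9

    def test_entries_bounded_by_scale(self, default_weights):
        W = default_weights.weights
        assert np.all(np.abs(W) <= default_weights.scale_factor)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(inhibitory_fraction=1.5)


class TestModulation:
    def test_gamma_one_is_identity(self, default_weights):
        out = apply_inhibitory_modulation(default_weights, 1.0)
        assert np.array_equal(out.weights, default_weights.weights)

    def test_gamma_zero_removes_inhibition_and_raises_eigenvalue(self, default_weights):
        out = apply_inhibitory_modulation(default_weights, 0.0)
        assert not np.any(out.weights < 0)
        assert out.gamma_applied == 0.0
        # purely excitatory matrix has a larger spectral radius
        assert out.leading_eigenvalue_magnitude() > 1.0 + 1e-6

    def test_gamma_three_lowers_eigenvalue(self, default_weights):
        out = apply_inhibitory_modulation(default_weights, 3.0)
        assert out.leading_eigenvalue_magnitude() < 1.0 - 1e-6

    def test_positive_entries_untouched(self, default_weights):
        out = apply_inhibitory_modulation(default_weights, 2.0)
        pos = default_weights.weights > 0
        assert np.array_equal(out.weights[pos], default_weights.weights[pos])

    def test_negative_gamma_rejected(self, default_weights):
        with pytest.raises(ValueError):
            apply_inhibitory_modulation(default_weights, -0.1)


class TestDepressionDivisor:
    def test_silent_neuron_gives_one(self):
        assert depression_divisor(np.zeros(4, dtype=int), 2) == 1.0

    def test_counts_returned_directly(self):
        counts = np.array([0, 4, 1, 7])
        assert depression_divisor(counts, 1) == 4.0
        assert np.array_equal(depression_divisor(counts), [1.0, 4.0, 1.0, 7.0])

    def test_no_depression_window_always_one(self):
        # with T = 0 the history counts stay zero, so h is identically 1
        state = NetworkState.zeros(5, depression_window=0)
        assert np.all(depression_divisor(state.history_counts) == 1.0)


class TestStep:
    def _weights(self, n, seed=0, frac=0.2):
        return build_weight_matrix(ModelConfig(n_neurons=n, inhibitory_fraction=frac), seed=seed)

    def test_quiescent_network_stays_quiescent_without_drive(self, rng):
        wm = self._weights(10)
        state = NetworkState.zeros(10, 5)
        out = step(state, wm, p_ext=0.0, rng=rng)
        assert not out.s.any()
        assert not out.external_flags.any()

    def test_supra_unit_input_fires_with_certainty(self, rng):
        # all presynaptic neurons active and strong positive coupling: I > 1
        n = 6
        W = np.full((n, n), 2.0)
        np.fill_diagonal(W, 0.0)
        wm = WeightMatrix(W, np.empty(0, dtype=int), 1.0)
        state = NetworkState.zeros(n, 0)
        state.s[:] = True
        out = step(state, wm, p_ext=0.0, rng=rng)
        assert out.s.all()

    def test_negative_input_never_fires_recurrently(self, rng):
        n = 8
        W = -np.ones((n, n))
        np.fill_diagonal(W, 0.0)
        wm = WeightMatrix(W, np.arange(n), 1.0)
        state = NetworkState.zeros(n, 0)
        state.s[:] = True
        out = step(state, wm, p_ext=0.0, rng=rng)
        assert not out.s.any()

    def test_external_flags_subset_of_spikes(self, rng):
        wm = self._weights(20)
        state = NetworkState.zeros(20, 5)
        state.s[::3] = True
        out = step(state, wm, p_ext=0.5, rng=rng)
        assert not np.any(out.external_flags & ~out.s)


class TestSimulateOngoing:
    def test_deterministic_for_fixed_seed(self, small_config):
        r1 = simulate_ongoing(small_config, 300, seed=42)
        r2 = simulate_ongoing(small_config, 300, seed=42)
        assert np.array_equal(r1.spike_steps, r2.spike_steps)
        assert np.array_equal(r1.spike_neurons, r2.spike_neurons)
        assert np.array_equal(r1.external, r2.external)

    def test_uncoupled_rate_matches_external_drive(self):
        # W = 0: spikes are purely external Bernoulli events
        cfg = ModelConfig(n_neurons=1000, p_ext_baseline=5e-6)
        wm = WeightMatrix(np.zeros((1000, 1000)), np.empty(0, dtype=int), 1.0)
        n_steps = 200_000
        raster = simulate_ongoing(cfg, n_steps, seed=11, weights=wm)
        expected = 1000 * n_steps * 5e-6
        sd = np.sqrt(1000 * n_steps * 5e-6 * (1 - 5e-6))
        assert abs(raster.n_spikes - expected) < 3 * sd
        assert raster.external_count() == raster.n_spikes

    def test_external_marks_match_dense_invariant(self, small_config):
        raster = simulate_ongoing(small_config, 500, seed=7)
        dense = raster.to_dense()
        ext = raster.external_to_dense()
        assert not np.any(ext & ~dense)

    def test_matches_naive_loop_oracle(self, small_config):
        """Vectorized driver and per-neuron/per-step loop agree exactly."""
        wm = build_weight_matrix(small_config, seed=5)
        rng_fast = np.random.default_rng(99)
        raster = simulate_ongoing(
            small_config, 500, seed=rng_fast, weights=wm
        )
        rng_slow = np.random.default_rng(99)
        expected = naive_simulate(
            wm.weights, small_config.depression_window, small_config.p_ext_baseline,
            500, rng_slow,
        )
        assert np.array_equal(raster.to_dense(), expected)

    def test_depression_limits_saturation(self):
        """At gamma=0, depression keeps the network from sustained saturation
        while the no-depression variant locks into a high-activity state."""
        # drive strong enough that ignition seeds arrive early in the run
        base = dict(
            n_neurons=300, inhibitory_fraction=0.2, gamma=0.0, p_ext_baseline=1e-4
        )
        with_dep = simulate_ongoing(
            ModelConfig(**base, depression_window=80), 3000, seed=21
        )
        without = simulate_ongoing(
            ModelConfig(**base, depression_window=0), 3000, seed=21
        )
        pop_dep = with_dep.population_counts()
        pop_no = without.population_counts()
        # no-depression: persistent high occupancy once ignited
        assert pop_no[-1000:].mean() > 0.5 * 300
        # depression: bursty, never saturating at N
        assert pop_dep.max() < 300
        assert pop_dep[-1000:].mean() < 0.5 * 300


class TestStimulusTrials:
    def test_baseline_level_response_matches_ongoing(self):
        # subcritical state: light-tailed counts make the comparison stable
        cfg = ModelConfig(
            n_neurons=200, gamma=3.0, depression_window=80, p_ext_baseline=1e-4
        )
        ts = simulate_stimulus_trials(
            cfg, levels=[cfg.p_ext_baseline], reps=30, response_window=100,
            inter_trial_gap=300, seed=3,
        )
        # null stimulus: response statistically indistinguishable from ongoing
        sem = np.sqrt(ts.responses.var() + ts.ongoing_counts.var()) / np.sqrt(30)
        assert ts.responses.mean() == pytest.approx(
            ts.ongoing_counts.mean(), abs=3 * sem + 1e-9
        )

    def test_monotone_response_in_level(self, default_weights):
        cfg = ModelConfig(gamma=1.0, depression_window=80)
        ts = simulate_stimulus_trials(
            cfg, reps=5, inter_trial_gap=400, seed=8, weights=default_weights
        )
        means = ts.mean_responses()
        # strong stimuli evoke far larger responses than weak ones
        assert means[-1] > means[0]
        assert np.corrcoef(np.log10(ts.levels), means)[0, 1] > 0.9

    def test_overlapping_windows_rejected(self):
        cfg = ModelConfig(n_neurons=50)
        with pytest.raises(ValueError):
            simulate_stimulus_trials(cfg, reps=1, response_window=200, inter_trial_gap=100)

    def test_levels_validated(self):
        cfg = ModelConfig(n_neurons=50)
        with pytest.raises(ValueError):
            simulate_stimulus_trials(cfg, levels=[1e-7], reps=1)
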