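"""Tests for response extraction, sigmoid fitting and dynamic range."""

import numpy as np
import pandas as pd
import pytest

from critrange import (
    EventTable,
    ResponseCurve,
    SigmoidFit,
    StimulusTrialSet,
    TrialTable,
    bin_curve,
    dynamic_range,
    extract_responses,
    fit_sigmoid,
    model_response_curve,
    select_dominant_whisker,
    sigmoid,
)


def curve_from(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return ResponseCurve(x, y, np.ones(x.size, dtype=np.int64))


class TestExtractResponses:
    def test_counts_spikes_across_channels_in_window(self):
        # 2 channels x 3 spikes each inside the window, plus spikes outside
        times = np.concatenate([np.full(3, 1.02), np.full(3, 1.05), [0.5, 2.0]])
        chans = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        events = EventTable(chans, times, 2)
        log = pd.DataFrame({"onset_s": [1.0], "speed": [12.0]})
        tt = extract_responses(events, log, window=0.1)
        assert tt.responses.tolist() == [6.0]

    def test_no_spikes_gives_zero(self):
        events = EventTable(np.array([0]), np.array([5.0]), 1)
        log = pd.DataFrame({"onset_s": [1.0, 2.0], "speed": [1.0, 2.0]})
        tt = extract_responses(events, log)
        assert tt.responses.tolist() == [0.0, 0.0]

    def test_overlapping_windows_rejected(self):
        events = EventTable(np.array([0]), np.array([0.5]), 1)
        log = pd.DataFrame({"onset_s": [1.0, 1.05], "speed": [1.0, 2.0]})
        with pytest.raises(ValueError):
            extract_responses(events, log, window=0.1)


class TestDominantWhisker:
    def test_single_whisker(self):
        tt = TrialTable(np.arange(3.0), np.ones(3), np.ones(3))
        assert select_dominant_whisker({4: tt}) == 4

    def test_planted_strongest_selected(self):
        weak = TrialTable(np.arange(3.0), np.ones(3), np.array([1.0, 2, 1]))
        strong = TrialTable(np.arange(3.0), np.ones(3), np.array([9.0, 8, 10]))
        assert select_dominant_whisker({0: weak, 1: strong}) == 1

    def test_tie_resolves_to_lowest_index(self):
        a = TrialTable(np.arange(2.0), np.ones(2), np.array([3.0, 5.0]))
        b = TrialTable(np.arange(2.0), np.ones(2), np.array([4.0, 4.0]))
        with pytest.warns(RuntimeWarning):
            assert select_dominant_whisker({2: a, 1: b}) == 1


class TestBinCurve:
    def test_uniform_stimuli_make_equal_width_bins(self, rng):
        stim = rng.uniform(0, 30, 500)
        stim[0], stim[1] = 0.0, 30.0
        tt = TrialTable(np.arange(500.0) * 10, stim, rng.poisson(5, 500).astype(float))
        curve = bin_curve(tt, 10)
        widths = np.diff(curve.bin_centers)
        assert np.allclose(widths, 3.0)
        assert curve.bin_counts.sum() == 500

    def test_planted_bin_means_recovered(self):
        stim = np.repeat(np.arange(10) + 0.5, 2)  # 2 trials centered in each bin
        resp = np.repeat(np.arange(10.0) * 2, 2)
        tt = TrialTable(np.arange(20.0) * 10, stim, resp)
        # span [0.5, 9.5] -> 10 bins of width 0.9; planted equal pairs per bin
        curve = bin_curve(tt, 10)
        assert np.allclose(curve.mean_responses[curve.occupied][[0, -1]], [0.0, 18.0])

    def test_empty_bin_flagged(self):
        stim = np.array([0.0, 1.0, 9.0, 10.0])
        tt = TrialTable(np.arange(4.0) * 10, stim, np.ones(4))
        curve = bin_curve(tt, 10)
        assert curve.has_empty_bins
        assert curve.occupied.sum() < 10

    def test_identical_stimuli_rejected(self):
        tt = TrialTable(np.arange(4.0), np.full(4, 2.0), np.ones(4))
        with pytest.raises(ValueError):
            bin_curve(tt)


class TestFitSigmoid:
    def test_noiseless_round_trip(self):
        x = np.linspace(0, 30, 10)
        y = sigmoid(x, 50.0, 0.5, 10.0, 2.0)
        fit = fit_sigmoid(curve_from(x, y), r_min=2.0)
        assert fit.converged
        assert fit.r_max == pytest.approx(50.0, abs=1e-6)
        assert fit.b == pytest.approx(0.5, abs=1e-6)
        assert fit.c == pytest.approx(10.0, abs=1e-6)

    def test_noisy_recovery_within_five_percent(self, rng):
        x = np.linspace(0, 30, 10)
        reps = 20
        y = np.array(
            [np.mean(sigmoid(xi, 50.0, 0.5, 10.0, 2.0) + rng.normal(0, 1, reps)) for xi in x]
        )
        fit = fit_sigmoid(curve_from(x, y), r_min=2.0)
        assert fit.converged
        assert fit.r_max == pytest.approx(50.0, rel=0.05)
        assert fit.b == pytest.approx(0.5, rel=0.05)
        assert fit.c == pytest.approx(10.0, rel=0.05)

    def test_flat_data_flagged_unconverged(self):
        x = np.linspace(0, 30, 10)
        fit = fit_sigmoid(curve_from(x, np.full(10, 2.0)), r_min=2.0)
        assert not fit.converged

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid(curve_from([1, 2, 3], [1, 2, 3]), r_min=0.0)


class TestDynamicRange:
    def test_analytic_example(self):
        # R_min=0, R_max=1, b=1, c=5: S10 = 5 - ln 9, S90 = 5 + ln 9
        fit = SigmoidFit(0.0, 1.0, 1.0, 5.0, converged=True)
        res = dynamic_range(fit)
        assert res.s10 == pytest.approx(5 - np.log(9), abs=1e-9)
        assert res.s90 == pytest.approx(5 + np.log(9), abs=1e-9)
        assert res.delta == pytest.approx(10 * np.log10((5 + np.log(9)) / (5 - np.log(9))), abs=1e-9)
        assert res.delta == pytest.approx(4.096, abs=1e-3)

    def test_decade_ratio_gives_ten_db(self):
        # construct b, c so that S90/S10 = 10 exactly (with R_min = 0)
        s10, s90 = 2.0, 20.0
        b = 2 * np.log(9) / (s90 - s10)
        c = 0.5 * (s10 + s90)
        res = dynamic_range(SigmoidFit(0.0, 1.0, b, c, converged=True))
        assert res.delta == pytest.approx(10.0, abs=1e-9)

    def test_inversion_consistency(self):
        fit = SigmoidFit(2.0, 50.0, 0.5, 10.0, converged=True)
        res = dynamic_range(fit)
        assert fit(res.s10) == pytest.approx(res.r10, abs=1e-9)
        assert fit(res.s90) == pytest.approx(res.r90, abs=1e-9)

    def test_stimulus_axis_scale_invariance(self):
        fit_mm = SigmoidFit(2.0, 50.0, 0.5, 10.0, converged=True)
        # same curve in cm/s: b *= 10, c /= 10
        fit_cm = SigmoidFit(2.0, 50.0, 5.0, 1.0, converged=True)
        assert dynamic_range(fit_mm).delta == pytest.approx(
            dynamic_range(fit_cm).delta, abs=1e-9
        )

    def test_response_axis_affine_invariance(self):
        base = SigmoidFit(2.0, 50.0, 0.5, 10.0, converged=True)
        scaled = SigmoidFit(2.0 * 3, 50.0 * 3, 0.5, 10.0, converged=True)
        assert dynamic_range(base).delta == pytest.approx(
            dynamic_range(scaled).delta, abs=1e-9
        )

    def test_s10_clamped_with_warning(self):
        # shallow sigmoid centered near zero extrapolates S10 below zero
        fit = SigmoidFit(0.0, 1.0, 1.0, 1.0, converged=True)
        with pytest.warns(RuntimeWarning):
            res = dynamic_range(fit, smallest_positive_stimulus=0.5)
        assert res.clamped and res.s10 == 0.5

    def test_unconverged_fit_rejected(self):
        with pytest.raises(ValueError):
            dynamic_range(SigmoidFit(0.0, 1.0, np.nan, np.nan, converged=False))


def make_trialset(levels, responses_per_level, ongoing, reps=5):
    levels = np.asarray(levels, float)
    trial_levels = np.repeat(levels, reps)
    responses = np.repeat(np.asarray(responses_per_level, float), reps)
    return StimulusTrialSet(
        levels=levels,
        repetitions=reps,
        response_window=200,
        trial_levels=trial_levels,
        onset_steps=np.arange(trial_levels.size) * 1000,
        responses=responses,
        ongoing_counts=np.full(trial_levels.size, ongoing),
    )


class TestModelResponseCurve:
    def test_planted_sigmoid_round_trip(self):
        # responses exactly on a sigmoid in log10(p_ext)
        levels = np.logspace(-5.3, -3, 10)
        logx = np.log10(levels)
        r_min, r_max = 10.0, 1000.0
        y = r_min + (r_max - r_min) / (1 + np.exp(-4.0 * (logx - (-4.15))))
        ts = make_trialset(levels, y, ongoing=r_min)
        _, dr = model_response_curve(ts, truncate_at=None)
        # analytic inversion of the planted log-domain sigmoid
        span = r_max - r_min
        r10 = r_min + 0.1 * span
        r90 = r_min + 0.9 * span
        s10 = -4.15 - np.log(span / (r10 - r_min) - 1) / 4.0
        s90 = -4.15 - np.log(span / (r90 - r_min) - 1) / 4.0
        assert dr.delta == pytest.approx(10 * (s90 - s10), rel=0.05)

    def test_truncation_drops_high_levels(self):
        levels = np.logspace(-5.3, -1, 10)
        y = np.linspace(5, 500, 10)
        ts = make_trialset(levels, y, ongoing=5.0)
        curve, _ = model_response_curve(ts, truncate_at=1e-3)
        assert np.all(curve.bin_centers <= 1e-3)

    def test_nonmonotone_peak_smoothed_below_r90_flagged(self):
        # a transient mid-curve peak sets R_max, but the monotone regression
        # smooths it away, so the curve never traverses to R90
        levels = np.logspace(-5, -3, 4)
        y = np.array([10.0, 80.0, 30.0, 30.0])
        ts = make_trialset(levels, y, ongoing=10.0)
        with pytest.warns(RuntimeWarning):
            _, dr = model_response_curve(ts, truncate_at=None, r_min=10.0)
        assert dr is None

    def test_fully_saturated_state_has_zero_delta(self):
        # flat curve already above R90 at the weakest stimulus
        levels = np.logspace(-5, -3, 6)
        y = np.full(6, 1000.0)
        ts = make_trialset(levels, y, ongoing=999.0)
        _, dr = model_response_curve(ts, truncate_at=None, r_min=999.0)
        assert dr is not None and dr.clamped
        assert dr.delta == pytest.approx(0.0, abs=1e-9)

    def test_flat_curve_at_ongoing_undefined(self):
        levels = np.logspace(-5, -3, 5)
        ts = make_trialset(levels, np.full(5, 7.0), ongoing=7.0)
        with pytest.warns(RuntimeWarning):
            _, dr = model_response_curve(ts, truncate_at=None)
        assert dr is None
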