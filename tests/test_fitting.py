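"""Logistic fit, metric extraction and detector tests."""

import dataclasses
import warnings

import numpy as np
import pytest

from covertrace import (
    FitDataError,
    GazeTrace,
    LogisticFitResult,
    MetricUnavailableError,
    ParameterError,
    PhoriaTraceParams,
    SmallDeviationWarning,
    StabilizationWarning,
    TropiaTraceParams,
    classify_overshoot,
    compute_metrics,
    detect_rebound_saccade,
    deviation_signal,
    fit_logistic,
    logistic_model,
    overshoot_depth,
    peak_speed,
    simulate_phoria_trace,
    simulate_tropia_trace,
    stabilization_time,
)


def _tiny_trace(fixating, covered, side="left", fs=30.0, missing=None):
    n = len(fixating)
    t = (np.arange(n) - n // 2) / fs
    return GazeTrace(
        sample_times=t,
        fixating_eye_pos=np.asarray(fixating, dtype=float),
        covered_eye_pos=np.asarray(covered, dtype=float),
        covered_eye_side=side,
        fs_hz=fs,
        missing_mask=missing,
    )


class TestDeviationSignal:
    def test_identical_series_give_zero(self):
        x = np.linspace(-1, 1, 9)
        tr = _tiny_trace(x, x)
        assert np.allclose(deviation_signal(tr), 0.0)

    def test_temporal_excursion_of_covered_right_eye_is_exo_negative(self):
        """Covered right eye 2° rightward (temporal) of the fixating eye."""
        tr = _tiny_trace(np.zeros(9), np.full(9, 2.0), side="right")
        assert np.allclose(deviation_signal(tr), -2.0)

    def test_temporal_excursion_of_covered_left_eye_is_exo_negative(self):
        """Covered left eye 2° leftward (temporal): same signed deviation."""
        tr = _tiny_trace(np.zeros(9), np.full(9, -2.0), side="left")
        assert np.allclose(deviation_signal(tr), -2.0)

    def test_missing_samples_propagate(self):
        missing = np.zeros(9, dtype=bool)
        missing[4] = True
        cov = np.zeros(9)
        cov[4] = np.nan
        tr = _tiny_trace(np.zeros(9), cov, missing=missing)
        dev = deviation_signal(tr)
        assert np.isnan(dev[4]) and np.isfinite(np.delete(dev, 4)).all()


class TestFitLogistic:
    def test_noise_free_recovery_to_machine_precision(self, noise_free_trace):
        fit = fit_logistic(noise_free_trace)
        assert fit.converged
        assert fit.baseline_deg == pytest.approx(0.0, abs=1e-6)
        assert fit.deviation_a_deg == pytest.approx(-6.0, abs=1e-6)
        assert fit.rate_k_per_s == pytest.approx(2.0, abs=1e-6)
        assert fit.midpoint_t0_s == pytest.approx(1.5, abs=1e-6)

    def test_flat_noisy_trace_flags_small_deviation(self):
        """A zero-deviation trace should not masquerade as a real phoria."""
        flagged, small_amp = 0, 0
        for seed in range(100):
            p = PhoriaTraceParams(
                deviation_deg=0.0, rate_per_s=1.0, noise_sd_deg=0.1, seed=seed
            )
            tr = simulate_phoria_trace(p)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SmallDeviationWarning)
                fit = fit_logistic(tr)
            flagged += fit.small_deviation
            small_amp += abs(fit.deviation_a_deg) < 0.4
        assert flagged >= 95
        assert small_amp >= 95

    def test_noisy_recovery_is_unbiased(self):
        a_hat = []
        for seed in range(50):
            p = PhoriaTraceParams(noise_sd_deg=0.2, seed=1000 + seed)
            fit = fit_logistic(simulate_phoria_trace(p))
            a_hat.append(fit.deviation_a_deg)
        assert abs(np.mean(a_hat) + 6.0) < 0.1
        assert np.std(a_hat) < 0.15

    def test_too_few_samples_raises(self):
        tr = _tiny_trace(np.zeros(9), np.zeros(9))
        with pytest.raises(FitDataError):
            fit_logistic(tr)

    def test_missing_samples_excluded_from_loss(self):
        p = PhoriaTraceParams(noise_sd_deg=0.1, blink_prob=0.1, seed=2)
        tr = simulate_phoria_trace(p)
        fit = fit_logistic(tr)
        assert fit.n_used == int((~tr.missing_mask).sum())
        assert fit.converged


class TestPeakSpeed:
    def test_closed_form(self):
        fit = LogisticFitResult(0.0, -6.0, 2.0, 1.5, 0.0, True, 601)
        assert peak_speed(fit) == pytest.approx(3.0)

    def test_zero_amplitude(self):
        fit = LogisticFitResult(0.0, 0.0, 2.0, 1.5, 0.0, True, 601)
        assert peak_speed(fit) == 0.0

    def test_matches_dense_numerical_derivative(self, noise_free_trace):
        fit = fit_logistic(noise_free_trace)
        tt = np.linspace(-10, 10, 20001)  # 1 kHz sampling
        f = logistic_model(tt, fit.baseline_deg, fit.deviation_a_deg, fit.rate_k_per_s, fit.midpoint_t0_s)
        v_max = np.max(np.abs(np.diff(f) / np.diff(tt)))
        assert peak_speed(fit) == pytest.approx(v_max, rel=1e-3)

    def test_requires_convergence(self):
        fit = LogisticFitResult(0.0, -6.0, 2.0, 1.5, 0.0, False, 601)
        with pytest.raises(MetricUnavailableError):
            peak_speed(fit)


class TestStabilizationTime:
    def test_closed_form(self):
        fit = LogisticFitResult(0.0, -6.0, np.log(9.0), 1.0, 0.0, True, 601)
        assert stabilization_time(fit) == pytest.approx(2.0)

    def test_step_function_limit(self):
        fit = LogisticFitResult(0.0, -6.0, 200.0, 0.5, 0.0, True, 601)
        assert stabilization_time(fit) == pytest.approx(0.5, abs=0.02)

    def test_plug_back_reaches_90_percent(self, noise_free_trace):
        fit = fit_logistic(noise_free_trace)
        t_star = stabilization_time(fit)
        f = logistic_model(t_star, fit.baseline_deg, fit.deviation_a_deg, fit.rate_k_per_s, fit.midpoint_t0_s)
        assert abs(f - fit.baseline_deg) / abs(fit.deviation_a_deg) == pytest.approx(
            0.9, abs=1e-9
        )

    def test_pre_onset_midpoint_returns_zero_with_warning(self):
        fit = LogisticFitResult(0.0, -6.0, 2.0, -5.0, 0.0, True, 601)
        with pytest.warns(StabilizationWarning):
            assert stabilization_time(fit) == 0.0


class TestOvershoot:
    def test_monotone_trace_has_zero_depth(self, noise_free_trace):
        fit = fit_logistic(noise_free_trace)
        depth, max_dev = overshoot_depth(noise_free_trace, fit)
        assert depth == 0.0
        assert max_dev == pytest.approx(-6.0, abs=0.05)

    @pytest.mark.parametrize("k", [0.3, 1.0, 20.0])
    def test_monotone_zero_depth_across_rates(self, k):
        p = PhoriaTraceParams(rate_per_s=k, noise_sd_deg=0.0, seed=0)
        tr = simulate_phoria_trace(p)
        fit = fit_logistic(tr)
        assert overshoot_depth(tr, fit)[0] == 0.0

    def test_constructed_transient_recovered(self):
        p = PhoriaTraceParams(overshoot_amp_deg=1.2, noise_sd_deg=0.0, seed=0)
        tr = simulate_phoria_trace(p)
        fit = fit_logistic(tr)
        depth, _ = overshoot_depth(tr, fit)
        assert 1.1 <= depth <= 1.3

    def test_noise_floor_documented(self):
        """Median depth from pure noise stays below the smallest category edge."""
        depths = []
        for seed in range(200):
            p = PhoriaTraceParams(noise_sd_deg=0.2, seed=3000 + seed)
            tr = simulate_phoria_trace(p)
            fit = fit_logistic(tr)
            depths.append(overshoot_depth(tr, fit)[0])
        assert np.median(depths) < 0.5


class TestClassifyOvershoot:
    @pytest.mark.parametrize(
        "depth,expected",
        [(0.7, "mid"), (0.0, "lt0p5"), (1.0001, "gt1"), (0.5, "mid"), (1.0, "mid"), (0.4999, "lt0p5")],
    )
    def test_category_bounds(self, depth, expected):
        assert classify_overshoot(depth) == expected

    def test_negative_depth_rejected(self):
        with pytest.raises(ParameterError):
            classify_overshoot(-0.1)


class TestReboundSaccade:
    def test_tropia_with_rebound_detected(self):
        p = TropiaTraceParams(rebound_amp_deg=3.0, noise_sd_deg=0.0, seed=0)
        assert detect_rebound_saccade(simulate_tropia_trace(p)) is True

    def test_tropia_without_rebound_not_detected(self):
        p = TropiaTraceParams(rebound_amp_deg=0.0, noise_sd_deg=0.0, seed=0)
        assert detect_rebound_saccade(simulate_tropia_trace(p)) is False

    def test_slow_phoria_not_detected(self):
        p = PhoriaTraceParams(deviation_deg=-8.0, rate_per_s=2.0, noise_sd_deg=0.1, seed=5)
        assert detect_rebound_saccade(simulate_phoria_trace(p)) is False


class TestInvariants:
    @pytest.mark.parametrize("a,k", [(-2.0, 0.5), (-6.0, 2.0), (-10.0, 8.0)])
    def test_forward_inverse_consistency(self, a, k):
        p = PhoriaTraceParams(deviation_deg=a, rate_per_s=k, noise_sd_deg=0.0, seed=0)
        tr = simulate_phoria_trace(p)
        fit = fit_logistic(tr)
        gt = tr.ground_truth
        m = compute_metrics(tr, fit)
        assert fit.deviation_a_deg == pytest.approx(a, abs=1e-6)
        assert fit.rate_k_per_s == pytest.approx(k, abs=1e-6)
        assert m.peak_speed_deg_s == pytest.approx(gt["peak_speed_deg_s"], abs=1e-6)
        assert m.stabilization_time_s == pytest.approx(gt["stabilization_time_s"], abs=1e-6)

    def test_stabilization_decreases_with_rate(self):
        times = [
            stabilization_time(LogisticFitResult(0.0, -6.0, k, 1.0, 0.0, True, 601))
            for k in (0.5, 1.0, 2.0, 5.0, 20.0)
        ]
        assert all(t1 > t2 for t1, t2 in zip(times, times[1:]))

    def test_peak_speed_increases_with_amplitude(self):
        speeds = [
            peak_speed(LogisticFitResult(0.0, a, 2.0, 1.0, 0.0, True, 601))
            for a in (-2.0, -4.0, -8.0, -12.0)
        ]
        assert all(s1 < s2 for s1, s2 in zip(speeds, speeds[1:]))

    def test_sign_equivariance(self):
        p = PhoriaTraceParams(noise_sd_deg=0.1, overshoot_amp_deg=0.8, seed=7)
        tr = simulate_phoria_trace(p)
        flipped = GazeTrace(
            tr.sample_times,
            -tr.fixating_eye_pos,
            -tr.covered_eye_pos,
            tr.covered_eye_side,
            tr.fs_hz,
            tr.missing_mask,
        )
        m1 = compute_metrics(tr)
        m2 = compute_metrics(flipped)
        assert m2.angle_deg == pytest.approx(-m1.angle_deg, abs=1e-6)
        assert m2.max_deviation_deg == pytest.approx(-m1.max_deviation_deg, abs=1e-6)
        assert m2.peak_speed_deg_s == pytest.approx(m1.peak_speed_deg_s, abs=1e-6)
        assert m2.stabilization_time_s == pytest.approx(m1.stabilization_time_s, abs=1e-6)
        assert m2.overshoot_depth_deg == pytest.approx(m1.overshoot_depth_deg, abs=1e-6)
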