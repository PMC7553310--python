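"""Curve-level procedures: decay, Hill, AUC, smoothing, qPCR arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

from isgdyn.curves import (
    auc_timecourse,
    fit_exponential_decay,
    fit_hill,
    normalize_to_reference,
    relative_quantity,
    smooth_timecourse,
)
from isgdyn.synth import GeneratorConfig, generate_decay_series, generate_dose_response


class TestExponentialDecay:
    def test_noiseless_halving_series_gives_exact_half_life(self):
        fit = fit_exponential_decay([0, 2, 4, 8], [1.0, 0.5, 0.25, 0.0625])
        assert fit.t_half == pytest.approx(2.0, rel=1e-5)
        assert fit.d == pytest.approx(0.0, abs=1e-6)
        assert not fit.stable

    def test_noiseless_recovery_of_all_three_parameters(self):
        t = np.array([0, 0.5, 1, 2, 3, 4, 6, 8.0])
        y = 0.3 + 1.7 * 2.0 ** (-t / 1.25)
        fit = fit_exponential_decay(t, y)
        assert fit.d == pytest.approx(0.3, rel=1e-5)
        assert fit.a == pytest.approx(1.7, rel=1e-5)
        assert fit.t_half == pytest.approx(1.25, rel=1e-5)

    def test_value_at_half_life_is_half_amplitude_when_offset_zero(self):
        fit = fit_exponential_decay([0, 1, 2, 4, 6], 2.0 ** (-np.array([0, 1, 2, 4, 6.0]) / 1.5))
        assert fit(1.5) == pytest.approx(fit.a / 2 + fit.d, rel=1e-4)

    def test_noisy_recovery_of_one_hour_half_life(self):
        # generate-and-fit oracle: sd=0.05, true half-life 1 h, 8 chase
        # times in biological duplicate, 100 seeded repeats
        errs = []
        for seed in range(100):
            df = generate_decay_series(
                1.0, GeneratorConfig(seed=seed), times=(0, 0.5, 1, 1.5, 2, 3, 4, 6),
                d=0.0, noise_sd=0.05, n_replicates=2,
            )
            fit = fit_exponential_decay(df["time_h"], df["value"])
            errs.append(abs(fit.t_half - 1.0))
        assert np.median(errs) < 0.10
        assert np.mean(np.array(errs) < 0.15) > 0.75

    def test_non_decreasing_series_classified_stable(self):
        fit = fit_exponential_decay([0, 2, 4, 8], [1.0, 1.0, 1.1, 1.2])
        assert fit.stable
        assert math.isinf(fit.t_half)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([0, 1, 2], [1, 0.5, 0.25])


class TestHill:
    def test_exact_hill_data_recovers_ec50_and_inflection_value(self):
        x = np.array([0, 10, 30, 100, 300, 1000, 5000.0])
        y = 1.0 * x / (100.0 + x)  # d=0, a=1, b=1, c=100
        fit = fit_hill(x, y)
        assert fit.c == pytest.approx(100.0, rel=1e-4)
        assert fit(100.0) == pytest.approx(fit.d + fit.a / 2, rel=1e-4)

    def test_noisy_recovery_within_20_percent(self):
        # triplicate 9-level design at 5% noise; the estimator is within
        # 20% of the true EC50 in the typical dataset
        errs = []
        for seed in range(50):
            df = generate_dose_response(135.0, GeneratorConfig(seed=seed))
            fit = fit_hill(df["dose_Uml"], df["value"])
            errs.append(abs(fit.ec50 - 135.0) / 135.0)
        errs = np.array(errs)
        assert np.median(errs) < 0.10
        assert np.mean(errs < 0.2) >= 0.9

    def test_dose_rescaling_rescales_ec50(self):
        x = np.array([0, 10, 30, 100, 300, 1000, 5000.0])
        y = 0.1 + 0.9 * x**1.3 / (150.0**1.3 + x**1.3)
        f1 = fit_hill(x, y)
        f2 = fit_hill(10 * x, y)
        assert f2.c == pytest.approx(10 * f1.c, rel=1e-3)

    def test_value_offset_absorbed_into_intercept(self):
        x = np.array([0, 10, 30, 100, 300, 1000, 5000.0])
        y = 0.9 * x**1.3 / (150.0**1.3 + x**1.3)
        f1 = fit_hill(x, y)
        f2 = fit_hill(x, y + 5.0)
        assert f2.d == pytest.approx(f1.d + 5.0, rel=1e-3, abs=1e-3)
        assert f2.c == pytest.approx(f1.c, rel=1e-3)

    def test_flat_replicated_response_flagged_poor(self):
        rng = np.random.default_rng(0)
        x = np.tile([0, 10, 30, 100, 300, 1000, 5000.0], 3)
        fit = fit_hill(x, rng.normal(1.0, 0.3, len(x)))
        assert fit.poor_fit

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([0, 10, 100, 1000], [0, 0.2, 0.6, 1.0])


class TestAUC:
    def test_constant_signal(self):
        assert auc_timecourse([0, 6, 12, 24], [1, 1, 1, 1]) == pytest.approx(24.0)

    def test_triangle(self):
        assert auc_timecourse([0, 1, 2], [0, 1, 0]) == pytest.approx(1.0)

    def test_matches_manual_trapezoid_sum(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 24, 20))
        y = rng.normal(size=20)
        manual = sum(
            0.5 * (y[i] + y[i + 1]) * (t[i + 1] - t[i]) for i in range(19)
        )
        assert auc_timecourse(t, y) == pytest.approx(manual, abs=1e-12)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            auc_timecourse([0, 2, 1], [1, 1, 1])


class TestSmoothing:
    def test_p1_interpolates(self):
        t = np.arange(8.0)
        y = np.sin(t)
        assert np.allclose(smooth_timecourse(t, y, p=1.0), y, atol=1e-8)

    def test_p0_is_least_squares_line(self):
        t = np.arange(8.0)
        y = np.array([0, 1, 0.5, 2, 1.5, 3, 2.5, 4])
        line = np.polyval(np.polyfit(t, y, 1), t)
        assert np.allclose(smooth_timecourse(t, y, p=0.0), line, atol=1e-8)

    def test_default_smoothing_reduces_noise_variance(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 24, 25)
        clean = np.sin(2 * np.pi * t / 24)
        noisy = clean + rng.normal(0, 0.3, len(t))
        smoothed = smooth_timecourse(t, noisy)
        assert np.var(smoothed - clean) < np.var(noisy - clean)


class TestQpcrArithmetic:
    @pytest.mark.parametrize(
        "ddct,expected", [(0.0, 1.0), (-1.0, 2.0), (3.32, 2 ** -3.32)]
    )
    def test_relative_quantity(self, ddct, expected):
        assert relative_quantity(ddct) == pytest.approx(expected)

    def test_normalize_identity_and_self(self):
        target = pd.Series([2.0, 3.0, 4.0], index=["a", "b", "c"])
        ones = pd.Series(1.0, index=["a", "b", "c"])
        assert normalize_to_reference(target, ones).tolist() == [2.0, 3.0, 4.0]
        assert normalize_to_reference(target, target).tolist() == [1.0, 1.0, 1.0]

    def test_normalize_drops_zero_reference_samples(self):
        target = pd.Series([2.0, 3.0, 4.0], index=["a", "b", "c"])
        ref = pd.Series([1.0, 0.0, 2.0], index=["a", "b", "c"])
        out = normalize_to_reference(target, ref)
        assert list(out.index) == ["a", "c"]
        assert out["c"] == pytest.approx(2.0)
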