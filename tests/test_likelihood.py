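"""Likelihood objective, Latin-hypercube sampling and multi-start fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isgdyn as isg
from isgdyn.experiments import free_parameter_sets, FITTED_OBSERVABLES
from isgdyn.likelihood import (
    TimecourseDataset,
    _Objective,
    latin_hypercube_starts,
    multistart_fit,
    neg2_log_likelihood,
)
from isgdyn.model import ConfigurationError
from isgdyn.synth import GeneratorConfig, generate_timecourse


@pytest.fixture(scope="module")
def clean_data(model_fb, ref_params_fb):
    cfg = GeneratorConfig(seed=0, noise_fraction=0.0, n_replicates=1)
    data, truth = generate_timecourse(model_fb, cfg, observables=["mIRF1", "mSOCS1"])
    return data, truth


class TestObjective:
    def test_zero_residuals_give_n_log_2pi(self, model_fb, ref_params_fb, clean_data):
        data, _ = clean_data
        params = ref_params_fb.updated(sd_mIRF1=1.0, sd_mSOCS1=1.0)
        val = neg2_log_likelihood(model_fb, params, data)
        assert val == pytest.approx(len(data) * np.log(2 * np.pi), rel=1e-6)

    def test_matches_brute_force_summation(self, model_fb, ref_params_fb):
        # independent oracle: simulate, then sum the Gaussian -2 log L terms
        # point by point without any of the objective's bookkeeping
        cfg = GeneratorConfig(seed=3, n_replicates=2)
        data, _ = generate_timecourse(model_fb, cfg, observables=["mIRF1", "mMX1"])
        params = ref_params_fb
        val = neg2_log_likelihood(model_fb, params, data)
        times = np.array(sorted(data.frame["time_h"].unique()))
        traj = isg.simulate(model_fb, params, 500.0, times,
                            rtol=1e-10, atol=1e-12)
        expected = 0.0
        for _, row in data.frame.iterrows():
            obs = model_fb.observable(row["observable"])
            yhat = params.values[obs.scale_parameter] * sum(
                traj[s][list(times).index(row["time_h"])] for s in obs.species
            )
            sd = params.values[obs.noise_parameter]
            expected += (row["value"] - yhat) ** 2 / sd**2 + np.log(2 * np.pi * sd**2)
        assert val == pytest.approx(expected, rel=1e-4)

    def test_ten_sigma_outlier_adds_about_100(self, model_fb, ref_params_fb, clean_data):
        data, _ = clean_data
        params = ref_params_fb
        base = neg2_log_likelihood(model_fb, params, data)
        bumped = data.frame.copy()
        sd = params.values["sd_mIRF1"]
        idx = bumped[bumped["observable"] == "mIRF1"].index[3]
        bumped.loc[idx, "value"] += 10 * sd
        val = neg2_log_likelihood(model_fb, params, TimecourseDataset(bumped))
        assert val - base == pytest.approx(100.0, rel=1e-3)

    def test_common_rescaling_shifts_objective_by_2n_log_c(
        self, model_fb, ref_params_fb, clean_data
    ):
        # scaling data, observable scale and noise sd by c is a unit change;
        # -2 log L moves by exactly the Jacobian term 2 N log c
        data, _ = clean_data
        c = 3.7
        params = ref_params_fb
        base = neg2_log_likelihood(model_fb, params, data)
        scaled_frame = data.frame.copy()
        scaled_frame["value"] *= c
        scaled = TimecourseDataset(scaled_frame)
        params_c = params.updated(
            s_mIRF1=c * params.values["s_mIRF1"],
            s_mSOCS1=c * params.values["s_mSOCS1"],
            sd_mIRF1=c * params.values["sd_mIRF1"],
            sd_mSOCS1=c * params.values["sd_mSOCS1"],
        )
        val = neg2_log_likelihood(model_fb, params_c, scaled)
        assert val - base == pytest.approx(2 * len(data) * np.log(c), rel=1e-6)

    def test_unknown_observable_rejected(self, model_fb, ref_params_fb, clean_data):
        data, _ = clean_data
        bad = data.frame.copy()
        bad.loc[0, "observable"] = "pSTAT9"
        with pytest.raises(ValueError, match="pSTAT9"):
            neg2_log_likelihood(model_fb, ref_params_fb, TimecourseDataset(bad))


class TestLatinHypercube:
    def test_strata_occupied_once_per_parameter(self):
        draws = latin_hypercube_starts(10, [(1e-6, 1.0)], seed=0)
        bins = np.floor((np.log10(draws[:, 0]) + 6.0) / 0.6).astype(int)
        assert sorted(bins) == list(range(10))

    def test_same_seed_reproduces_matrix(self):
        a = latin_hypercube_starts(25, [(1e-6, 1.0), (1e-3, 1e2)], seed=42)
        b = latin_hypercube_starts(25, [(1e-6, 1.0), (1e-3, 1e2)], seed=42)
        assert np.array_equal(a, b)

    def test_marginal_uniform_in_log10(self):
        draws = latin_hypercube_starts(1000, [(1e-6, 1.0)], seed=1)
        u = (np.log10(draws[:, 0]) + 6.0) / 6.0
        ks = stats.kstest(u, "uniform").statistic
        assert ks < 0.05

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            latin_hypercube_starts(5, [(1.0, 1.0)], seed=0)
        with pytest.raises(ConfigurationError):
            latin_hypercube_starts(0, [(1e-6, 1.0)], seed=0)


class TestMultistartFit:
    @pytest.fixture(scope="class")
    def small_problem(self, model_fb, ref_params_fb):
        cfg = GeneratorConfig(seed=5, noise_fraction=0.10)
        data, truth = generate_timecourse(
            model_fb, cfg, observables=["mIRF1", "mSOCS1"]
        )
        template = ref_params_fb.fixing(
            all_except=["vmax_mIRF1", "vmax_mSOCS1", "sd_mIRF1", "sd_mSOCS1"]
        )
        return data, truth, template

    def test_best_objective_not_worse_than_truth(self, model_fb, small_problem):
        data, truth, template = small_problem
        sigmas = truth["sigmas"]
        at_truth = template.updated(
            sd_mIRF1=sigmas["mIRF1"], sd_mSOCS1=sigmas["mSOCS1"]
        )
        fit = multistart_fit(model_fb, data, template, n_starts=4, seed=1)
        assert fit.best_objective <= neg2_log_likelihood(model_fb, at_truth, data) + 1e-6

    def test_waterfall_sorted_and_headed_by_best(self, model_fb, small_problem):
        data, _, template = small_problem
        fit = multistart_fit(model_fb, data, template, n_starts=4, seed=2)
        assert np.all(np.diff(fit.waterfall) >= 0)
        assert fit.best_objective == fit.waterfall[0]
        assert fit.n_converged_to_best >= 1

    def test_same_seed_bit_reproducible(self, model_fb, small_problem):
        data, _, template = small_problem
        a = multistart_fit(model_fb, data, template, n_starts=2, seed=3)
        b = multistart_fit(model_fb, data, template, n_starts=2, seed=3)
        assert np.array_equal(a.waterfall, b.waterfall)
        assert a.best_params.values == b.best_params.values

    def test_fitted_noise_sd_recovers_injected_sigma(self, model_fb, small_problem):
        data, truth, template = small_problem
        fit = multistart_fit(model_fb, data, template, n_starts=3, seed=4)
        sigma_true = truth["sigmas"]["mIRF1"]
        assert 0.7 * sigma_true <= fit.best_params.values["sd_mIRF1"] <= 1.4 * sigma_true

    def test_fixed_parameters_untouched(self, model_fb, small_problem, ref_params_fb):
        data, _, template = small_problem
        fit = multistart_fit(model_fb, data, template, n_starts=2, seed=6)
        for name, v in fit.best_params.values.items():
            if not template.free[name]:
                assert v == template.values[name]

    def test_single_start_rejected(self, model_fb, small_problem):
        data, _, template = small_problem
        with pytest.raises(ConfigurationError):
            multistart_fit(model_fb, data, template, n_starts=1, seed=0)
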