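"""Binning, the G-squared objective and the two-stage Nelder-Mead fit."""

import numpy as np
import pandas as pd
import pytest

from flankerssp.fitting import (
    BinnedProportions,
    BinScheme,
    FitSettings,
    binned_bic,
    fit_participant,
    g_squared,
    make_bin_scheme,
    observed_proportions,
    predicted_proportions,
)
from flankerssp.model import SSPParameters
from flankerssp.simulate import SimulationSettings

TINY_FIT = FitSettings(
    stage1_maxfev=40,
    stage2_maxfev=80,
    sim=SimulationSettings(n_sim_trials=500, max_decision_time=1.5),
)


def two_condition_frame(cong, incong):
    rows = []
    for condition, (rts, accs) in (("congruent", cong), ("incongruent", incong)):
        rows.append(pd.DataFrame({"condition": condition, "rt": rts, "accuracy": accs}))
    return pd.concat(rows, ignore_index=True)


class TestBinScheme:
    def test_quantile_edges_from_uniform_rts(self):
        rts = np.linspace(300.5, 399.5, 100)  # order-statistics oracle
        df = two_condition_frame((rts, np.ones(100)), (rts, np.ones(100)))
        scheme = make_bin_scheme(df)
        assert np.allclose(scheme.correct_edges["congruent"], [310, 330, 350, 370, 390], atol=1.0)

    def test_no_errors_collapse_to_single_error_bin(self):
        rts = np.linspace(300, 400, 50)
        df = two_condition_frame((rts, np.ones(50)), (rts, np.ones(50)))
        scheme = make_bin_scheme(df)
        assert scheme.error_edges["congruent"] is None
        obs = observed_proportions(df, scheme)
        assert obs.observed["congruent"][-1] == 0.0  # pooled error bin empty

    def test_five_cuts_make_six_correct_bins(self):
        rts = np.linspace(300, 400, 50)
        df = two_condition_frame((rts, np.ones(50)), (rts, np.ones(50)))
        scheme = make_bin_scheme(df)
        assert scheme.n_bins("congruent") == 6 + 1

    def test_plentiful_errors_get_quantile_bins(self):
        rng = np.random.default_rng(0)
        rts = rng.uniform(300, 500, 60)
        acc = np.r_[np.zeros(20), np.ones(40)]
        df = two_condition_frame((rts, acc), (rts, acc))
        scheme = make_bin_scheme(df, min_error_count=11)
        assert scheme.error_edges["congruent"] is not None
        assert scheme.n_bins("congruent") == 12

    def test_condition_without_correct_trials_rejected(self):
        df = two_condition_frame(
            (np.array([300.0, 310.0]), np.array([1, 1])),
            (np.array([300.0, 310.0]), np.array([0, 0])),
        )
        with pytest.raises(ValueError, match="incongruent"):
            make_bin_scheme(df)

    def test_invalid_quantiles_rejected(self):
        with pytest.raises(ValueError):
            BinScheme(quantiles=(0.5, 0.3), correct_edges={}, error_edges={})


class TestGSquared:
    def test_zero_at_identity(self):
        bp = BinnedProportions(
            observed={"congruent": np.array([0.6, 0.4])},
            n={"congruent": 10},
            predicted={"congruent": np.array([0.6, 0.4])},
        )
        assert g_squared(bp) == pytest.approx(0.0, abs=1e-14)

    def test_two_bin_value_matches_direct_formula(self):
        bp = BinnedProportions(
            observed={"congruent": np.array([0.6, 0.4])},
            n={"congruent": 10},
            predicted={"congruent": np.array([0.5, 0.5])},
        )
        direct = 2 * 10 * (0.6 * np.log(0.6 / 0.5) + 0.4 * np.log(0.4 / 0.5))
        assert g_squared(bp) == pytest.approx(direct, abs=1e-10)
        assert g_squared(bp) == pytest.approx(0.4027, abs=2e-4)

    def test_independent_loglikelihood_ratio_oracle(self):
        # oracle: multinomial log-likelihood ratio 2*(ll_sat - ll_model)
        rng = np.random.default_rng(4)
        counts = np.array([17.0, 40.0, 23.0, 20.0])
        pred = rng.dirichlet(np.ones(4))
        obs = counts / counts.sum()
        bp = BinnedProportions(
            observed={"incongruent": obs}, n={"incongruent": int(counts.sum())},
            predicted={"incongruent": pred},
        )
        ll_sat = np.sum(counts * np.log(obs))
        ll_model = np.sum(counts * np.log(pred))
        assert g_squared(bp) == pytest.approx(2 * (ll_sat - ll_model), abs=1e-10)

    def test_linear_in_trial_count(self):
        obs = {"congruent": np.array([0.7, 0.3])}
        pred = {"congruent": np.array([0.5, 0.5])}
        g1 = g_squared(BinnedProportions(observed=obs, n={"congruent": 10}, predicted=pred))
        g3 = g_squared(BinnedProportions(observed=obs, n={"congruent": 30}, predicted=pred))
        assert g3 == pytest.approx(3 * g1, rel=1e-12)

    def test_empty_observed_bins_contribute_nothing(self):
        bp = BinnedProportions(
            observed={"congruent": np.array([1.0, 0.0])},
            n={"congruent": 5},
            predicted={"congruent": np.array([0.5, 0.5])},
        )
        assert np.isfinite(g_squared(bp))

    def test_unsmoothed_zero_prediction_raises(self):
        bp = BinnedProportions(
            observed={"congruent": np.array([0.5, 0.5])},
            n={"congruent": 5},
            predicted={"congruent": np.array([1.0, 0.0])},
        )
        with pytest.raises(ValueError, match="smoothing"):
            g_squared(bp)


class TestBinnedBic:
    def test_arithmetic(self):
        assert binned_bic(100.0, 5, 384) == pytest.approx(100 + 5 * np.log(384), abs=1e-9)
        assert binned_bic(100.0, 5, 384) == pytest.approx(129.75, abs=0.01)

    def test_zero_parameters_passes_through(self):
        assert binned_bic(7.5, 0, 1000) == 7.5

    def test_penalty_monotone_in_n(self):
        assert binned_bic(10, 5, 500) > binned_bic(10, 5, 400)


class TestPredictedProportions:
    def test_deterministic_under_common_random_numbers(self, reference_params, reference_trials):
        scheme = make_bin_scheme(reference_trials)
        settings = SimulationSettings(n_sim_trials=800, max_decision_time=1.5)
        noise = np.random.default_rng(5).standard_normal((800, settings.n_steps))
        p1 = predicted_proportions(reference_params, scheme, settings, noise=noise)
        p2 = predicted_proportions(reference_params, scheme, settings, noise=noise)
        for condition in p1:
            assert np.array_equal(p1[condition], p2[condition])
            assert p1[condition].sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p1[condition] > 0)

    def test_true_parameters_fit_better_than_perturbed(self, reference_params, reference_trials):
        scheme = make_bin_scheme(reference_trials)
        obs = observed_proportions(reference_trials, scheme)
        settings = SimulationSettings(n_sim_trials=4000, max_decision_time=2.0)
        noise = np.random.default_rng(6).standard_normal((4000, settings.n_steps))

        def g_at(params):
            bp = BinnedProportions(observed=obs.observed, n=obs.n)
            bp.predicted = predicted_proportions(params, scheme, settings, noise=noise)
            return g_squared(bp)

        perturbed = reference_params.replace(
            a=reference_params.a * 1.5, p=reference_params.p * 0.5
        )
        assert g_at(reference_params) < g_at(perturbed)


class TestFitParticipant:
    def test_fit_is_deterministic_given_seed(self, reference_trials):
        f1 = fit_participant(reference_trials, fit_settings=TINY_FIT, seed=3)
        f2 = fit_participant(reference_trials, fit_settings=TINY_FIT, seed=3)
        assert f1.params == f2.params
        assert f1.g2 == f2.g2

    def test_stage_two_refines_stage_one(self, reference_trials):
        fr = fit_participant(reference_trials, fit_settings=TINY_FIT, seed=4)
        assert fr.g2 <= fr.stage1_g2
        assert fr.g2 >= 0
        assert fr.interference_time == pytest.approx(fr.params.sd_a / fr.params.rd)
        assert fr.bic == pytest.approx(binned_bic(fr.g2, 5, len(reference_trials)))

    def test_non_decision_time_capped_below_fastest_response(self, reference_trials):
        fr = fit_participant(reference_trials, fit_settings=TINY_FIT, seed=5)
        assert fr.params.ter < reference_trials["rt"].min() / 1000.0
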