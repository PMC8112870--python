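"""Likelihood fitting, split protocol, comparison, logistic interactions."""

import numpy as np
import pandas as pd
import pytest

from multidec.fit_compare import (
    double_decision_negloglik,
    fit_mle,
    interaction_logistic_bic,
    log10_bayes_factor,
    make_strongest_split,
    pack_params,
    split_fit_predict,
    unpack_params,
)
from multidec.synthetic_data import DesignGrid, generate_design, simulate_trials


@pytest.fixture(scope="module")
def serial_trials(serial_gen_params, small_design):
    return simulate_trials("serial", serial_gen_params, small_design, n=150, seed=13)


@pytest.fixture(scope="module")
def x_true(serial_gen_params):
    return pack_params(
        serial_gen_params["motion"], serial_gen_params["color"], serial_gen_params["nd"]
    )


class TestNegLogLik:
    def test_true_params_beat_perturbed(self, serial_trials, serial_gen_params):
        nll_true = double_decision_negloglik(serial_trials, serial_gen_params, "serial")
        pert = unpack_params(
            pack_params(**serial_gen_params) * np.array([1.5] + [1.0] * 11)
        )
        nll_pert = double_decision_negloglik(serial_trials, pert, "serial")
        assert nll_true < nll_pert

    def test_duplication_doubles_nll(self, serial_trials, serial_gen_params):
        doubled = pd.concat([serial_trials, serial_trials], ignore_index=True)
        one = double_decision_negloglik(serial_trials, serial_gen_params, "serial")
        two = double_decision_negloglik(doubled, serial_gen_params, "serial")
        assert two == pytest.approx(2 * one, rel=1e-9)

    def test_truth_is_neighborhood_minimum(self, serial_trials, serial_gen_params, x_true):
        """The NLL at the generating vector beats sizeable perturbations
        along each parameter axis (gradient-free neighborhood check)."""
        nll_true = double_decision_negloglik(serial_trials, serial_gen_params, "serial")
        for i in (0, 2, 5, 7, 10, 11):  # kappas, bound heights, nd params
            step = 0.3 * abs(x_true[i]) + 0.05
            for sign in (+1, -1):
                vec = x_true.copy()
                vec[i] += sign * step
                if vec[i] <= 0:
                    continue
                nll = double_decision_negloglik(
                    serial_trials, unpack_params(vec), "serial"
                )
                assert nll > nll_true, f"param {i} perturbed by {sign * step}"

    def test_generating_rule_scores_better(self, serial_trials, serial_gen_params):
        nll_s = double_decision_negloglik(serial_trials, serial_gen_params, "serial")
        nll_p = double_decision_negloglik(serial_trials, serial_gen_params, "parallel")
        assert nll_s < nll_p


class TestSplit:
    def test_9x9_split_counts(self):
        five = (0, 0.032, 0.064, 0.128, 0.256)
        conds = generate_design(DesignGrid(five, five))
        trials = conds.assign(R_m=1, R_c=1, rt=1.0)
        split = make_strongest_split(trials)
        assert len(split.fit_conditions) == 32
        assert len(split.predict_conditions) == 49

    def test_11x11_split_counts(self):
        six = (0, 0.032, 0.064, 0.128, 0.256, 0.512)
        conds = generate_design(DesignGrid(six, six))
        trials = conds.assign(R_m=1, R_c=1, rt=1.0)
        split = make_strongest_split(trials)
        assert len(split.fit_conditions) == 40
        assert len(split.predict_conditions) == 81

    def test_single_level_design_has_no_split(self):
        conds = generate_design(DesignGrid((0.2,), (0.3,)))
        trials = conds.assign(R_m=1, R_c=1, rt=1.0)
        with pytest.raises(ValueError):
            make_strongest_split(trials)


class TestFitAndCompare:
    def test_warm_started_fit_recovers_nll(self, serial_trials, serial_gen_params, x_true):
        fit = fit_mle(serial_trials, "serial", seed=0, n_starts=1, x0=x_true, maxfev=80)
        nll_true = double_decision_negloglik(serial_trials, serial_gen_params, "serial")
        assert fit.nll <= nll_true + 1e-6

    def test_identical_fits_give_zero_bf(self, serial_trials, x_true):
        a = fit_mle(serial_trials, "serial", seed=0, n_starts=1, x0=x_true, maxfev=30)
        b = fit_mle(serial_trials, "serial", seed=0, n_starts=1, x0=x_true, maxfev=30)
        b.rule = "parallel"  # same likelihoods, labelled as the other rule
        assert log10_bayes_factor(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_data_rejected(self, serial_trials, serial_gen_params, x_true, small_design):
        other = simulate_trials("serial", serial_gen_params, small_design, n=150, seed=99)
        a = fit_mle(serial_trials, "serial", seed=0, n_starts=1, x0=x_true, maxfev=20)
        b = fit_mle(other, "parallel", seed=0, n_starts=1, x0=x_true, maxfev=20)
        with pytest.raises(ValueError):
            log10_bayes_factor(a, b)

    def test_split_fit_predict_holdout(self, serial_gen_params, x_true):
        grid = DesignGrid((0.064, 0.512), (0.064, 0.472))
        trials = simulate_trials("serial", serial_gen_params, grid, n=120, seed=21)
        fit = split_fit_predict(trials, "serial", seed=0, n_starts=1, x0=x_true, maxfev=60)
        assert fit.holdout_nll is not None
        assert fit.holdout_n == (trials.groupby(["s_m", "s_c"]).ngroups - 12) * 120
        # held-out likelihood per trial does not beat training per trial
        assert fit.holdout_nll / fit.holdout_n >= fit.nll / fit.n_trials - 0.05

    def test_too_few_trials_rejected(self, serial_trials):
        with pytest.raises(ValueError):
            fit_mle(serial_trials.head(10), "serial")


def _simulate_logistic_2d(beta3, n, seed):
    rng = np.random.default_rng(seed)
    s = rng.choice([-0.5, -0.25, -0.1, 0.1, 0.25, 0.5], size=n)
    other = rng.choice([0.1, 0.3, 0.6], size=n)
    logit = 0.2 + 6.0 * s + 0.1 * other + beta3 * s * other
    p = 1 / (1 + np.exp(-logit))
    r = np.where(rng.random(n) < p, 1, -1)
    return pd.DataFrame(
        {"subject": "s1", "s_m": s, "s_c": other, "R_m": r, "R_c": 1}
    )


class TestLogisticInteraction:
    def test_no_interaction_favors_reduced_model(self):
        """With beta3 = 0 the BIC penalty should reject the interaction
        term in at least 90% of replicates."""
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            trials = _simulate_logistic_2d(0.0, 1500, seed=rep)
            res = interaction_logistic_bic(trials, "motion")
            wins += res.delta_bic > 0
        assert wins >= 0.9 * n_rep

    def test_large_interaction_favors_full_model(self):
        trials = _simulate_logistic_2d(12.0, 4000, seed=1)
        res = interaction_logistic_bic(trials, "motion")
        assert res.delta_bic < 0

    def test_intercept_only_recovery(self):
        rng = np.random.default_rng(3)
        n = 4000
        p = 1 / (1 + np.exp(-0.8))
        trials = pd.DataFrame(
            {
                "subject": "s1",
                "s_m": np.zeros(n),
                "s_c": np.zeros(n),
                "R_m": np.where(rng.random(n) < p, 1, -1),
                "R_c": 1,
            }
        )
        res = interaction_logistic_bic(trials, "motion")
        assert res.coef_full[0] == pytest.approx(0.8, abs=0.15)

    def test_task_variant_requires_task_column(self):
        trials = _simulate_logistic_2d(0.0, 200, seed=5)
        with pytest.raises(ValueError):
            interaction_logistic_bic(trials, "motion", variant="task")
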