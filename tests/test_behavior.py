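"""Stay/shift table construction, regressions, simple slopes, ASI-X scoring, power."""

import numpy as np
import pandas as pd
import pytest

import lossvol as lv
from lossvol.behavior import (
    PowerConfig,
    RegressionResult,
    _simulate_power_cohort,
    _POWER_TERMS,
    build_stay_table,
    fit_mixed_logistic,
    fit_parameter_regression,
    power_simulation,
    score_asix,
    simple_slopes,
)
from lossvol.mixedlogit import fit_mixed_logit
from lossvol.task import SubjectDataset, TrialSchedule


class TestScoreAsix:
    def test_sum_and_transform(self):
        records = pd.DataFrame(
            {"alcohol": [0, 1, 2, 4], "cannabis": [0, 0, 2, 5]},
            index=["a", "b", "c", "d"],
        )
        total, z = score_asix(records)
        np.testing.assert_array_equal(total.to_numpy(), [0, 1, 4, 9])
        # sqrt -> {0,1,2,3}; z-scored with sample SD
        np.testing.assert_allclose(
            z.to_numpy(), [-1.1619, -0.3873, 0.3873, 1.1619], atol=1e-4
        )

    def test_transform_order_is_sqrt_then_z(self):
        base = pd.DataFrame({"s": [0.0, 1.0, 4.0, 9.0]})
        shifted = base + 4.0
        _, z0 = score_asix(base)
        _, z1 = score_asix(shifted)
        # a constant shift in years changes the z-scores non-linearly
        assert not np.allclose(np.diff(z0), np.diff(z1))

    def test_negative_years_rejected(self):
        with pytest.raises(ValueError):
            score_asix(pd.DataFrame({"s": [-1.0, 2.0]}))


def _toy_dataset(subject_id, choices, correct, context=None, mags=None):
    n = len(choices)
    choices = np.asarray(choices)
    correct = np.asarray(correct)
    context = np.array(["stable"] * n) if context is None else np.asarray(context)
    m1 = np.full(n, 2.0) if mags is None else np.asarray(mags[0], dtype=float)
    m2 = np.full(n, 3.0) if mags is None else np.asarray(mags[1], dtype=float)
    sched = TrialSchedule(
        context=context, p_loss_card1=np.full(n, 0.75), mag_card1=m1, mag_card2=m2,
        correct_card=correct, block_order="stable_first",
    )
    outcome = (choices != correct).astype(int)
    chosen = np.where(choices == 1, m1, m2)
    return SubjectDataset(subject_id, sched, choices, outcome,
                          np.where(outcome == 1, chosen, 0.0))


def _toy_covariates(subject_ids):
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": np.linspace(25, 45, len(subject_ids)),
            "randomization": ["stable_first"] * len(subject_ids),
            "asix_z": np.linspace(-1, 1, len(subject_ids)),
        }
    )


class TestStayTable:
    def test_definition_unrolled(self):
        ds = _toy_dataset("a", [1, 1, 2, 2], [2, 1, 1, 2])
        other = _toy_dataset("b", [1, 2, 1, 2], [1, 1, 2, 2])
        table = build_stay_table([ds, other], _toy_covariates(["a", "b"]))
        rows = table[table.subject_id == "a"]
        np.testing.assert_array_equal(rows["trial"], [2, 3, 4])
        np.testing.assert_array_equal(rows["stay"], [1, 0, 1])
        # outcomes were [incurred, avoided, incurred, avoided]
        np.testing.assert_array_equal(rows["prev_outcome"], [1, 0, 1])

    def test_constant_chooser_always_stays(self):
        ds = _toy_dataset("a", [1] * 6, [1, 2, 1, 1, 2, 1])
        table = build_stay_table([ds, ds], _toy_covariates(["a", "a"]))
        assert (table["stay"] == 1).all()

    def test_block_boundaries_excluded(self, small_cohort):
        datasets, cov = small_cohort
        table = build_stay_table(datasets, cov)
        assert len(table) == len(datasets) * 198
        assert not (table["trial"] == 1).any()
        assert not (table["trial"] == 101).any()

    def test_centering(self, small_cohort):
        datasets, cov = small_cohort
        table = build_stay_table(datasets, cov)
        assert table["lmd_c"].mean() == pytest.approx(0.0, abs=1e-9)


class TestSimpleSlopes:
    def test_closed_form_linear_combination(self):
        cov = np.array([[0.04, 0.01, -0.005], [0.01, 0.09, 0.002], [-0.005, 0.002, 0.0025]])
        res = RegressionResult(
            terms=["x", "m", "x:m"], estimate=np.array([0.5, -0.2, 0.3]),
            se=np.sqrt(np.diag(cov)), statistic=np.zeros(3), pvalues=np.ones(3),
            conf_int=np.zeros((3, 2)), cov=cov, formula="y ~ x*m", kind="ols",
            n_obs=100, n_subjects=100,
        )
        slopes = simple_slopes(res, "x", "m", levels=[0.0, 1.0, -1.0])
        np.testing.assert_allclose(slopes["slope"], [0.5, 0.8, 0.2], atol=1e-12)
        for lev, se in zip(slopes["level"], slopes["se"]):
            c = np.array([1.0, 0.0, lev])
            np.testing.assert_allclose(se, np.sqrt(c @ cov @ c), atol=1e-12)

    def test_zero_interaction_gives_main_effect(self):
        cov = np.eye(3) * 0.01
        res = RegressionResult(
            terms=["x", "m", "x:m"], estimate=np.array([0.4, 0.1, 0.0]),
            se=np.zeros(3), statistic=np.zeros(3), pvalues=np.ones(3),
            conf_int=np.zeros((3, 2)), cov=cov, formula="y ~ x*m", kind="ols",
            n_obs=10, n_subjects=10,
        )
        slopes = simple_slopes(res, "x", "m", levels=[0, 1])
        assert (slopes["slope"] == 0.4).all()

    def test_missing_term_errors(self):
        res = RegressionResult(
            terms=["x"], estimate=np.zeros(1), se=np.zeros(1), statistic=np.zeros(1),
            pvalues=np.ones(1), conf_int=np.zeros((1, 2)), cov=np.eye(1),
            formula="", kind="ols", n_obs=1, n_subjects=1,
        )
        with pytest.raises(KeyError):
            simple_slopes(res, "x", "m", levels=[0])


class TestParameterRegression:
    def test_permuted_covariate_has_null_effect(self, small_cohort, rng):
        _, cov = small_cohort
        df = cov.copy()
        df["omega"] = rng.normal(size=len(df))          # unrelated outcome
        res = fit_parameter_regression(df, "omega")
        assert abs(res["asix_z"]) < 1.5
        assert res.pvalues[res.terms.index("asix_z")] > 1e-3

    def test_rank_deficiency_reported(self, small_cohort):
        _, cov = small_cohort
        df = cov.copy()
        df["omega"] = 1.0 * df["asix_z"]
        df["asix_z"] = 0.0                               # constant predictor
        with pytest.raises(ValueError, match="rank"):
            fit_parameter_regression(df, "omega")


class TestMixedLogisticRegression:
    def test_toy_interaction_recovery_with_coverage(self):
        """Simulated previous-outcome x ASI-X interactions are recovered
        within +-2 SE in most replicates (scaled-down Monte Carlo)."""
        cfg = PowerConfig(trials_per_subject=60, re_slope_sd=0.4)
        rng = np.random.default_rng(99)
        j = _POWER_TERMS.index("prev:asix")
        hits = 0
        reps = 25
        for _ in range(reps):
            y, X, g, prev = _simulate_power_cohort(60, 0.3, cfg, rng)
            res = fit_mixed_logit(y, X, g, names=_POWER_TERMS, slope=prev,
                                  start_sd=(0.8, 0.4))
            hits += abs(res.beta[j] - 0.3) <= 2 * res.se[j]
        assert hits / reps >= 0.8

    def test_requires_two_subjects(self):
        ds = _toy_dataset("a", [1, 2, 1, 2], [1, 1, 2, 2])
        table = build_stay_table([ds], _toy_covariates(["a"]))
        with pytest.raises(ValueError):
            fit_mixed_logistic(table, "eq1")


class TestPower:
    def test_null_calibration(self):
        cfg = PowerConfig(trials_per_subject=60)
        res = power_simulation(0.0, n_subjects=40, n_replicates=60, seed=17, config=cfg)
        assert res["power"] <= 0.15

    def test_monotone_in_effect_size(self):
        cfg = PowerConfig(trials_per_subject=60)
        powers = [
            power_simulation(e, n_subjects=40, n_replicates=50, seed=23, config=cfg)["power"]
            for e in (0.0, 0.45, 1.5)
        ]
        assert powers[0] <= powers[1] + 0.15
        assert powers[1] <= powers[2] + 0.10
        assert powers[2] > 0.9

    def test_monotone_in_sample_size(self):
        cfg = PowerConfig(trials_per_subject=60)
        powers = [
            power_simulation(0.5, n_subjects=n, n_replicates=50, seed=29, config=cfg)["power"]
            for n in (12, 35, 90)
        ]
        assert powers[0] <= powers[1] + 0.15
        assert powers[1] <= powers[2] + 0.15

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(0.2, n_replicates=10)
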