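"""Synthetic-trial generation: predictors, outcomes, calibration, determinism."""

import numpy as np
import pytest
from dataclasses import replace

from zicount import (
    GenerativeModel,
    calibrate_intercepts,
    draw_predictors,
    make_generative_model,
    nb_zero_prob,
    replicate_rng,
    simulate_dataset,
    simulate_outcome,
    zinb_moments,
)
from zicount.synthetic import PredictorRanges


class TestDrawPredictors:
    def test_determinism(self):
        df1, h1 = draw_predictors(422, np.random.default_rng(3))
        df2, h2 = draw_predictors(422, np.random.default_rng(3))
        assert df1.equals(df2) and h1 == h2

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="60"):
            draw_predictors(59, np.random.default_rng(0))

    def test_treated_fraction_concentrates(self):
        df, h = draw_predictors(422, np.random.default_rng(11))
        sd = np.sqrt(h.treatment_prob * (1 - h.treatment_prob) / 422)
        assert abs(df["treatment"].mean() - h.treatment_prob) < 5 * sd
        assert 0.45 <= h.treatment_prob <= 0.55

    def test_risk_dummies_one_hot(self):
        df, _ = draw_predictors(500, np.random.default_rng(4))
        assert not np.any((df["risk2"] == 1) & (df["risk3"] == 1))
        # rows with neither dummy are reference risk level 1, and all three
        # levels appear at these probabilities
        assert ((df["risk2"] == 0) & (df["risk3"] == 0)).sum() > 0
        assert df["risk2"].sum() > 0 and df["risk3"].sum() > 0

    def test_age_within_bounds_and_dichotomized(self):
        df, h = draw_predictors(400, np.random.default_rng(9))
        assert df["age"].between(*h.age_bounds).all()
        assert (df["age_ge2"] == (df["age"] >= 2).astype(int)).all()


class TestSimulateOutcome:
    def test_nb_zero_fraction_closed_form(self):
        # constant m = 0.5, r = 0.36 (the observed marginal MLEs) implies
        # P(zero) = (r/(r+m))^r = 0.731, matching the ~72.75% observed zeros
        model = GenerativeModel(
            family="nb",
            outcome_label="serious_illness",
            count_coefficients=(np.log(0.5), 0.0, 0.0, 0.0, 0.0),
            dispersion_r=0.36,
        )
        df, _ = draw_predictors(10**5, np.random.default_rng(0))
        y = simulate_outcome(model, df, np.random.default_rng(1))
        p0 = nb_zero_prob(0.5, 0.36)
        assert p0 == pytest.approx(0.731, abs=5e-4)
        se = np.sqrt(p0 * (1 - p0) / y.size)
        assert abs(np.mean(y == 0) - p0) < 3 * se

    def test_zinb_mean_matches_moment_formula(self):
        model = GenerativeModel(
            family="zinb",
            outcome_label="serious_illness",
            count_coefficients=(0.0, 0.0, 0.0, 0.0, 0.0),
            logit_coefficients=(-1.0, 0.0),
            dispersion_r=0.5,
        )
        n = 10**6
        df, _ = draw_predictors(n, np.random.default_rng(2))
        y = simulate_outcome(model, df, np.random.default_rng(3))
        p = 1 / (1 + np.exp(1.0))
        mean, var = zinb_moments(p, 1.0, 0.5)
        assert abs(y.mean() - mean) < 3 * np.sqrt(var / n)

    def test_deeply_negative_logit_equals_nb(self):
        nb = make_generative_model("serious_illness", "nb")
        nb = replace(nb, count_coefficients=(0.5,) + nb.count_coefficients[1:],
                     dispersion_r=0.4)
        zi = GenerativeModel(
            family="zinb",
            outcome_label="serious_illness",
            count_coefficients=nb.count_coefficients,
            logit_coefficients=(-30.0, -30.0),
            dispersion_r=0.4,
        )
        df, _ = draw_predictors(2000, np.random.default_rng(5))
        y_nb = simulate_outcome(nb, df, np.random.default_rng(6))
        y_zi = simulate_outcome(zi, df, np.random.default_rng(6))
        # the structural-zero step consumes one uniform draw, so compare
        # distributions rather than streams
        hi = max(y_nb.max(), y_zi.max())
        c_nb = np.bincount(y_nb, minlength=hi + 1)
        c_zi = np.bincount(y_zi, minlength=hi + 1)
        assert np.abs(c_nb - c_zi).sum() / y_nb.size < 0.02

    def test_overflow_reported(self):
        model = GenerativeModel(
            family="nb",
            outcome_label="serious_illness",
            count_coefficients=(100.0, 0.0, 0.0, 0.0, 0.0),
            dispersion_r=1.0,
        )
        df, _ = draw_predictors(100, np.random.default_rng(0))
        with pytest.raises(OverflowError, match="linear predictor"):
            simulate_outcome(model, df, np.random.default_rng(0))


class TestDatasetDeterminism:
    def test_model_seed_reproduces_dataset(self):
        model = replace(
            make_generative_model("serious_illness", "nb"),
            count_coefficients=(1.0, -0.49, -0.74, -0.74, -1.86),
            dispersion_r=0.5,
        )
        a = simulate_dataset(model, 422, master_seed=77, replicate_id=3)
        b = simulate_dataset(model, 422, master_seed=77, replicate_id=3)
        assert np.array_equal(a.data.outcome, b.data.outcome)
        assert np.array_equal(a.data.count_covariates, b.data.count_covariates)
        c = simulate_dataset(model, 422, master_seed=77, replicate_id=4)
        assert not np.array_equal(a.data.outcome, c.data.outcome)

    def test_replicate_rng_streams_differ(self):
        a = replicate_rng(1, 0).random(4)
        b = replicate_rng(1, 1).random(4)
        assert not np.allclose(a, b)


class TestCalibration:
    def test_identity_case_recovers_zero_intercept(self):
        # all slopes zero, offset zero, target mean 1 -> beta0 = 0 by the log link
        model = GenerativeModel(
            family="nb",
            outcome_label="serious_illness",
            count_coefficients=(5.0, 0.0, 0.0, 0.0, 0.0),
            dispersion_r=1.0,
        )
        cal = calibrate_intercepts(
            model, targets=(1.0, 50.0), rng=np.random.default_rng(0), n_batches=20
        )
        assert cal.count_coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_mean_monotone_in_intercept(self):
        from zicount.synthetic import _expected_profiles, draw_predictors

        model = make_generative_model("serious_illness", "nb")
        rng = np.random.default_rng(1)
        batches = []
        for _ in range(20):
            df, _ = draw_predictors(422, rng)
            batches.append(
                (df[["treatment", "age_ge2", "risk2", "risk3"]].to_numpy(float),
                 df["treatment"].to_numpy(float))
            )
        means = [
            _expected_profiles(model, batches, b0, 0.0)[0] for b0 in (-1.0, 0.0, 1.0, 2.0)
        ]
        assert np.all(np.diff(means) > 0)
        # and the zero fraction falls as the intercept (hence the mean) rises
        zeros = [
            _expected_profiles(model, batches, b0, 0.0)[1] for b0 in (-1.0, 0.0, 1.0, 2.0)
        ]
        assert np.all(np.diff(zeros) < 0)

    def test_zero_fraction_rises_with_logit_intercept(self):
        from zicount.synthetic import _expected_profiles, draw_predictors

        rng = np.random.default_rng(2)
        df, _ = draw_predictors(422, rng)
        batch = [
            (df[["treatment", "age_ge2", "risk2", "risk3"]].to_numpy(float),
             df["treatment"].to_numpy(float))
        ]
        zeros = []
        for g0 in (-4.0, -2.0, 0.0, 2.0):
            model = GenerativeModel(
                family="zinb",
                outcome_label="serious_illness",
                count_coefficients=(0.0, -0.64, -0.74, -0.78, -1.88),
                logit_coefficients=(g0, -15.66),
                dispersion_r=0.5,
            )
            zeros.append(_expected_profiles(model, batch, 0.5, 0.0)[1])
        assert np.all(np.diff(zeros) > 0)

    def test_unattainable_target_reports_closest(self):
        model = make_generative_model("serious_illness", "nb")
        with pytest.raises(ValueError, match="calibration failed"):
            # 5% zeros at mean 0.1 is impossible for any NB dispersion
            calibrate_intercepts(
                model, targets=(0.1, 5.0), rng=np.random.default_rng(0), n_batches=10
            )

    def test_primary_targets_reproduced_across_replicates(self):
        # the headline check: calibrated DD-NB generation puts the median
        # per-replicate zero percentage within 2 points of the 69.9% target
        model = calibrate_intercepts(
            make_generative_model("serious_illness", "nb"),
            rng=np.random.default_rng(42),
        )
        zeros, means = [], []
        for k in range(200):
            ds = simulate_dataset(model, 422, master_seed=99, replicate_id=k)
            zeros.append(100.0 * np.mean(ds.data.outcome == 0))
            means.append(ds.data.outcome.mean())
        assert np.median(zeros) == pytest.approx(69.9, abs=2.0)
        assert np.median(means) == pytest.approx(0.68, abs=0.05)

    @pytest.mark.parametrize("outcome", ["serious_illness", "days_hospital", "care_days"])
    @pytest.mark.parametrize("family", ["nb", "zinb"])
    def test_all_outcomes_calibrate(self, outcome, family):
        model = calibrate_intercepts(
            make_generative_model(outcome, family),
            rng=np.random.default_rng(3),
            n_batches=40,
        )
        assert model.dispersion_r > 0
        # a single large replicate sits near the targets
        from zicount.synthetic import CALIBRATION_TARGETS

        target_mean, target_zero = CALIBRATION_TARGETS[outcome]
        y = simulate_dataset(model, 422, master_seed=1).data.outcome
        assert y.mean() == pytest.approx(target_mean, rel=0.5)
        assert 100 * np.mean(y == 0) == pytest.approx(target_zero, abs=12)

    def test_nb_outcomes_overdispersed(self):
        model = calibrate_intercepts(
            make_generative_model("serious_illness", "nb"),
            rng=np.random.default_rng(42),
        )
        over = 0
        for k in range(50):
            y = simulate_dataset(model, 422, master_seed=5, replicate_id=k).data.outcome
            over += y.var(ddof=1) > y.mean()
        assert over == 50
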