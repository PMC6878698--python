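"""Tests of the logistic model: fitting, prediction, AUC, threshold, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from phsmoke.errors import (
    CalibrationError,
    FittingError,
    StateError,
    ValidationError,
)
from phsmoke.harmonize import DesignMatrix, harmonize_survey
from phsmoke.model import (
    ModelCoefficients,
    SmokingModel,
    SmokingModelResults,
    calibrate_threshold_values,
    compute_auc,
    cross_validate,
)
from phsmoke.synthetic import default_population_spec, generate_survey


def _zero_coefficients(intercept=0.0, tax_slope=0.0):
    from phsmoke.categories import COVARIATE_LEVELS, DEFAULT_REFERENCE_LEVELS

    levels = {
        (cov, lev): 0.0
        for cov, levs in COVARIATE_LEVELS.items()
        for lev in levs
        if lev != DEFAULT_REFERENCE_LEVELS[cov]
    }
    return ModelCoefficients(intercept, tax_slope, levels)


def _reference_records(n=1, tax=0.0):
    return pd.DataFrame(
        {
            "residence": ["City"] * n,
            "race": ["White"] * n,
            "age_bin": ["18-24"] * n,
            "income_bin": ["<$10k"] * n,
            "gen_ma_ch": ["Two spouses/married/with children"] * n,
            "age_dis": ["Age <65 with disability"] * n,
            "tax": [tax] * n,
        }
    )


class TestPrediction:
    def test_all_zero_coefficients_give_half(self):
        res = SmokingModelResults.from_coefficients(_zero_coefficients())
        assert res.predict_proba(_reference_records())[0] == pytest.approx(0.5)

    def test_tax_slope_hand_computation(self):
        # intercept 0, tax slope 1, tax 2 -> logistic(2) = 1/(1+e^-2)
        res = SmokingModelResults.from_coefficients(_zero_coefficients(tax_slope=1.0))
        p = res.predict_proba(_reference_records(tax=2.0))[0]
        assert p == pytest.approx(0.8807970779778823, abs=1e-12)

    def test_log_odds_linear_in_tax(self):
        res = SmokingModelResults.from_coefficients(
            _zero_coefficients(intercept=-0.7, tax_slope=-0.12)
        )
        lp0 = res.linear_predictor(_reference_records(tax=1.0))[0]
        lp1 = res.linear_predictor(_reference_records(tax=2.0))[0]
        assert lp1 - lp0 == pytest.approx(-0.12, abs=1e-12)

    def test_unknown_level_raises_prediction_error(self, fitted):
        from phsmoke.errors import PredictionError

        bad = _reference_records()
        bad.loc[0, "residence"] = "Exurb"
        with pytest.raises(PredictionError):
            fitted.predict_proba(bad)


class TestFitting:
    def test_single_class_outcome_rejected(self, harmonized):
        df = harmonized.copy()
        df["smokes"] = 0
        with pytest.raises(FittingError, match="single class"):
            SmokingModel.from_dataframe(df).fit()

    def test_intercept_only_closed_form(self):
        # prevalence 0.25 -> intercept estimate near log(0.25/0.75)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.binomial(1, 0.25, size=4000))
        X = pd.DataFrame({"const": np.ones(len(y))})
        design = DesignMatrix(X=X, reference_levels={}, y=y)
        model = SmokingModel.__new__(SmokingModel)
        model.design = design
        res = SmokingModel.fit(model)
        truth = np.log(0.25 / 0.75)
        assert abs(res.params["const"] - truth) < 2 * res.bse["const"] + 0.05

    def test_rank_deficiency_names_columns(self, harmonized):
        df = harmonized.head(2000)
        design = SmokingModel.from_dataframe(df).design
        design.X["dup"] = design.X["tax"]
        model = SmokingModel.__new__(SmokingModel)
        model.design = design
        with pytest.raises(FittingError, match="rank deficient"):
            model.fit()

    def test_wald_interval_covers_truth_single_replicate(self):
        spec = default_population_spec(n_individuals=20_000, rng_seed=17)
        raw, _ = generate_survey(spec)
        harm = harmonize_survey(raw, spec.tax_by_state)
        res = SmokingModel.from_dataframe(harm).fit()
        beta = spec.true_coefficients.to_series()
        ci = res.conf_int(alpha=0.001)  # generous interval for one replicate
        inside = (beta >= ci["lower"]) & (beta <= ci["upper"])
        assert inside.all(), f"missed: {list(beta.index[~inside])}"

    def test_coefficient_rmse_shrinks_with_n(self):
        rmses = []
        for n, seed in ((4000, 71), (32_000, 72)):
            spec = default_population_spec(n_individuals=n, rng_seed=seed)
            raw, _ = generate_survey(spec)
            harm = harmonize_survey(raw, spec.tax_by_state)
            res = SmokingModel.from_dataframe(harm).fit()
            err = res.params - spec.true_coefficients.to_series()
            rmses.append(float(np.sqrt((err**2).mean())))
        assert rmses[1] < rmses[0]


class TestAUC:
    def test_perfect_ranking(self):
        assert compute_auc([0.9, 0.1], [1, 0]) == 1.0

    def test_ties_contribute_half(self):
        assert compute_auc([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(25):
            n = 20
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert compute_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(500)
        labels = rng.integers(0, 2, size=500)
        assert compute_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            compute_auc([0.1, 0.2], [1, 1])

    @given(
        shift=st.floats(-3, 3, allow_nan=False),
        scale=st.floats(0.1, 5, allow_nan=False),
    )
    def test_invariant_under_monotone_transform(self, shift, scale):
        rng = np.random.default_rng(3)
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        base = compute_auc(scores, labels)
        assert compute_auc(np.exp(scale * scores) + shift, labels) == pytest.approx(
            base, abs=1e-12
        )


class TestThreshold:
    def test_worked_example(self):
        t = calibrate_threshold_values(np.array([0.1, 0.2, 0.6, 0.9]), 0.5)
        assert t == 0.6
        assert (np.array([0.1, 0.2, 0.6, 0.9]) >= t).mean() == 0.5

    def test_target_one_returns_minimum(self):
        probs = np.array([0.15, 0.4, 0.8])
        t = calibrate_threshold_values(probs, 1.0)
        assert t == 0.15 and (probs >= t).mean() == 1.0

    def test_all_equal_scores_unattainable(self):
        with pytest.raises(CalibrationError, match="attainable"):
            calibrate_threshold_values(np.full(10, 0.4), 0.5)

    def test_tolerance_enforced(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold_values(np.array([0.1, 0.9]), 0.25, tolerance=0.1)

    def test_classified_prevalence_non_increasing_in_threshold(self, fitted, harmonized):
        probs = fitted.predict_proba(harmonized)
        prevs = [(probs >= t).mean() for t in np.linspace(0.01, 0.99, 25)]
        assert all(a >= b for a, b in zip(prevs, prevs[1:]))

    def test_classify_boundary_convention(self):
        res = SmokingModelResults.from_coefficients(_zero_coefficients())
        res.set_threshold(0.5)
        assert res.classify(_reference_records())[0] == 1  # p == threshold -> 1
        res.set_threshold(0.500001)
        assert res.classify(_reference_records())[0] == 0

    def test_classify_requires_threshold(self):
        res = SmokingModelResults.from_coefficients(_zero_coefficients())
        with pytest.raises(StateError):
            res.classify(_reference_records())

    def test_log_odds_scale_agrees_with_probability_scale(self, fitted, harmonized):
        p_cls = fitted.classify(harmonized)
        other = SmokingModelResults.from_coefficients(fitted.coefficients)
        other.calibrate_threshold(harmonized, 0.33, scale="log_odds")
        assert (other.classify(harmonized) == p_cls).all()


class TestCrossValidation:
    def test_repeat_and_fraction_bookkeeping(self, harmonized):
        report = cross_validate(harmonized, repeats=8, seed=4)
        assert report.n_repeats == 8
        assert report.train_fraction == 0.75
        assert len(report.per_repeat) == 8
        assert 0 <= report.false_positive_rate_mean <= 1

    def test_deterministic_given_seed(self, harmonized):
        a = cross_validate(harmonized.head(2000), repeats=3, seed=11)
        b = cross_validate(harmonized.head(2000), repeats=3, seed=11)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)
        assert a.auc_mean == b.auc_mean

    def test_in_sample_reduction(self, harmonized):
        df = harmonized.head(3000)
        report = cross_validate(df, train_fraction=1.0, repeats=1, seed=0)
        res = SmokingModel.from_dataframe(df).fit()
        res.calibrate_threshold(df, 0.33)
        in_sample = compute_auc(res.predict_proba(df), df["smokes"].to_numpy())
        assert report.auc_mean == pytest.approx(in_sample, abs=1e-12)
        assert report.auc_sd == 0.0

    def test_stratified_splits_keep_both_classes(self, harmonized):
        report = cross_validate(harmonized.head(1200), repeats=3, seed=2, stratified=True)
        assert report.n_redrawn_splits == 0


class TestPersistence:
    def test_save_load_round_trip(self, fitted, harmonized, tmp_path):
        path = tmp_path / "model.json"
        fitted.save(path)
        loaded = SmokingModelResults.load(path)
        pd.testing.assert_series_equal(fitted.params, loaded.params)
        assert loaded.threshold == fitted.threshold
        np.testing.assert_allclose(
            loaded.predict_proba(harmonized.head(50)),
            fitted.predict_proba(harmonized.head(50)),
        )

    def test_summary_mentions_every_term(self, fitted):
        text = fitted.summary()
        for name in fitted.params.index:
            assert name in text
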