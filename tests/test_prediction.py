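"""Logistic/multinomial models, stepwise selection, ROC and predictive values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braingrid.errors import InvalidDesignError, UndefinedMetricError
from braingrid.prediction import (
    check_collinearity,
    classification_metrics,
    fit_binary_logistic,
    fit_multinomial,
    forward_conditional_select,
    ppv_npv,
    roc_auc,
)


def table_2x2_data(n_exp_event=12, n_exp=20, n_unexp_event=4, n_unexp=20):
    y = np.r_[
        np.ones(n_exp_event), np.zeros(n_exp - n_exp_event),
        np.ones(n_unexp_event), np.zeros(n_unexp - n_unexp_event),
    ]
    x = np.r_[np.ones(n_exp), np.zeros(n_unexp)]
    return y, pd.DataFrame({"exposed": x})


class TestBinaryLogistic:
    def test_saturated_or_equals_cross_product_ratio(self):
        y, X = table_2x2_data(12, 20, 4, 20)
        fit = fit_binary_logistic(y, X)
        eff = fit.effect("exposed")
        assert eff.odds_ratio == pytest.approx(6.0, rel=1e-4)
        assert eff.coef == pytest.approx(np.log(6.0), rel=1e-4)
        assert eff.ci_low <= eff.odds_ratio <= eff.ci_high

    def test_balanced_independent_predictor(self):
        y, X = table_2x2_data(10, 20, 10, 20)
        eff = fit_binary_logistic(y, X).effect("exposed")
        assert eff.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert eff.p_value == pytest.approx(1.0, abs=1e-6)

    def test_univariable_mode_fits_each_predictor_alone(self, rng):
        n = 200
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = (rng.random(n) < 1 / (1 + np.exp(-X["a"]))).astype(float)
        fits = fit_binary_logistic(y, X, univariable=True)
        assert len(fits) == 2
        solo = fit_binary_logistic(y, X[["a"]])
        assert fits[0].effect("a").coef == pytest.approx(solo.effect("a").coef, rel=1e-6)

    def test_complete_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        fit = fit_binary_logistic(y, pd.DataFrame({"x": x}))
        assert fit.effect("x").flag is not None

    def test_constant_predictor_dropped(self):
        y, X = table_2x2_data()
        X["const_col"] = 3.0
        with pytest.warns(UserWarning):
            fit = fit_binary_logistic(y, X)
        assert "const_col" not in [e.variable for e in fit.effects]

    def test_one_class_outcome_raises(self):
        with pytest.raises(InvalidDesignError):
            fit_binary_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestForwardConditional:
    def test_signal_predictor_selected(self, rng):
        n = 300
        X = pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(4)})
        X["signal"] = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.1 + 1.5 * X["signal"])))).astype(float)
        fit = forward_conditional_select(y, X)
        assert "signal" in fit.selected

    def test_pure_noise_gives_intercept_only(self, rng):
        n = 200
        X = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(3)})
        y = (rng.random(n) < 0.4).astype(float)
        fit = forward_conditional_select(y, X, p_enter=0.001)
        assert fit.selected == [] and fit.effects == []

    def test_duplicated_predictor_enters_once(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(float)
        X = pd.DataFrame({"x1": x, "x2": x.copy()})
        fit = forward_conditional_select(y, X)
        assert fit.selected == ["x1"]  # tie broken by candidate order

    def test_invalid_thresholds_raise(self, rng):
        with pytest.raises(InvalidDesignError):
            forward_conditional_select(
                np.r_[0, 1] * 5, pd.DataFrame({"x": np.arange(10.0)}), p_enter=0.2, p_remove=0.1
            )


class TestCollinearity:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)})
        vifs = check_collinearity(X)
        assert np.allclose(vifs["vif"], 1.0, atol=1e-8)
        assert not vifs["flagged"].any()

    def test_duplicated_column_flagged_infinite(self, rng):
        x = rng.normal(size=50)
        vifs = check_collinearity(pd.DataFrame({"a": x, "b": x}))
        assert vifs["flagged"].all()
        assert np.isinf(vifs["vif"]).all()

    def test_correlated_pair_matches_r2_oracle(self, rng):
        n = 500
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b})
        vifs = check_collinearity(X).set_index("variable")["vif"]
        import statsmodels.api as sm

        r2 = sm.OLS(X["a"], sm.add_constant(X["b"])).fit().rsquared
        assert vifs["a"] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestMultinomial:
    def test_intercept_only_recovers_class_shares(self):
        labels = ["astro_IDHm"] * 65 + ["astro_IDHwt"] * 54 + ["oligo"] * 116
        model = fit_multinomial(labels, reference="astro_IDHm")
        p = model.probabilities.iloc[0]
        assert p["astro_IDHm"] == pytest.approx(65 / 235, abs=1e-6)
        assert p["astro_IDHwt"] == pytest.approx(54 / 235, abs=1e-6)
        assert p["oligo"] == pytest.approx(116 / 235, abs=1e-6)

    def test_saturated_binary_predictor_slopes(self):
        # x=1: classes (10, 20, 30); x=0: classes (20, 10, 10)
        labels = (
            ["c1"] * 10 + ["c2"] * 20 + ["c3"] * 30 + ["c1"] * 20 + ["c2"] * 10 + ["c3"] * 10
        )
        x = pd.DataFrame({"x": [1.0] * 60 + [0.0] * 40})
        model = fit_multinomial(labels, x, reference="c1")
        # slope_k = log odds-ratio of class k vs reference between x=1 and x=0
        assert model.params.loc["x", "c2"] == pytest.approx(np.log(4.0), abs=1e-4)
        assert model.params.loc["x", "c3"] == pytest.approx(np.log(6.0), abs=1e-4)

    def test_probabilities_sum_to_one(self, rng):
        labels = rng.choice(["a", "b", "c"], size=120)
        X = pd.DataFrame({"x": rng.normal(size=120)})
        model = fit_multinomial(labels, X, reference="b")
        assert np.allclose(model.probabilities.sum(axis=1), 1.0)
        assert model.classes[0] == "b"

    def test_missing_reference_raises(self):
        with pytest.raises(InvalidDesignError):
            fit_multinomial(["a", "b", "a", "b"], reference="zzz")


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_uninformative_scores(self):
        res = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert res.auc == 0.5

    def test_pairwise_enumeration_example(self):
        res = roc_auc([0.9, 0.8, 0.4, 0.7, 0.3], [1, 1, 1, 0, 0])
        assert res.auc == pytest.approx(5 / 6)

    def test_rank_statistic_equivalence(self, rng):
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        s = rng.normal(size=80)
        res = roc_auc(s, y)
        pos, neg = s[y == 1], s[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.normal(size=60)
        assert roc_auc(s, y).auc == pytest.approx(roc_auc(np.exp(2 * s), y).auc)

    def test_single_class_raises(self):
        with pytest.raises(InvalidDesignError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPPVNPV:
    def test_worked_example(self):
        ppv, npv = ppv_npv(0.43, 0.82, 0.277)
        assert round(npv, 2) == 0.79

    def test_perfect_test(self):
        assert ppv_npv(1, 1, 0.3) == (1.0, 1.0)

    def test_uninformative_test(self):
        ppv, npv = ppv_npv(0.5, 0.5, 0.21)
        assert ppv == pytest.approx(0.21) and npv == pytest.approx(0.79)

    def test_degenerate_prevalence_raises(self):
        with pytest.raises(UndefinedMetricError):
            ppv_npv(0.5, 0.5, 0.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        tp=st.integers(1, 50), fn=st.integers(1, 50),
        fp=st.integers(1, 50), tn=st.integers(1, 50),
    )
    def test_matches_confusion_matrix(self, tp, fn, fp, tn):
        """The closed form reproduces TP/(TP+FP) and TN/(TN+FN) for every
        integer confusion matrix with the matching Se/Sp/prevalence."""
        n = tp + fn + fp + tn
        se, sp, pi = tp / (tp + fn), tn / (tn + fp), (tp + fn) / n
        ppv, npv = ppv_npv(se, sp, pi)
        assert ppv == pytest.approx(tp / (tp + fp))
        assert npv == pytest.approx(tn / (tn + fn))


class TestClassificationMetrics:
    def test_perfect_classifier(self, rng):
        labels = np.repeat(["a", "b", "c"], 30)
        X = pd.DataFrame({"xa": (labels == "a") * 1.0, "xb": (labels == "b") * 1.0})
        model = fit_multinomial(labels, X, reference="a")
        for m in classification_metrics(model, labels):
            assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.auc == 1.0

    def test_intercept_only_predicts_majority(self):
        labels = ["a"] * 10 + ["b"] * 30
        model = fit_multinomial(labels, reference="a")
        metrics = {m.class_name: m for m in classification_metrics(model, labels)}
        assert metrics["b"].sensitivity == 1.0
        assert metrics["a"].sensitivity == 0.0
        assert metrics["a"].flag is not None

    def test_confusion_matrix_oracle(self, rng):
        n = 240
        X = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        eta_b = 1.2 * X["x"]
        eta_c = -0.8 * X["z"]
        den = 1 + np.exp(eta_b) + np.exp(eta_c)
        u = rng.random(n)
        pb, pc = np.exp(eta_b) / den, np.exp(eta_c) / den
        labels = np.where(u < pb, "b", np.where(u < pb + pc, "c", "a"))
        model = fit_multinomial(labels, X, reference="a")
        pred = model.predicted_class()
        for m in classification_metrics(model, labels):
            pos = labels == m.class_name
            hat = pred == m.class_name
            tp = np.sum(pos & hat); fn = np.sum(pos & ~hat)
            fp = np.sum(~pos & hat); tn = np.sum(~pos & ~hat)
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))
            assert m.prevalence == pytest.approx(pos.mean())
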