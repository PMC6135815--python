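"""Nested cross-validation, robust feature selection, consensus weights."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from placebo_rct import (
    accuracy_null, clopper_pearson, compare_predictions, consensus_weights,
    correlation_difference_z, nested_loocv_classify, nested_loocv_lasso,
    predict_with_consensus, select_features_robust,
)
from placebo_rct.prediction import robust_slope_pvalues

SMALL_GRID = {"C": np.logspace(-2, 2, 3), "gamma": np.logspace(-2, 2, 3)}


def _features(n, p, rng, index=None):
    idx = index or [f"s{i:02d}" for i in range(n)]
    return pd.DataFrame(rng.normal(size=(n, p)), index=idx,
                        columns=[f"f{j:02d}" for j in range(p)])


class TestClopperPearson:
    def test_printed_interval(self):
        lo, hi = clopper_pearson(31, 43)
        assert round(lo, 2) == 0.56
        assert round(hi, 2) == 0.85

    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_brackets_point_estimate(self):
        for k, n in [(1, 7), (5, 9), (20, 40)]:
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi

    def test_coverage_at_least_nominal(self, rng):
        # exact interval must cover the true p in >= 95% of binomial draws
        p_true, n = 0.35, 30
        cover = 0
        draws = 2000
        ks = rng.binomial(n, p_true, size=draws)
        for k in ks:
            lo, hi = clopper_pearson(int(k), n)
            cover += lo <= p_true <= hi
        assert cover / draws >= 0.95 - 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)


class TestCorrelationDifference:
    def test_equal_correlations_zero(self):
        z, p = correlation_difference_z(0.4, 30, 0.4, 50)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        z1, _ = correlation_difference_z(0.6, 43, 0.1, 19)
        z2, _ = correlation_difference_z(0.1, 19, 0.6, 43)
        assert z1 == pytest.approx(-z2)

    def test_hand_evaluated_formula(self):
        # oracle: direct arithmetic of the Fisher formula
        z_expected = (np.arctanh(0.6) - np.arctanh(0.0)) / np.sqrt(1 / 40 + 1 / 16)
        z, p = correlation_difference_z(0.6, 43, 0.0, 19)
        assert z == pytest.approx(z_expected)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_expected)))

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            correlation_difference_z(0.5, 3, 0.1, 30)


class TestRobustSelection:
    def test_copy_of_outcome_selected(self, rng):
        X = _features(30, 5, rng)
        y = rng.normal(size=30)
        X["f00"] = y
        assert "f00" in select_features_robust(X, y)

    def test_null_selection_rate_near_threshold(self):
        hits = total = 0
        for k in range(8):
            rng = np.random.default_rng(k)
            X = _features(40, 300, rng)
            y = rng.normal(size=40)
            hits += len(select_features_robust(X, y, p_thresh=0.01))
            total += 300
        # expected ~1% of null features at p<0.01 (robust p is approximate;
        # allow generous Monte-Carlo slack)
        assert hits / total < 0.035

    def test_contamination_resisted_where_ols_fooled(self, rng):
        # a single extreme point drives an OLS association on an otherwise
        # null feature; the bisquare fit down-weights it (statsmodels RLM,
        # the reference robust fit, is the oracle for attainable robustness)
        import statsmodels.api as sm

        n = 30
        fooled_ols = robust_hits = oracle_hits = 0
        for k in range(10):
            r = np.random.default_rng(k)
            x = r.normal(size=n)
            y = r.normal(size=n)
            x[0], y[0] = 8.0, 8.0  # leverage point
            ols_p = stats.linregress(x, y).pvalue
            _, rob_p = robust_slope_pvalues(x[:, None], y)
            rlm = sm.RLM(y, sm.add_constant(x),
                         M=sm.robust.norms.TukeyBiweight()).fit()
            fooled_ols += ols_p < 0.01
            robust_hits += rob_p[0] < 0.01
            oracle_hits += rlm.pvalues[1] < 0.01
        assert fooled_ols >= 8  # OLS oracle: contamination creates the signal
        assert robust_hits <= oracle_hits + 1  # as robust as the reference fit
        assert robust_hits <= fooled_ols - 5  # and far less fooled than OLS

    def test_agrees_with_statsmodels_rlm(self, rng):
        import statsmodels.api as sm

        X = _features(50, 20, rng)
        y = 0.8 * X["f03"].to_numpy() + rng.standard_t(df=3, size=50)
        slopes, pvals = robust_slope_pvalues(X.to_numpy(), y)
        for j in range(20):
            fit = sm.RLM(
                y, sm.add_constant(X.iloc[:, j].to_numpy()),
                M=sm.robust.norms.TukeyBiweight(),
            ).fit()
            assert slopes[j] == pytest.approx(fit.params[1], abs=0.05)
        assert pvals.argmin() == 3

    def test_zero_variance_feature_skipped(self, rng):
        X = _features(20, 3, rng)
        X["f01"] = 7.0
        sel = select_features_robust(X, X["f00"].to_numpy(), p_thresh=0.5)
        assert "f01" not in sel


class TestNestedClassification:
    def test_separable_features_high_accuracy(self, rng):
        n = 24
        y = pd.Series(["Responder"] * 12 + ["NonResponder"] * 12)
        X = _features(n, 4, rng)
        X.iloc[:12, 0] += 4.0  # wide separation on one feature
        rep = nested_loocv_classify(X, y, hyper_grid=SMALL_GRID, inner_folds=5, seed=0)
        assert rep.accuracy >= 0.9
        assert rep.confusion["TP"] + rep.confusion["FN"] == 12
        assert rep.accuracy_ci[0] <= rep.accuracy <= rep.accuracy_ci[1]

    def test_determinism(self, rng):
        y = pd.Series(["Responder"] * 10 + ["NonResponder"] * 10)
        X = _features(20, 3, rng)
        r1 = nested_loocv_classify(X, y, hyper_grid=SMALL_GRID, inner_folds=5, seed=4)
        r2 = nested_loocv_classify(X, y, hyper_grid=SMALL_GRID, inner_folds=5, seed=4)
        assert (r1.y_pred == r2.y_pred).all()
        assert r1.fold_params == r2.fold_params

    def test_shuffled_labels_within_null_band(self, rng):
        n = 22
        y = pd.Series(["Responder"] * 11 + ["NonResponder"] * 11)
        X = _features(n, 4, rng)
        X.iloc[:11, 0] += 3.0
        rep = nested_loocv_classify(X, y, hyper_grid=SMALL_GRID, inner_folds=5, seed=1)
        y_shuf = pd.Series(np.random.default_rng(0).permutation(y.to_numpy()))
        rep_shuf = nested_loocv_classify(
            X, y_shuf, hyper_grid=SMALL_GRID, inner_folds=5, seed=1
        )
        null = accuracy_null(
            X, y_shuf, rep_shuf.accuracy, n_label_draws=20, seed=2,
            hyper_grid=SMALL_GRID, inner_folds=5,
        )
        lo, hi = np.quantile(null.null_accuracies, [0.025, 0.975])
        assert lo - 1e-9 <= rep_shuf.accuracy <= hi + 1e-9
        # while the real labeling clears the z = 1.96 threshold
        z_obs = (rep.accuracy - null.null_accuracies.mean()) / null.null_accuracies.std(ddof=1)
        assert z_obs > 1.96

    def test_class_missing_from_inner_folds_errors(self, rng):
        y = pd.Series(["Responder"] * 3 + ["NonResponder"] * 17)
        X = _features(20, 3, rng)
        with pytest.raises(ValueError, match="stratified"):
            nested_loocv_classify(X, y, hyper_grid=SMALL_GRID, inner_folds=5, seed=0)


class TestNestedLasso:
    def test_planted_signal_recovered(self, rng):
        # 6 planted predictive subscales out of 38, robust-selection +
        # LASSO pipeline as configured for the study
        n, p = 43, 38
        X = _features(n, p, rng)
        planted = ["f00", "f05", "f11", "f17", "f23", "f30"]
        y = pd.Series(rng.normal(size=n))
        z = ((y - y.mean()) / y.std()).to_numpy()
        rho = 0.65  # marginal correlation of each planted subscale with y
        for f in planted:
            X[f] = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
        rep = nested_loocv_lasso(X, y, inner_folds=10, seed=0)
        assert rep.r_pred_actual > 0.5
        freq = rep.consensus.frequency
        others = [f for f in X.columns if f not in planted]
        assert freq[planted].min() > freq[others].max()
        w = rep.consensus.weights.abs()
        assert np.median(w[planted]) > 5 * max(np.median(w[others]), 1e-12)

    def test_pure_noise_no_positive_skill(self, rng):
        # with no signal the out-of-fold correlation must show no positive
        # skill; it is typically *negative* here because folds that shrink
        # every weight predict the training mean, which is anti-correlated
        # with the held-out value under leave-one-out
        X = _features(30, 10, rng)
        y = pd.Series(rng.normal(size=30))
        rep = nested_loocv_lasso(X, y, selection=None, inner_folds=5, seed=0)
        assert rep.r_pred_actual < 0.35

    def test_empty_selection_predicts_training_mean(self, rng):
        X = _features(15, 4, rng)
        y = pd.Series(rng.normal(size=15))

        def select_nothing(X_train, y_train, p_thresh=0.001):
            return []

        rep = nested_loocv_lasso(X, y, selection=select_nothing, inner_folds=5, seed=0)
        for hold in range(15):
            expected = np.delete(y.to_numpy(), hold).mean()
            assert rep.y_pred[hold] == pytest.approx(expected)

    def test_no_leakage_corrupting_heldout_outcome(self, rng):
        X = _features(16, 5, rng)
        y = pd.Series(0.9 * X["f01"].to_numpy() + rng.normal(size=16))
        rep1 = nested_loocv_lasso(X, y, selection=None, inner_folds=5, seed=3)
        for victim in [0, 7, 15]:
            y_bad = y.copy()
            y_bad.iloc[victim] = 1e6
            rep2 = nested_loocv_lasso(X, y_bad, selection=None, inner_folds=5, seed=3)
            assert rep2.y_pred[victim] == pytest.approx(rep1.y_pred[victim], rel=1e-9)


class TestConsensusWeights:
    def test_always_selected(self):
        cw = consensus_weights([{"a": 2.0}, {"a": 2.0}], all_features=["a", "b"])
        assert cw.weights["a"] == 2.0
        assert cw.frequency["a"] == 1.0
        assert cw.weights["b"] == 0.0 and cw.frequency["b"] == 0.0

    def test_half_selected_halves_weight(self):
        cw = consensus_weights([{"a": 3.0}, {}])
        assert cw.weights["a"] == 1.5
        assert cw.frequency["a"] == 0.5

    def test_threshold_requires_37_of_43_folds(self):
        folds = [{"a": 1.0} if k < 37 else {} for k in range(43)]
        cw = consensus_weights(folds, report_threshold=0.84)
        assert cw.flagged["a"]  # 37/43 ≈ 0.860 > 0.84
        folds36 = [{"a": 1.0} if k < 36 else {} for k in range(43)]
        assert not consensus_weights(folds36, report_threshold=0.84).flagged["a"]


class TestComparePredictions:
    def test_identical_predictions_collinear(self, rng):
        a = rng.normal(size=30)
        out = compare_predictions(a, a, a + rng.normal(size=30))
        assert out["r_pred_a_pred_b"] == pytest.approx(1.0)
        assert out["flags"]["collinear"]

    def test_orthogonal_predictors_add_r2(self, rng):
        n = 400
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a -= a.mean(); b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal
        y = a + b + 0.5 * rng.normal(size=n)
        out = compare_predictions(a, b, y)
        r2a = np.corrcoef(a, y)[0, 1] ** 2
        r2b = np.corrcoef(b, y)[0, 1] ** 2
        assert out["joint_r2"] == pytest.approx(r2a + r2b, abs=0.02)

    def test_noise_predictor_contributes_nothing(self, rng):
        n = 200
        a = rng.normal(size=n)
        y = a + 0.3 * rng.normal(size=n)
        noise = rng.normal(size=n)
        out = compare_predictions(a, noise, y)
        assert out["p_a"] < 1e-6
        assert out["p_b"] > 0.05
        assert abs(out["coef_b"]) < 0.15


class TestArmGeneralization:
    def test_model_transfers_worse_to_null_arm(self, rng):
        """Mirrors the specificity analysis: a model trained on the treated
        arm predicts its own arm but not a no-treatment arm with no
        planted feature-outcome association."""
        n, p = 43, 15
        X = _features(n, p, rng)
        y = pd.Series(3.0 * X["f02"].to_numpy() + rng.normal(size=n))
        rep = nested_loocv_lasso(X, y, selection=None, inner_folds=10, seed=1)
        X_null = _features(19, p, rng, index=[f"t{i}" for i in range(19)])
        y_null = rng.normal(size=19) * y.std() + y.mean()
        pred_null = predict_with_consensus(rep, X_null)
        r_null = np.corrcoef(pred_null, y_null)[0, 1]
        z, pz = correlation_difference_z(rep.r_pred_actual, n, r_null, 19)
        assert rep.r_pred_actual > r_null
        assert z > 1.96
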