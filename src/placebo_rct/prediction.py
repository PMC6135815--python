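"""Cross-validated prediction of placebo response.

Nested leave-one-out cross-validation (LOOCV): the outer loop holds out
one subject at a time for an unbiased generalization estimate; the inner
ten-fold loop, run on the remaining n−1 subjects only, tunes
hyperparameters (SVM box constraint and RBF kernel scale, or the LASSO
regularization λ) and, for connectivity features, performs robust-
regression feature selection.  Everything the model learns — feature
scaling, selected features, hyperparameters, weights — comes from the
training side of each split, so held-out subjects never leak into their
own predictions.

Significance of the observed accuracy is calibrated against a null
distribution built by repeating the entire nested procedure on randomly
scrambled labels; an observed accuracy more than 1.96 null SDs above the
null mean is called significant.  Binomial proportions carry exact
Clopper–Pearson confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: default hyperparameter grid: 7 log-spaced points in [1e-3, 1e3] for both
#: the box constraint C and the RBF kernel coefficient gamma
DEFAULT_HYPER_GRID = {
    "C": np.logspace(-3, 3, 7),
    "gamma": np.logspace(-3, 3, 7),
}

BISQUARE_C = 4.685  # Tukey bisquare tuning constant (95% Gaussian efficiency)


# ---------------------------------------------------------------------------
# reports

@dataclass
class ClassifierReport:
    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    confusion: dict[str, int]  # TP, TN, FP, FN
    fold_params: list[dict]
    positive_label: str

    @property
    def n(self) -> int:
        return len(self.y_true)


@dataclass
class NullCalibration:
    null_accuracies: np.ndarray
    z: float
    threshold: float  # mean_null + 1.96 * sd_null


@dataclass
class RegressionReport:
    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    r_pred_actual: float
    p_pred_actual: float
    fold_features: list[list[str]]
    fold_weights: list[dict[str, float]]
    consensus: "ConsensusWeights"
    norm_mean: pd.Series  # full-sample normalisation, for out-of-arm transfer
    norm_sd: pd.Series
    intercept: float


@dataclass
class ConsensusWeights:
    weights: pd.Series  # mean weight across all folds (absent = 0)
    frequency: pd.Series  # fraction of folds selecting the feature
    flagged: pd.Series  # frequency > report_threshold
    report_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"consensus_weight": self.weights, "frequency": self.frequency,
             "flag": self.flagged}
        )


# ---------------------------------------------------------------------------
# small statistical primitives

def clopper_pearson(
    successes: int, n: int, conf: float = 0.95
) -> tuple[float, float]:
    """Exact binomial (beta-quantile) confidence interval for a proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n")
    alpha = 1.0 - conf
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    upper = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return lower, upper


def correlation_difference_z(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher r-to-z test for the difference of two independent correlations.

    z = (atanh(r1) − atanh(r2)) / sqrt(1/(n1−3) + 1/(n2−3)), two-sided p.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in each group")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("need |r| < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_predictions(
    pred_a: np.ndarray, pred_b: np.ndarray, actual: np.ndarray
) -> dict:
    """Do two prediction vectors carry independent information?

    Reports the Pearson correlation between the two prediction vectors
    and a joint two-predictor OLS of the actual outcome on both, with
    each predictor's coefficient, t and p, and the joint R².
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    y = np.asarray(actual, dtype=float)
    if not len(a) == len(b) == len(y):
        raise ValueError("all three vectors must cover the same subjects")
    flags = {"pred_a_constant": a.std() == 0, "pred_b_constant": b.std() == 0}
    if flags["pred_a_constant"] or flags["pred_b_constant"]:
        logger.warning("compare_predictions: constant prediction vector")
        r_ab = np.nan
    else:
        r_ab = float(stats.pearsonr(a, b).statistic)
        flags["collinear"] = abs(r_ab) > 0.999

    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([a, b]))
    fit = sm.OLS(y, X).fit()
    return {
        "r_pred_a_pred_b": r_ab,
        "coef_a": float(fit.params[1]),
        "coef_b": float(fit.params[2]),
        "p_a": float(fit.pvalues[1]),
        "p_b": float(fit.pvalues[2]),
        "joint_r2": float(fit.rsquared),
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# robust-regression feature selection

def robust_slope_pvalues(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature robust simple regression of y on x (IRLS, Tukey bisquare).

    Vectorised across features so that thousands of connectivity edges can
    be screened inside every cross-validation fold.  Scale is re-estimated
    each iteration from the MAD of residuals; the slope's standard error
    uses the weighted least-squares formula with the robust scale, and the
    p-value a t reference with n−2 df.  Zero-variance features get p = 1.

    Returns (slopes, p_values), each of length n_features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 observations")

    sd = X.std(axis=0)
    live = sd > 0
    slopes = np.zeros(p)
    pvals = np.ones(p)
    if not live.any():
        return slopes, pvals
    Xl = X[:, live]

    # OLS start
    xc = Xl - Xl.mean(axis=0)
    yc = y - y.mean()
    b1 = (xc * yc[:, None]).sum(axis=0) / (xc**2).sum(axis=0)
    b0 = y.mean() - b1 * Xl.mean(axis=0)

    for _ in range(max_iter):
        r = y[:, None] - b0 - b1 * Xl
        s = np.median(np.abs(r - np.median(r, axis=0)), axis=0) / 0.6745
        s = np.where(s < 1e-10, np.std(r, axis=0) + 1e-10, s)
        u = r / (BISQUARE_C * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        sw = w.sum(axis=0)
        # guard: if nearly all weight vanished, fall back to uniform weights
        bad = sw < 2.0
        if bad.any():
            w[:, bad] = 1.0
            sw = w.sum(axis=0)
        xw = (w * Xl).sum(axis=0) / sw
        yw = (w * y[:, None]).sum(axis=0) / sw
        dx = Xl - xw
        sxx = (w * dx**2).sum(axis=0)
        b1_new = (w * dx * (y[:, None] - yw)).sum(axis=0) / sxx
        b0_new = yw - b1_new * xw
        if np.max(np.abs(b1_new - b1)) < tol * (1 + np.max(np.abs(b1))):
            b1, b0 = b1_new, b0_new
            break
        b1, b0 = b1_new, b0_new

    r = y[:, None] - b0 - b1 * Xl
    s = np.median(np.abs(r - np.median(r, axis=0)), axis=0) / 0.6745
    s = np.where(s < 1e-10, np.std(r, axis=0) + 1e-10, s)
    u = r / (BISQUARE_C * s)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    sw = w.sum(axis=0)
    bad = sw < 2.0
    if bad.any():
        w[:, bad] = 1.0
        sw = w.sum(axis=0)
    xw = (w * Xl).sum(axis=0) / sw
    dx = Xl - xw
    sxx = (w * dx**2).sum(axis=0)
    se = np.sqrt(np.maximum(s**2 / np.maximum(sxx, 1e-300), 1e-300))
    t = b1 / se
    pv = 2 * stats.t.sf(np.abs(t), df=n - 2)

    slopes[live] = b1
    pvals[live] = pv
    return slopes, pvals


def select_features_robust(
    X_train: pd.DataFrame, y_train: np.ndarray, p_thresh: float = 0.001
) -> list[str]:
    """Features whose robust simple-regression slope on the outcome has
    p < ``p_thresh``.  Uses training subjects only; zero-variance features
    are skipped."""
    if len(X_train) < 10:
        raise ValueError("need at least 10 training subjects")
    _, pvals = robust_slope_pvalues(X_train.to_numpy(dtype=float),
                                    np.asarray(y_train, dtype=float))
    return [c for c, p in zip(X_train.columns, pvals) if p < p_thresh]


# ---------------------------------------------------------------------------
# nested LOOCV — classification

def _zscore_train_apply(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def nested_loocv_classify(
    X: pd.DataFrame,
    y: pd.Series,
    hyper_grid: dict | None = None,
    inner_folds: int = 10,
    seed: int = 0,
    positive_label: str = "Responder",
) -> ClassifierReport:
    """Nested LOOCV RBF-SVM classification.

    For every held-out subject, the remaining n−1 subjects are z-scored
    with their own statistics and the SVM box constraint / kernel scale
    pair with the lowest stratified inner ``inner_folds``-fold error is
    refit on all n−1 and applied to the held-out subject.
    """
    if hyper_grid is None:
        hyper_grid = DEFAULT_HYPER_GRID
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()
    n = len(yv)
    classes = np.unique(yv)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if n < inner_folds + 1:
        raise ValueError("need n >= inner_folds + 1 subjects")

    grid = [(float(c), float(g)) for c in hyper_grid["C"] for g in hyper_grid["gamma"]]
    preds = np.empty(n, dtype=object)
    fold_params: list[dict] = []
    for hold in range(n):
        tr = np.ones(n, dtype=bool)
        tr[hold] = False
        X_tr, X_te = _zscore_train_apply(Xv[tr], Xv[~tr])
        y_tr = yv[tr]
        counts = pd.Series(y_tr).value_counts()
        if counts.min() < inner_folds:
            raise ValueError(
                "cannot build stratified inner folds: a class has fewer "
                f"members ({counts.min()}) than inner_folds={inner_folds}"
            )
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X_tr, y_tr))
        best_err, best = np.inf, grid[0]
        for c, g in grid:
            err = 0
            for itr, ite in splits:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(X_tr[itr], y_tr[itr])
                err += (clf.predict(X_tr[ite]) != y_tr[ite]).sum()
            if err < best_err:  # first minimum wins: deterministic tie-break
                best_err, best = err, (c, g)
        clf = SVC(C=best[0], gamma=best[1], kernel="rbf")
        clf.fit(X_tr, y_tr)
        preds[hold] = clf.predict(X_te)[0]
        fold_params.append({"C": best[0], "gamma": best[1],
                            "inner_error": int(best_err)})

    y_pred = np.asarray(preds)
    pos = positive_label if positive_label in classes else classes[0]
    tp = int(((y_pred == pos) & (yv == pos)).sum())
    tn = int(((y_pred != pos) & (yv != pos)).sum())
    fp = int(((y_pred == pos) & (yv != pos)).sum())
    fn = int(((y_pred != pos) & (yv == pos)).sum())
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return ClassifierReport(
        subject_ids=list(X.index.astype(str)),
        y_true=yv,
        y_pred=y_pred,
        accuracy=acc,
        accuracy_ci=clopper_pearson(tp + tn, n),
        sensitivity=sens,
        sensitivity_ci=clopper_pearson(tp, tp + fn) if tp + fn else (np.nan, np.nan),
        specificity=spec,
        specificity_ci=clopper_pearson(tn, tn + fp) if tn + fp else (np.nan, np.nan),
        confusion={"TP": tp, "TN": tn, "FP": fp, "FN": fn},
        fold_params=fold_params,
        positive_label=str(pos),
    )


def accuracy_null(
    X: pd.DataFrame,
    y: pd.Series,
    observed_accuracy: float,
    n_label_draws: int = 1000,
    seed: int = 0,
    **classify_kwargs,
) -> NullCalibration:
    """Null distribution of accuracy from scrambled labels.

    Repeats the *entire* nested LOOCV procedure on ``n_label_draws``
    random permutations of the labels.  z = (acc_obs − mean)/sd of the
    null; the significance threshold is mean + 1.96·sd.
    """
    rng = np.random.default_rng(seed)
    accs = np.empty(n_label_draws)
    for k in range(n_label_draws):
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        rep = nested_loocv_classify(X, y_perm, seed=seed + k + 1, **classify_kwargs)
        accs[k] = rep.accuracy
    sd = accs.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null: zero variance in null accuracies")
    return NullCalibration(
        null_accuracies=accs,
        z=float((observed_accuracy - accs.mean()) / sd),
        threshold=float(accs.mean() + 1.96 * sd),
    )


# ---------------------------------------------------------------------------
# nested LOOCV — LASSO regression

def _quantile_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Fold assignment stratified by outcome quantile: subjects are sorted
    by outcome and fold labels shuffled within consecutive blocks of k."""
    order = np.argsort(y, kind="stable")
    folds = np.empty(len(y), dtype=int)
    for start in range(0, len(y), k):
        block = order[start:start + k]
        folds[block] = rng.permutation(len(block)) % k
    return [
        (np.flatnonzero(folds != f), np.flatnonzero(folds == f)) for f in range(k)
    ]


def nested_loocv_lasso(
    X: pd.DataFrame,
    y: pd.Series,
    selection=select_features_robust,
    inner_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    report_threshold: float = 0.84,
) -> RegressionReport:
    """Nested LOOCV LASSO prediction of a continuous outcome.

    Per outer fold: features are selected on the n−1 training subjects
    (``selection``; pass ``None`` to keep all), z-scored with training
    statistics, λ tuned by inner ``inner_folds``-fold CV over ``n_alphas``
    log-spaced values below the training λ_max (minimum mean error rule),
    and the refit model predicts the held-out subject.  A fold whose
    selection comes back empty predicts the training outcome mean.

    The consensus model averages each feature's weight over all outer
    folds (never-selected ⇒ 0) and records its selection frequency.
    """
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if n < inner_folds + 1:
        raise ValueError("need n >= inner_folds + 1 subjects")
    rng = np.random.default_rng(seed)

    preds = np.empty(n)
    fold_features: list[list[str]] = []
    fold_weights: list[dict[str, float]] = []
    for hold in range(n):
        tr = np.ones(n, dtype=bool)
        tr[hold] = False
        X_tr_df = X.iloc[tr]
        y_tr = yv[tr]
        feats = list(X.columns) if selection is None else selection(X_tr_df, y_tr)
        fold_features.append(list(feats))
        if not feats:
            logger.info("lasso fold %d: empty selection, predicting training mean", hold)
            preds[hold] = y_tr.mean()
            fold_weights.append({})
            continue
        cols = [X.columns.get_loc(f) for f in feats]
        X_tr, X_te = _zscore_train_apply(Xv[np.ix_(tr, cols)], Xv[np.ix_(~tr, cols)])
        folds = _quantile_folds(y_tr, inner_folds, rng)
        lcv = LassoCV(alphas=n_alphas, cv=folds, max_iter=50_000)
        lcv.fit(X_tr, y_tr)
        preds[hold] = float(lcv.predict(X_te)[0])
        fold_weights.append(
            {f: float(w) for f, w in zip(feats, lcv.coef_) if w != 0.0}
        )

    consensus = consensus_weights(
        fold_weights, all_features=list(X.columns), report_threshold=report_threshold
    )
    if np.std(preds) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(preds, yv)
    mu = X.mean()
    sd = X.std(ddof=1).replace(0.0, 1.0)
    return RegressionReport(
        subject_ids=list(X.index.astype(str)),
        y_true=yv,
        y_pred=preds,
        r_pred_actual=float(r),
        p_pred_actual=float(p),
        fold_features=fold_features,
        fold_weights=fold_weights,
        consensus=consensus,
        norm_mean=mu,
        norm_sd=sd,
        intercept=float(yv.mean()),
    )


def consensus_weights(
    per_fold_weights: list[dict[str, float]],
    all_features: list[str] | None = None,
    report_threshold: float = 0.84,
) -> ConsensusWeights:
    """Average weights across outer folds, with selection frequency.

    A feature absent from a fold contributes weight 0 to the average, so
    consensus weight = (sum of fitted weights)/(number of folds).  With 43
    folds and threshold 0.84, reporting requires selection in ≥ 37 folds.
    """
    if not per_fold_weights:
        raise ValueError("need at least one fold")
    n_folds = len(per_fold_weights)
    if all_features is None:
        all_features = sorted({f for fw in per_fold_weights for f in fw})
    total = pd.Series(0.0, index=all_features)
    count = pd.Series(0, index=all_features)
    for fw in per_fold_weights:
        for f, w in fw.items():
            total[f] += w
            count[f] += 1
    weights = total / n_folds
    freq = count / n_folds
    return ConsensusWeights(
        weights=weights,
        frequency=freq.astype(float),
        flagged=freq > report_threshold,
        report_threshold=report_threshold,
    )


def predict_with_consensus(report: RegressionReport, X_new: pd.DataFrame) -> np.ndarray:
    """Apply a frozen consensus LASSO model to new subjects.

    Used to test generalization across arms: features are normalised with
    the training arm's statistics, then intercept + Xz · w_consensus.
    """
    Xz = (X_new[report.consensus.weights.index] - report.norm_mean[
        report.consensus.weights.index
    ]) / report.norm_sd[report.consensus.weights.index]
    return report.intercept + Xz.to_numpy(dtype=float) @ report.consensus.weights.to_numpy()
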