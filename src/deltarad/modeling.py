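"""Feature selection and per-bin logistic models with bootstrap-LOO AUC.

Selection ranks features by random-forest Gini importance on the pooled
(all-bins) design matrix, removes lower-ranked features whose absolute
Pearson correlation with an already-kept feature exceeds 0.8, and keeps at
most seven survivors.  Each BED bin is then modeled independently by logistic
regression with the shared selected features, and evaluated by the median and
percentile CI of AUCs from leave-one-out predictions inside patient-level
bootstrap resamples.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .exceptions import ModelingError

__all__ = [
    "ImportanceRanking",
    "ModelResult",
    "rf_gini_importance",
    "correlation_filter",
    "select_features",
    "fit_logistic",
    "compute_auc",
    "loo_bootstrap_auc",
    "roc_points",
    "build_bin_model",
]

MAX_SELECTED = 7
RIDGE_FALLBACK = 1e-4  # L2 strength used when the unpenalized fit diverges
_COEF_LIMIT = 1e3


ImportanceRanking = list[tuple[str, float]]


@dataclass
class FittedLogit:
    """Logistic fit: intercept + per-feature log-odds coefficients."""

    features: list[str]
    intercept: float
    coefficients: dict[str, float]
    ridged: bool

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        z = self.intercept + X[self.features].to_numpy() @ np.array(
            [self.coefficients[f] for f in self.features]
        )
        return expit(z)


@dataclass
class ModelResult:
    endpoint: str
    bin: float
    selected_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    auc_distribution: np.ndarray
    auc_median: float
    auc_ci: tuple[float, float]
    roc: list[tuple[float, float]]
    unevaluable: bool = False

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "bin": self.bin,
            "selected_features": self.selected_features,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "auc_median": self.auc_median,
            "auc_ci": list(self.auc_ci),
            "n_bootstrap": int(self.auc_distribution.size),
            "roc": [list(p) for p in self.roc],
            "unevaluable": self.unevaluable,
        }


def rf_gini_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    n_trees: int = 500,
    features_per_split: int = 7,
    bag_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> ImportanceRanking:
    """Rank features by mean decrease in Gini impurity across a random forest
    (500 trees, 2/3 of patients per bag, 7 candidate features per split by
    default).  Ties are broken by feature name so the ranking is deterministic
    for a given seed.
    """
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise ModelingError("need at least 2 rows for feature selection")
    if np.unique(y).size < 2:
        raise ModelingError("labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=min(features_per_split, X.shape[1]),
        bootstrap=True,
        max_samples=max(2, int(round(bag_fraction * X.shape[0]))),
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X.to_numpy(), y)
    imp = forest.feature_importances_
    order = sorted(zip(X.columns, imp), key=lambda t: (-t[1], t[0]))
    return [(str(n), float(v)) for n, v in order]


def correlation_filter(
    X: pd.DataFrame,
    ranking: ImportanceRanking,
    threshold: float = 0.8,
    exempt: tuple[str, ...] = (),
) -> ImportanceRanking:
    """Greedy de-correlation: walk the ranking from the top and keep a feature
    only if its absolute Pearson correlation with every already-kept feature
    is <= threshold.  ``exempt`` features (clinical covariates) are always
    kept and do not block others.
    """
    names = [n for n, _ in ranking]
    missing = set(names) - set(X.columns)
    if missing:
        raise ValueError(f"ranking covers features absent from X: {sorted(missing)}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(X[names].to_numpy(), rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate with nothing
    kept: list[int] = []
    out: ImportanceRanking = []
    for idx, (name, gini) in enumerate(ranking):
        if name in exempt:
            out.append((name, gini))
            continue
        if all(corr[idx, j] <= threshold for j in kept):
            kept.append(idx)
            out.append((name, gini))
    return out


def select_features(
    filtered_ranking: ImportanceRanking, max_k: int = MAX_SELECTED
) -> list[str]:
    """Top-k feature names after filtering."""
    return [n for n, _ in filtered_ranking[:max_k]]


def _newton_logit(
    X: np.ndarray, y: np.ndarray, alpha: float, max_iter: int = 60, tol: float = 1e-10
) -> np.ndarray | None:
    """Newton-Raphson MLE of [intercept, coefficients] with optional L2
    penalty ``alpha`` on the non-intercept terms.  Returns None on divergence
    (complete separation drives the unpenalized coefficients off to infinity).
    """
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, alpha)
    pen[0] = 0.0
    for _ in range(max_iter):
        mu = expit(Z @ beta)
        grad = Z.T @ (y - mu) - pen * beta
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (Z * W[:, None]).T @ Z + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if np.abs(beta).max() > _COEF_LIMIT:
            return None
        if np.abs(step).max() < tol:
            return beta
    return beta if np.abs(beta).max() <= _COEF_LIMIT else None


def fit_logistic(X: pd.DataFrame, y: np.ndarray, selected: list[str]) -> FittedLogit:
    """Maximum-likelihood logistic regression on the selected features.

    On complete separation or non-convergence the fit falls back to a small
    ridge penalty so coefficients stay finite; the result is flagged.
    """
    y = np.asarray(y, dtype=np.float64)
    if np.unique(y).size < 2:
        raise ModelingError("labels contain a single class")
    Xm = X[selected].to_numpy(dtype=np.float64) if selected else np.zeros((len(y), 0))
    if Xm.shape[1] == 0 or np.all(Xm.std(axis=0) < 1e-15):
        # intercept-only model: predicted probability = prevalence
        p = float(y.mean())
        logit = np.log(p / (1 - p)) if 0 < p < 1 else 0.0
        return FittedLogit(list(selected), logit, {f: 0.0 for f in selected}, ridged=False)
    ridged = False
    beta = _newton_logit(Xm, y, alpha=0.0)
    if beta is None:
        beta = _newton_logit(Xm, y, alpha=RIDGE_FALLBACK)
        ridged = True
        if beta is None:  # pathological even under ridge: strengthen once
            beta = _newton_logit(Xm, y, alpha=1.0)
            if beta is None:
                raise ModelingError("logistic fit failed to converge")
    coefs = {f: float(c) for f, c in zip(selected, beta[1:])}
    return FittedLogit(list(selected), float(beta[0]), coefs, ridged=ridged)


def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ModelingError("AUC needs both classes")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """(FPR, TPR) points of the empirical ROC curve, threshold-sorted."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return [(float(f), float(t)) for f, t in zip(fpr, tpr)]


def _fit_and_score(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray) -> float:
    """Array-level train/score used by the cross-validation loops."""
    if y_tr.min() == y_tr.max():
        return float(y_tr.mean())
    if X_tr.shape[1] == 0 or np.all(X_tr.std(axis=0) < 1e-15):
        return float(y_tr.mean())
    beta = _newton_logit(X_tr, y_tr.astype(np.float64), alpha=0.0)
    if beta is None:
        beta = _newton_logit(X_tr, y_tr.astype(np.float64), alpha=RIDGE_FALLBACK)
    if beta is None:
        beta = _newton_logit(X_tr, y_tr.astype(np.float64), alpha=1.0)
    if beta is None:
        return float(y_tr.mean())
    return float(expit(beta[0] + X_te @ beta[1:]))


def _loo_scores(X: pd.DataFrame, y: np.ndarray, selected: list[str]) -> np.ndarray:
    """Leave-one-out held-out probabilities over the rows of X."""
    Xm = X[selected].to_numpy(dtype=np.float64)
    scores = np.empty(len(y))
    idx = np.arange(len(y))
    for i in idx:
        tr = idx != i
        scores[i] = _fit_and_score(Xm[tr], y[tr], Xm[i])
    return scores


def loo_bootstrap_auc(
    X: pd.DataFrame,
    y: np.ndarray,
    selected: list[str],
    n_iter: int = 1000,
    seed: int = 0,
    mode: str = "bootstrap_loo",
    max_redraws: int = 100,
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Bootstrap AUC distribution from leave-one-out cross validation.

    mode="bootstrap_loo" (default): each iteration draws a patient-level
    bootstrap resample (redrawn until each class holds at least two unique
    patients, so every LOO training fold keeps both classes), runs LOO over
    the resample's unique patients — fitting on the resample minus every copy
    of the held-out patient — and records one AUC from the held-out scores.

    mode="loo_then_bootstrap": runs LOO once on the full data and bootstraps
    the (score, label) pairs.

    Returns (distribution, median, (2.5, 97.5 percentile) CI).
    """
    y = np.asarray(y)
    n = len(y)
    if n < 4 or np.unique(y).size < 2:
        raise ModelingError("need >= 4 patients with both classes")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_iter)

    if mode == "loo_then_bootstrap":
        base_scores = _loo_scores(X, y, selected)
        for it in range(n_iter):
            for _ in range(max_redraws):
                take = rng.integers(0, n, size=n)
                if np.unique(y[take]).size == 2:
                    break
            else:
                raise ModelingError("could not draw a two-class bootstrap resample")
            aucs[it] = compute_auc(base_scores[take], y[take])
    elif mode == "bootstrap_loo":
        Xm = X[selected].to_numpy(dtype=np.float64)
        for it in range(n_iter):
            for _ in range(max_redraws):
                take = rng.integers(0, n, size=n)
                uniq = np.unique(take)
                if min((y[uniq] == 0).sum(), (y[uniq] == 1).sum()) >= 2:
                    break
            else:
                raise ModelingError("could not draw a two-class bootstrap resample")
            scores = np.empty(uniq.size)
            for j, u in enumerate(uniq):
                tr = take[take != u]
                scores[j] = _fit_and_score(Xm[tr], y[tr], Xm[u])
            aucs[it] = compute_auc(scores, y[uniq])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    median = float(np.median(aucs))
    ci = (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))
    return aucs, median, ci


def build_bin_model(
    endpoint: str,
    bin_bed: float,
    X_bin: pd.DataFrame,
    y_bin: np.ndarray,
    selected: list[str],
    n_iter: int = 1000,
    seed: int = 0,
    mode: str = "bootstrap_loo",
) -> ModelResult:
    """Fit the per-bin logistic model and its bootstrap AUC evaluation."""
    y_bin = np.asarray(y_bin)
    if np.unique(y_bin).size < 2:
        return ModelResult(
            endpoint, bin_bed, list(selected), {}, 0.0,
            np.array([]), float("nan"), (float("nan"), float("nan")), [], unevaluable=True,
        )
    fit = fit_logistic(X_bin, y_bin, selected)
    try:
        aucs, median, ci = loo_bootstrap_auc(
            X_bin, y_bin, selected, n_iter=n_iter, seed=seed, mode=mode
        )
    except ModelingError:
        return ModelResult(
            endpoint, bin_bed, list(selected), fit.coefficients, fit.intercept,
            np.array([]), float("nan"), (float("nan"), float("nan")), [], unevaluable=True,
        )
    final_scores = _loo_scores(X_bin, y_bin, selected)
    roc = roc_points(final_scores, y_bin)
    return ModelResult(
        endpoint, bin_bed, list(selected), fit.coefficients, fit.intercept,
        aucs, median, ci, roc,
    )
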