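"""Partial Least Squares Discriminant Analysis.

PLS2 regression of autoscaled predictors onto one-hot class membership
(components extracted by NIPALS with deflation, via scikit-learn), with
goodness of fit R², cross-validated predictive ability Q² and classification
accuracy from stratified K-fold CV, per-variable Variable Importance in
Projection (VIP) scores, and a label-permutation test of class separation.

VIP for variable j over A components with weights w_a and per-component
explained Y-variance SSY_a:

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

so that mean(VIP^2) = 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["PlsdaError", "PlsdaResult", "fit_plsda", "vip_scores", "permutation_test"]


class PlsdaError(ValueError):
    pass


@dataclass
class PlsdaResult:
    n_components: int
    classes: list
    x_scores: np.ndarray
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    explained_x_variance: np.ndarray
    r2: float
    q2: float
    accuracy: float
    vip: np.ndarray
    permutation_p: float | None = None
    _ssy: np.ndarray = field(default=None, repr=False)

    def metrics(self) -> dict:
        return {
            "r2": self.r2,
            "q2": self.q2,
            "accuracy": self.accuracy,
            "permutation_p": self.permutation_p,
            "vip": self.vip.tolist(),
        }


def _autoscale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.nonzero(sd <= 0)[0]
    if bad.size:
        raise PlsdaError(f"constant predictor column(s) at index {bad.tolist()}")
    return (X - mu) / sd

def _one_hot(y) -> tuple[np.ndarray, list]:
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise PlsdaError("need at least 2 classes")
    Y = np.zeros((len(y), len(classes)))
    for k, c in enumerate(classes):
        Y[y == c, k] = 1.0
    return Y, classes


def fit_plsda(
    X,
    y,
    n_components: int = 2,
    cv_folds: int = 10,
    seed: int = 0,
) -> PlsdaResult:
    """Fit PLS-DA on autoscaled X against one-hot y.

    R² is computed on the full fit; Q² = 1 - PRESS/SS_tot and accuracy (class
    of the largest predicted indicator column) come from stratified
    ``cv_folds``-fold cross-validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise PlsdaError(f"n_components {n_components} exceeds min(n-1, p) = {min(n - 1, p)}")
    Y, classes = _one_hot(y)
    counts = Y.sum(axis=0)
    if np.any(counts < cv_folds):
        small = [c for c, k in zip(classes, counts) if k < cv_folds]
        raise PlsdaError(f"classes {small} have fewer members than cv_folds = {cv_folds}")
    Xs = _autoscale(X)

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Y)
    Yhat = pls.predict(Xs)
    Yc = Y - Y.mean(axis=0)
    ss_tot = float(np.sum(Yc**2))
    r2 = 1.0 - float(np.sum((Y - Yhat) ** 2)) / ss_tot

    # per-component explained variances
    T, W, P_load, Q_load = pls.x_scores_, pls.x_weights_, pls.x_loadings_, pls.y_loadings_
    ssx_tot = float(np.sum(Xs**2))
    t_norms = np.sum(T**2, axis=0)
    explained_x = t_norms * np.sum(P_load**2, axis=0) / ssx_tot
    ssy = t_norms * np.sum(Q_load**2, axis=0)  # Y-variance captured per component

    # cross-validated PRESS and accuracy
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
    press = 0.0
    correct = 0
    for train, test in cv.split(Xs, y):
        mu, sd = X[train].mean(axis=0), X[train].std(axis=0, ddof=1)
        sd[sd <= 0] = 1.0
        m = PLSRegression(n_components=n_components, scale=False)
        m.fit((X[train] - mu) / sd, Y[train])
        pred = m.predict((X[test] - mu) / sd)
        press += float(np.sum((Y[test] - pred) ** 2))
        correct += int(np.sum(np.argmax(pred, axis=1) == np.argmax(Y[test], axis=1)))
    q2 = 1.0 - press / ss_tot
    accuracy = correct / n

    res = PlsdaResult(
        n_components=n_components,
        classes=classes,
        x_scores=T,
        x_weights=W,
        x_loadings=P_load,
        y_loadings=Q_load,
        explained_x_variance=explained_x,
        r2=r2,
        q2=q2,
        accuracy=accuracy,
        vip=np.empty(0),
        _ssy=ssy,
    )
    res.vip = vip_scores(res)
    return res


def vip_scores(result: PlsdaResult) -> np.ndarray:
    """Variable Importance in Projection: weighted sum of squared normalised
    weights, weighted by the Y-variance explained per component."""
    W = result.x_weights
    ssy = result._ssy
    if W.size == 0 or ssy is None:
        raise PlsdaError("need a fitted result with at least one component")
    total = float(np.sum(ssy))
    if total <= 0:
        raise PlsdaError("zero explained Y-variance; VIP undefined")
    p = W.shape[0]
    Wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (Wn2 @ ssy) / total)


def permutation_test(
    X,
    y,
    n_components: int = 2,
    n_perm: int = 999,
    statistic: str = "accuracy",
    cv_folds: int = 10,
    seed: int = 0,
) -> float:
    """Permutation p-value for class separation.

    Refits the model ``n_perm`` times on label-shuffled data and reports
    ``p = (1 + #{perm stat >= observed}) / (n_perm + 1)`` for the chosen
    statistic (cross-validated ``accuracy`` or ``separation`` = R²).
    """
    if n_perm < 1:
        raise PlsdaError("n_perm must be >= 1")
    if statistic not in ("accuracy", "separation"):
        raise PlsdaError(f"unknown permutation statistic {statistic!r}")

    def stat(res: PlsdaResult) -> float:
        return res.accuracy if statistic == "accuracy" else res.r2

    obs = stat(fit_plsda(X, y, n_components, cv_folds=cv_folds, seed=seed))
    rng = np.random.default_rng(seed % (2**31))
    y = np.asarray(y)
    hits = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        res = fit_plsda(X, y_perm, n_components, cv_folds=cv_folds, seed=seed)
        if stat(res) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)
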