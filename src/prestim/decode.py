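"""Penalized logistic decoding of pre-stimulus brain states.

The hypothesis tests are framed as decoding problems: an L2-penalized
logistic regression (C = 1) maps the per-trial brain-state vector to the
recognition report (binary, the *general* decoder) or to the stimulus /
reported category (multinomial softmax, the *specific* decoder).
Performance is the area under the receiver-operating-characteristic curve
(AUROC) of out-of-fold predicted probabilities under leave-one-out
cross-validation; multiclass performance follows the one-vs-rest
averaged-curve recipe.  Decoder weights are made interpretable through the
activation-pattern transform ``A = Σx β`` (covariance-projected weights).

Features (sensors) are z-scored using statistics of the training rows
only; penalized fits are scale-sensitive and sensors are heterogeneous.
Fits are delegated to scikit-learn with deterministic solvers (lbfgs for
binary, Newton-CG for multinomial models), tolerance 1e-6 and at most
1000 iterations, so results are reproducible bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

__all__ = [
    "FittedDecoder",
    "DecodingResult",
    "ActivationPattern",
    "WithinAcrossResult",
    "fit_logistic",
    "loo_cv_decode",
    "auroc_binary",
    "auroc_multiclass_avgcurve",
    "cross_condition_decode",
    "within_vs_across_category_decode",
    "activation_pattern",
    "group_activation_pattern",
]

_TOL = 1e-6
_MAX_ITER = 1000


def _solver_for(n_classes: int) -> str:
    # binary fits use lbfgs; multiclass fits use Newton-CG on the
    # multinomial (softmax) objective
    return "lbfgs" if n_classes == 2 else "newton-cg"


def _newton_logistic(Xs: np.ndarray, y01: np.ndarray, C: float,
                     w0: np.ndarray, tol: float = _TOL,
                     max_iter: int = _MAX_ITER) -> np.ndarray:
    """Damped Newton minimizer of the binary penalized logistic loss.

    Objective (identical to the scikit-learn parameterization):
    ``0.5 ||beta||^2 + C * sum softplus(-s f)`` with unpenalized intercept,
    ``f = Xs beta + b``.  ``w0`` stacks ``(beta, b)``; starting from the
    full-data solution, leave-one-out refits converge in 2-3 steps, which
    is what makes exact leave-one-out affordable.  Used only for the
    cross-validation inner loop; agreement with the scikit-learn fit is
    exercised in the test suite.
    """
    n, d = Xs.shape
    w = w0.copy()
    f = Xs @ w[:d] + w[d]
    p = 1.0 / (1.0 + np.exp(-f))
    g = np.empty(d + 1)
    for _ in range(max_iter):
        r = p - y01
        g[:d] = w[:d] + C * (Xs.T @ r)
        g[d] = C * r.sum()
        gnorm = np.abs(g).max()
        if gnorm < tol:
            break
        weight = p * (1.0 - p)
        XW = Xs * weight[:, None]
        H = np.empty((d + 1, d + 1))
        H[:d, :d] = C * (Xs.T @ XW)
        H[:d, :d][np.diag_indices(d)] += 1.0
        H[:d, d] = C * XW.sum(axis=0)
        H[d, :d] = H[:d, d]
        H[d, d] = C * weight.sum()
        step = np.linalg.solve(H, g)
        # backtracking safeguard: accept only gradient-norm decrease
        scale = 1.0
        for _ in range(30):
            w_new = w - scale * step
            f = Xs @ w_new[:d] + w_new[d]
            p = 1.0 / (1.0 + np.exp(-f))
            r = p - y01
            g_new = np.abs(np.concatenate((w_new[:d] + C * (Xs.T @ r),
                                           [C * r.sum()]))).max()
            if g_new < gnorm:
                break
            scale *= 0.5
        w = w_new
    return w


def _train_stats(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)  # constant sensor -> zero weight
    return mean, scale


@dataclass
class FittedDecoder:
    """A fitted penalized logistic decoder with its feature scaling.

    ``coef``/``intercept`` live in the standardized feature space defined by
    ``mean``/``scale`` (learned on the training rows only).  For binary
    problems ``coef`` has one row and probabilities are logistic in
    ``coef @ x``; for multiclass they are the softmax of the per-class
    scores.
    """

    classes: np.ndarray
    coef: np.ndarray
    intercept: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    C: float = 1.0

    @property
    def n_sensors(self) -> int:
        return self.coef.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        z = self.transform(X) @ self.coef.T + self.intercept
        return z[:, 0] if len(self.classes) == 2 else z

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class probabilities, columns ordered as ``self.classes``."""
        z = self.transform(X) @ self.coef.T + self.intercept
        if len(self.classes) == 2:
            p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack((1.0 - p1, p1))
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class ActivationPattern:
    """Covariance-projected decoder weights ``A = Σx β`` (one row per
    weight vector), with the sensor covariance used."""

    A: np.ndarray
    sigma: np.ndarray


@dataclass
class DecodingResult:
    """Out-of-fold decoding outcome.

    ``proba`` holds one row per evaluated trial (columns ordered as
    ``classes``); for binary problems ``auroc`` scores the positive-class
    column, for multiclass the one-vs-rest averaged curve.
    """

    auroc: float
    proba: np.ndarray
    classes: np.ndarray
    y: np.ndarray
    decoder: FittedDecoder
    fold_index: np.ndarray | None = None
    train_condition: str = ""
    test_condition: str = ""
    activation: ActivationPattern | None = None

    def positive_proba(self, pos_label=None) -> np.ndarray:
        label = self.classes[-1] if pos_label is None else pos_label
        return self.proba[:, list(self.classes).index(label)]


def fit_logistic(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                 standardize: bool = True) -> FittedDecoder:
    """Fit an L2-penalized logistic decoder (C = 1 by default).

    Raises ``ValueError`` when fewer than two classes are present or the
    data contain non-finite values.  The intercept is not penalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_trials, n_sensors) aligned with y")
    if not np.all(np.isfinite(X)):
        raise ValueError("brain-state matrix contains non-finite values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"need at least two classes to fit; got only {classes!r}")
    if standardize:
        mean, scale = _train_stats(X)
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    est = LogisticRegression(
        C=C, solver=_solver_for(classes.size),
        tol=_TOL, max_iter=_MAX_ITER,
    )
    est.fit((X - mean) / scale, y)
    coef, intercept = est.coef_.copy(), est.intercept_.copy()
    return FittedDecoder(
        classes=est.classes_, coef=coef, intercept=intercept,
        mean=mean, scale=scale, C=C,
    )


def auroc_binary(scores: np.ndarray, labels: np.ndarray, pos_label=None) -> float:
    """Area under the binary ROC from scores and labels.

    Computed in its rank (Mann-Whitney) form: the probability that a
    random positive-class trial is scored above a random negative-class
    trial, with ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"binary AUROC needs exactly two classes, got {classes!r}")
    pos = labels == (classes[-1] if pos_label is None else pos_label)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("one class is absent from the labels")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _interp_roc(fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray,
                interpolation: str) -> np.ndarray:
    # collapse vertical segments (duplicate FPR) to their upper TPR
    uniq, inverse = np.unique(fpr, return_inverse=True)
    top = np.zeros(uniq.size)
    np.maximum.at(top, inverse, tpr)
    if interpolation == "linear":
        return np.interp(grid, uniq, top)
    if interpolation == "step":
        idx = np.searchsorted(uniq, grid, side="right") - 1
        return np.where(idx >= 0, top[np.clip(idx, 0, None)], 0.0)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def auroc_multiclass_avgcurve(proba: np.ndarray, labels: np.ndarray,
                              classes: np.ndarray | None = None,
                              grid_points: int = 101,
                              interpolation: str = "linear",
                              average: str = "curve") -> float:
    """Multiclass AUROC: area under the averaged one-vs-rest ROC curve.

    For each class, a one-vs-rest ROC is built from that class's predicted
    probability column; the curves are interpolated onto a common grid of
    ``grid_points`` false-positive rates, averaged vertically, and the area
    is taken by the trapezoid rule.  Linear interpolation between operating
    points is the default (it is the convention consistent with ties
    counting one half, so chance-level all-tied probabilities give exactly
    0.5); right-continuous ``"step"`` interpolation is available.
    ``average="auc"`` instead averages the per-class areas (sensitivity
    variant).  Classes absent from ``labels`` are excluded with a warning.
    """
    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
        if classes.size != proba.shape[1]:
            raise ValueError(
                "cannot infer class order: pass `classes` matching proba columns"
            )
    classes = np.asarray(classes)
    present = np.isin(classes, labels)
    if not present.all():
        warnings.warn(
            f"classes absent from labels excluded from AUROC: "
            f"{list(classes[~present])}", stacklevel=2,
        )
    grid = np.linspace(0.0, 1.0, grid_points)
    curves, areas = [], []
    for j, cls in enumerate(classes):
        if not present[j]:
            continue
        y_bin = labels == cls
        if y_bin.all():
            raise ValueError(f"class {cls!r} is the only class present")
        fpr, tpr, _ = roc_curve(y_bin, proba[:, j], drop_intermediate=False)
        curves.append(_interp_roc(fpr, tpr, grid, interpolation))
        areas.append(auroc_binary(proba[:, j], y_bin.astype(int), pos_label=1))
    if average == "auc":
        return float(np.mean(areas))
    mean_curve = np.mean(curves, axis=0)
    return float(np.trapezoid(mean_curve, grid))


def _score(proba: np.ndarray, y: np.ndarray, classes: np.ndarray,
           pos_label=None) -> float:
    if classes.size == 2:
        label = classes[-1] if pos_label is None else pos_label
        return auroc_binary(proba[:, list(classes).index(label)], y, pos_label=label)
    return auroc_multiclass_avgcurve(proba, y, classes=classes)


def loo_cv_decode(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                  pos_label=None, condition: str = "") -> DecodingResult:
    """Leave-one-out cross-validated decoding.

    Each trial's class probabilities are predicted by a decoder fit on all
    remaining trials (feature scaling re-learned per fold on the training
    rows); the AUROC pools the out-of-fold probabilities.  A class with a
    single trial would vanish from some training fold and raises a
    ``ValueError`` naming it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes for decoding")
    if n < classes.size + 1:
        raise ValueError("need at least n_classes + 1 trials for leave-one-out")
    thin = classes[counts < 2]
    if thin.size:
        raise ValueError(
            f"class {thin[0]!r} has a single trial; some leave-one-out "
            "training set would not contain it"
        )
    s1 = X.sum(axis=0)
    s2 = (X * X).sum(axis=0)
    proba = np.empty((n, classes.size))
    if classes.size == 2:
        # exact Newton refits warm-started from the full-data solution
        y01 = (y == classes[1]).astype(float)
        mean_full, scale_full = s1 / n, np.sqrt(np.clip(s2 / n - (s1 / n) ** 2, 0, None))
        scale_full[scale_full == 0.0] = 1.0
        d = X.shape[1]
        w_full = _newton_logistic((X - mean_full) / scale_full, y01, C,
                                  np.zeros(d + 1))
        for i in range(n):
            mean = (s1 - X[i]) / (n - 1)
            var = (s2 - X[i] * X[i]) / (n - 1) - mean * mean
            scale = np.sqrt(np.clip(var, 0.0, None))
            scale[scale == 0.0] = 1.0
            X_tr = (np.delete(X, i, axis=0) - mean) / scale
            w = _newton_logistic(X_tr, np.delete(y01, i), C, w_full)
            x_i = (X[i] - mean) / scale
            p1 = 1.0 / (1.0 + np.exp(-(x_i @ w[:d] + w[d])))
            proba[i] = (1.0 - p1, p1)
    else:
        est = LogisticRegression(
            C=C, solver=_solver_for(classes.size),
            tol=_TOL, max_iter=_MAX_ITER, warm_start=True,
        )
        for i in range(n):
            mean = (s1 - X[i]) / (n - 1)
            var = (s2 - X[i] * X[i]) / (n - 1) - mean * mean
            scale = np.sqrt(np.clip(var, 0.0, None))
            scale[scale == 0.0] = 1.0
            X_tr = (np.delete(X, i, axis=0) - mean) / scale
            est.fit(X_tr, np.delete(y, i))
            proba[i] = est.predict_proba(((X[i] - mean) / scale)[None, :])[0]
    auroc = _score(proba, y, classes, pos_label)
    return DecodingResult(
        auroc=auroc, proba=proba, classes=classes, y=y,
        decoder=fit_logistic(X, y, C=C), fold_index=np.arange(n),
        train_condition=condition, test_condition=condition,
    )


def cross_condition_decode(X_train: np.ndarray, y_train: np.ndarray,
                           X_test: np.ndarray, y_test: np.ndarray,
                           C: float = 1.0, pos_label=None,
                           train_indices: np.ndarray | None = None,
                           test_indices: np.ndarray | None = None,
                           train_condition: str = "train",
                           test_condition: str = "test") -> DecodingResult:
    """Fit once on one condition, evaluate AUROC on a disjoint condition.

    No cross-validation is needed because the test trials never enter the
    fit.  Overlapping trial indices (when given), or literally identical
    train and test sets, raise a ``ValueError`` as a leakage guard.
    """
    if train_indices is not None and test_indices is not None:
        shared = np.intersect1d(train_indices, test_indices)
        if shared.size:
            raise ValueError(f"train and test conditions share trials: {shared[:5]}")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape == X_test.shape and np.array_equal(X_train, X_test):
        raise ValueError("train and test sets are identical; cross-condition "
                         "decoding requires disjoint conditions")
    decoder = fit_logistic(X_train, y_train, C=C)
    proba = decoder.predict_proba(X_test)
    auroc = _score(proba, np.asarray(y_test), decoder.classes, pos_label)
    return DecodingResult(
        auroc=auroc, proba=proba, classes=decoder.classes,
        y=np.asarray(y_test), decoder=decoder,
        train_condition=train_condition, test_condition=test_condition,
    )


@dataclass
class WithinAcrossResult:
    """Paired within-category and across-category decoding scores."""

    within: dict = field(default_factory=dict)
    across: dict = field(default_factory=dict)

    @property
    def within_mean(self) -> float:
        return float(np.mean(list(self.within.values())))

    @property
    def across_mean(self) -> float:
        return float(np.mean(list(self.across.values())))


def within_vs_across_category_decode(X: np.ndarray, y: np.ndarray,
                                     categories: np.ndarray,
                                     C: float = 1.0, pos_label=None
                                     ) -> WithinAcrossResult:
    """Compare recognition decoding within vs. across stimulus categories.

    Within: leave-one-out decoding restricted to each category's trials.
    Across: fit on all trials of category *a*, test on category *b*, over
    every ordered pair ``a != b``.  Categories (or pairs) lacking both
    recognition outcomes are skipped with a warning.  If the same latent
    process drives recognition in every category, the two score sets have
    the same expectation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    categories = np.asarray(categories)
    result = WithinAcrossResult()
    cats = np.unique(categories)
    usable = []
    for cat in cats:
        sel = categories == cat
        if np.unique(y[sel]).size < 2 or np.min(np.unique(y[sel], return_counts=True)[1]) < 2:
            warnings.warn(f"category {cat!r} lacks both recognition outcomes; skipped",
                          stacklevel=2)
            continue
        usable.append(cat)
        result.within[cat] = loo_cv_decode(
            X[sel], y[sel], C=C, pos_label=pos_label, condition=f"within:{cat}"
        ).auroc
    for a, b in permutations(usable, 2):
        sel_a, sel_b = categories == a, categories == b
        result.across[(a, b)] = cross_condition_decode(
            X[sel_a], y[sel_a], X[sel_b], y[sel_b], C=C, pos_label=pos_label,
            train_condition=f"cat:{a}", test_condition=f"cat:{b}",
        ).auroc
    return result


def activation_pattern(decoder: FittedDecoder, X: np.ndarray) -> ActivationPattern:
    """Activation patterns ``A = Σx β`` of a fitted decoder.

    ``Σx`` is the empirical covariance of the decoder's training data in
    its standardized feature space (the space the weights act on); the
    result has one pattern row per weight vector and is interpretable as
    the sensor signal pattern the decoder tracks.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("covariance undefined for fewer than two trials")
    Xs = decoder.transform(X)
    sigma = np.cov(Xs, rowvar=False)
    return ActivationPattern(A=decoder.coef @ sigma.T, sigma=sigma)


def group_activation_pattern(patterns: list[ActivationPattern]) -> np.ndarray:
    """Group-level pattern: element-wise median across subject patterns."""
    return np.median([p.A for p in patterns], axis=0)
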