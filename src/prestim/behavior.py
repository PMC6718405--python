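"""Behavioral quantification of the decoded spontaneous processes.

Recognition reports are scored in the signal-detection framework: real
images are signal trials, scrambled images are noise trials, a "yes"
report is a hit on real and a false alarm on scrambled images.  With
``Z`` the inverse normal CDF,

    d' = Z(HR) - Z(FAR)          (sensitivity)
    c  = -(Z(HR) + Z(FAR)) / 2   (criterion; positive = conservative)

Degenerate rates are replaced before the Z-transform (hit rate 1 ->
1 - 1/(2N_real), false-alarm rate 0 -> 1/(2N_scr), plus the symmetric
guards).  Category reports are scored as 4AFC percent correct, with
scrambled trials scored against the category of their source image.

The decoded decision variables split trials into high/low predicted-
probability groups per process — general: P(recognition) > 0.5;
specific: the objective category is the strict argmax of the predicted
category probabilities — and the SDT metrics are compared between groups,
which is where the double dissociation (general moves c, specific moves
d') shows up.  Prediction uncertainty is the base-n entropy of the
category probabilities (0 = one-hot, 1 = uniform), and pupil linkage
compares pre-stimulus pupil means across the splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .decode import loo_cv_decode
from .inference import PairedTestResult, paired_t, wilcoxon_signed_rank

__all__ = [
    "SDTMetrics",
    "EntropyResult",
    "SubjectDecisionVariables",
    "SubjectDissociation",
    "DissociationResult",
    "compute_sdt",
    "sdt_from_rates",
    "categorization_accuracy",
    "split_general",
    "split_specific",
    "entropy",
    "general_decision_variables",
    "specific_decision_variables",
    "subject_decision_variables",
    "subject_dissociation",
    "dissociation_table",
    "trial_history",
    "pupil_linkage",
]


@dataclass
class SDTMetrics:
    """Signal-detection metrics with correction bookkeeping."""

    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    criterion: float
    n_real: int
    n_scr: int
    corrections_applied: tuple[str, ...] = ()


def _as_yes(reports) -> np.ndarray:
    arr = np.asarray(reports)
    if arr.dtype == bool:
        return arr
    return arr.astype(str) == "yes"


def sdt_from_rates(hr: float, far: float, n_real: int, n_scr: int) -> SDTMetrics:
    """d' and criterion from raw hit and false-alarm rates.

    Degenerate rates are corrected to 1/(2N) from 0 and 1 - 1/(2N) from 1
    before the Z-transform (the 0-rate guards extend the published
    correction symmetrically).
    """
    corrections = []
    if hr >= 1.0:
        hr = 1.0 - 1.0 / (2 * n_real)
        corrections.append("HR=1")
    elif hr <= 0.0:
        hr = 1.0 / (2 * n_real)
        corrections.append("HR=0")
    if far <= 0.0:
        far = 1.0 / (2 * n_scr)
        corrections.append("FAR=0")
    elif far >= 1.0:
        far = 1.0 - 1.0 / (2 * n_scr)
        corrections.append("FAR=1")
    z_hr, z_far = norm.ppf(hr), norm.ppf(far)
    return SDTMetrics(
        hit_rate=float(hr),
        false_alarm_rate=float(far),
        d_prime=float(z_hr - z_far),
        criterion=float(-(z_hr + z_far) / 2.0),
        n_real=n_real,
        n_scr=n_scr,
        corrections_applied=tuple(corrections),
    )


def compute_sdt(recognition_reports, is_real) -> SDTMetrics:
    """Hit/false-alarm rates, d' and criterion from recognition reports.

    ``recognition_reports`` may be booleans or "yes"/"no" strings.  Raises
    if either stimulus class is absent; rate corrections as in
    :func:`sdt_from_rates`.
    """
    yes = _as_yes(recognition_reports)
    real = np.asarray(is_real, dtype=bool)
    n_real = int(real.sum())
    n_scr = int((~real).sum())
    if n_real == 0 or n_scr == 0:
        missing = "real" if n_real == 0 else "scrambled"
        raise ValueError(f"cannot compute SDT metrics: no {missing} trials present")
    return sdt_from_rates(float(yes[real].mean()), float(yes[~real].mean()),
                          n_real, n_scr)


def categorization_accuracy(category_reports, truth_categories, mask=None) -> float:
    """Percent of category reports matching the (source-image) category."""
    reports = np.asarray(category_reports).astype(str)
    truth = np.asarray(truth_categories).astype(str)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        reports, truth = reports[mask], truth[mask]
    if reports.size == 0:
        raise ValueError("no trials selected for categorization accuracy")
    return float(100.0 * np.mean(reports == truth))


def split_general(p_recognition) -> np.ndarray:
    """High-probability group of the general process: P(recognition) > 0.5.

    A probability of exactly 0.5 predicts "yes" no more than "no", so the
    trial goes to the low group (strict inequality).
    """
    return np.asarray(p_recognition, dtype=float) > 0.5


def split_specific(proba: np.ndarray, classes, objective_categories) -> np.ndarray:
    """High group of the specific process: objective category is the strict
    argmax of the predicted category probabilities (ties at the maximum go
    to the low group)."""
    proba = np.asarray(proba, dtype=float)
    classes = list(np.asarray(classes))
    objective = np.asarray(objective_categories).astype(str)
    col = np.array([classes.index(c) for c in objective])
    p_obj = proba[np.arange(proba.shape[0]), col]
    others = proba.copy()
    others[np.arange(proba.shape[0]), col] = -np.inf
    return p_obj > others.max(axis=1)


@dataclass
class EntropyResult:
    """Per-trial normalized entropy of category predictions with its
    median split (``high`` marks the more-uncertain half; group sizes
    differ by at most one, ties broken by trial order)."""

    H: np.ndarray
    n: int
    high: np.ndarray


def entropy(proba: np.ndarray, n: int | None = None) -> EntropyResult:
    """Base-n Shannon entropy of per-trial class probabilities.

    With the 0*log 0 = 0 convention, H is 0 for a one-hot prediction and 1
    for the uniform one.  Probability rows must be non-negative and sum
    to 1.
    """
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    if np.any(proba < -1e-12):
        raise ValueError("negative probabilities")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("probability rows must sum to 1")
    if n is None:
        n = proba.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(proba > 0.0, proba * np.log(proba), 0.0)
    H = -terms.sum(axis=1) / np.log(n)
    order = np.argsort(H, kind="stable")
    high = np.zeros(H.size, dtype=bool)
    high[order[(H.size + 1) // 2:]] = True
    return EntropyResult(H=H, n=int(n), high=high)


# ---------------------------------------------------------------------------
# Decision variables and the dissociation analysis
# ---------------------------------------------------------------------------


@dataclass
class SubjectDecisionVariables:
    """Per-trial decision variables of one subject.

    Both models are trained on real-image trials only: the general model
    on all real trials (recognition target), the specific model on
    recognized real trials (objective-category target).  Probabilities for
    the training trials come from leave-one-out cross-validation; trials
    outside the training condition (scrambled for both models, plus
    unrecognized real for the specific model) are predicted by the model
    fit to the full training condition.
    """

    trials: pd.DataFrame  # copy with p_recognition / general_hi / specific_hi
    category_proba: np.ndarray  # (n_trials, n_categories)
    classes: np.ndarray
    general_auroc: float
    specific_auroc: float


def general_decision_variables(X: np.ndarray, trials: pd.DataFrame,
                               C: float = 1.0) -> tuple[np.ndarray, float]:
    """Per-trial P(recognition) from the general (recognition) decoder.

    The decoder is fit to real-image trials; real-trial probabilities are
    out-of-fold (leave-one-out), scrambled-trial probabilities come from
    the model fit to all real trials.  Returns the probability vector
    aligned to ``trials`` and the real-trial AUROC.
    """
    X = np.asarray(X, dtype=float)
    real = trials["is_real"].to_numpy(dtype=bool)
    yes = _as_yes(trials["recognition_report"].to_numpy())
    res = loo_cv_decode(X[real], yes[real].astype(int), C=C, pos_label=1,
                        condition="real")
    p_rec = np.empty(len(trials))
    p_rec[real] = res.positive_proba(pos_label=1)
    if (~real).any():
        p_rec[~real] = res.decoder.predict_proba(X[~real])[:, 1]
    return p_rec, res.auroc


def specific_decision_variables(X: np.ndarray, trials: pd.DataFrame,
                                C: float = 1.0
                                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-trial category probabilities from the specific decoder.

    The decoder is fit to recognized real-image trials (objective-category
    target); those trials get out-of-fold probabilities, every other trial
    is predicted by the model fit to all recognized real trials.  Returns
    ``(proba, classes, auroc)``.
    """
    X = np.asarray(X, dtype=float)
    real = trials["is_real"].to_numpy(dtype=bool)
    yes = _as_yes(trials["recognition_report"].to_numpy())
    objective = trials["objective_category"].astype(str).to_numpy()
    rec_real = real & yes
    res = loo_cv_decode(X[rec_real], objective[rec_real], C=C,
                        condition="recognized-real")
    proba = np.empty((len(trials), res.classes.size))
    proba[rec_real] = res.proba
    rest = ~rec_real
    if rest.any():
        proba[rest] = res.decoder.predict_proba(X[rest])
    return proba, res.classes, res.auroc


def subject_decision_variables(X: np.ndarray, trials: pd.DataFrame,
                               C: float = 1.0) -> SubjectDecisionVariables:
    """Compute general and specific decision variables for one subject."""
    trials = trials.reset_index(drop=True)
    objective = trials["objective_category"].astype(str).to_numpy()
    p_rec, gen_auroc = general_decision_variables(X, trials, C=C)
    proba, classes, spec_auroc = specific_decision_variables(X, trials, C=C)

    out = trials.copy()
    out["p_recognition"] = p_rec
    out["general_hi"] = split_general(p_rec)
    out["specific_hi"] = split_specific(proba, classes, objective)
    return SubjectDecisionVariables(
        trials=out, category_proba=proba, classes=classes,
        general_auroc=gen_auroc, specific_auroc=spec_auroc,
    )


@dataclass
class SubjectDissociation:
    """Per-model, per-group behavioral metrics for one subject."""

    metrics: pd.DataFrame  # rows: model x group
    flagged: bool = False  # some group lacked a stimulus class


_METRIC_COLS = ["hit_rate", "false_alarm_rate", "d_prime", "criterion",
                "accuracy_real", "accuracy_scrambled"]


def subject_dissociation(dv: SubjectDecisionVariables) -> SubjectDissociation:
    """Group-wise SDT metrics and 4AFC accuracies for both model splits."""
    t = dv.trials
    real = t["is_real"].to_numpy(dtype=bool)
    yes = _as_yes(t["recognition_report"].to_numpy())
    reports = t["category_report"].to_numpy()
    truth = t["objective_category"].astype(str).to_numpy()
    rows = []
    flagged = False
    for model, hi in (("general", t["general_hi"].to_numpy()),
                      ("specific", t["specific_hi"].to_numpy())):
        for group, sel in (("hi", hi), ("lo", ~hi)):
            if not (sel & real).any() or not (sel & ~real).any():
                flagged = True
                rows.append(dict(model=model, group=group,
                                 **{c: np.nan for c in _METRIC_COLS}))
                continue
            sdt = compute_sdt(yes[sel], real[sel])
            rows.append(dict(
                model=model, group=group,
                hit_rate=sdt.hit_rate, false_alarm_rate=sdt.false_alarm_rate,
                d_prime=sdt.d_prime, criterion=sdt.criterion,
                accuracy_real=categorization_accuracy(reports, truth, sel & real),
                accuracy_scrambled=categorization_accuracy(reports, truth, sel & ~real),
            ))
    return SubjectDissociation(metrics=pd.DataFrame(rows), flagged=flagged)


@dataclass
class DissociationResult:
    """Group-level dissociation analysis.

    ``table`` holds subject-mean metrics per model x group; ``tests`` maps
    ``(model, metric)`` to the paired test of hi vs lo across subjects
    (paired t for d' and criterion, Wilcoxon signed-rank for rates and
    accuracies, following the convention for bounded variables).
    """

    table: pd.DataFrame
    tests: dict = field(default_factory=dict)
    per_subject: pd.DataFrame | None = None
    n_flagged: int = 0


def dissociation_table(subject_results: list[SubjectDissociation]) -> DissociationResult:
    """Aggregate subject dissociation metrics and test hi-vs-lo contrasts."""
    frames = []
    n_flagged = 0
    for i, res in enumerate(subject_results):
        if res.flagged:
            n_flagged += 1
            warnings.warn(f"subject {i} has an empty split group; excluded",
                          stacklevel=2)
            continue
        frame = res.metrics.copy()
        frame["subject"] = i
        frames.append(frame)
    if not frames:
        raise ValueError("no usable subjects for the dissociation analysis")
    per_subject = pd.concat(frames, ignore_index=True)
    table = (per_subject
             .groupby(["model", "group"], sort=True)[_METRIC_COLS]
             .mean()
             .reset_index())
    tests: dict[tuple[str, str], PairedTestResult] = {}
    wide = per_subject.pivot(index="subject", columns=["model", "group"])
    for model in ("general", "specific"):
        for metric in _METRIC_COLS:
            hi = wide[(metric, model, "hi")].to_numpy()
            lo = wide[(metric, model, "lo")].to_numpy()
            if metric in ("d_prime", "criterion"):
                tests[(model, metric)] = paired_t(hi, lo)
            else:
                tests[(model, metric)] = wilcoxon_signed_rank(hi, lo)
    return DissociationResult(table=table, tests=tests,
                              per_subject=per_subject, n_flagged=n_flagged)


# ---------------------------------------------------------------------------
# Trial history and pupil linkage
# ---------------------------------------------------------------------------


def trial_history(trials: pd.DataFrame, p_recognition=None,
                  predicted_category=None, max_lag: int = 5) -> dict:
    """Serial-dependence diagnostics of reports and decision variables.

    Returns a dict with, per lag k, the recognition-rate difference after a
    previous "yes" vs "no" report; the recognition-rate difference for
    repeated vs changed objective category (lag 1); the rate at which the
    model-predicted category matches the previous objective category; and
    the lag-1 autocorrelation of the recognition decision variable.
    """
    if len(trials) <= max_lag:
        raise ValueError("fewer trials than the maximum history lag")
    yes = _as_yes(trials["recognition_report"].to_numpy()).astype(float)
    objective = trials["objective_category"].astype(str).to_numpy()
    out: dict = {"recognition_rate_after_yes_minus_no": {}}
    for k in range(1, max_lag + 1):
        prev = yes[:-k]
        cur = yes[k:]
        after_yes = cur[prev == 1.0]
        after_no = cur[prev == 0.0]
        diff = (after_yes.mean() if after_yes.size else np.nan) - \
               (after_no.mean() if after_no.size else np.nan)
        out["recognition_rate_after_yes_minus_no"][k] = float(diff)
    same = objective[1:] == objective[:-1]
    out["repeat_category_recognition_diff"] = float(
        yes[1:][same].mean() - yes[1:][~same].mean()
    )
    if predicted_category is not None:
        pred = np.asarray(predicted_category).astype(str)
        out["predicted_matches_previous_objective_rate"] = float(
            np.mean(pred[1:] == objective[:-1])
        )
    if p_recognition is not None:
        p = np.asarray(p_recognition, dtype=float)
        p0, p1 = p[:-1], p[1:]
        denom = p0.std() * p1.std()
        out["dv_lag1_autocorrelation"] = float(
            np.mean((p0 - p0.mean()) * (p1 - p1.mean())) / denom
        ) if denom > 0 else np.nan
    return out


@dataclass
class PupilLinkageResult:
    """Across-subject comparison of pre-stimulus pupil size between the
    general hi/lo split and the entropy median split."""

    general_hi_means: np.ndarray
    general_lo_means: np.ndarray
    entropy_high_means: np.ndarray
    entropy_low_means: np.ndarray
    general_test: PairedTestResult
    entropy_test: PairedTestResult


def pupil_linkage(subjects: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
                  ) -> PupilLinkageResult:
    """Link pupil size to the decoded processes across subjects.

    ``subjects`` is a list of ``(pupil_means, general_hi, entropy_high)``
    per-trial arrays; trials with missing pupil means (NaN) are excluded.
    Group means are computed per subject and compared across subjects with
    Wilcoxon signed-rank tests.
    """
    g_hi, g_lo, e_hi, e_lo = [], [], [], []
    for pupil, general_hi, entropy_high in subjects:
        pupil = np.asarray(pupil, dtype=float)
        ok = np.isfinite(pupil)
        general_hi = np.asarray(general_hi, dtype=bool)
        entropy_high = np.asarray(entropy_high, dtype=bool)
        g_hi.append(pupil[ok & general_hi].mean())
        g_lo.append(pupil[ok & ~general_hi].mean())
        e_hi.append(pupil[ok & entropy_high].mean())
        e_lo.append(pupil[ok & ~entropy_high].mean())
    g_hi, g_lo = np.asarray(g_hi), np.asarray(g_lo)
    e_hi, e_lo = np.asarray(e_hi), np.asarray(e_lo)
    return PupilLinkageResult(
        general_hi_means=g_hi, general_lo_means=g_lo,
        entropy_high_means=e_hi, entropy_low_means=e_lo,
        general_test=wilcoxon_signed_rank(g_hi, g_lo),
        entropy_test=wilcoxon_signed_rank(e_hi, e_lo),
    )
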