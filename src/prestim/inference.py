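"""Group-level significance machinery.

Decoder significance follows a group-level label-permutation scheme: the
decoding analysis is repeated with labels shuffled across trials, the
per-subject scores are averaged, and the p-value is the fraction of
permuted group means that reach the actual group mean.  Model comparisons
use two-tailed Wilcoxon signed-rank or paired t tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy import stats

from .decode import loo_cv_decode

__all__ = [
    "PermutationNull",
    "PairedTestResult",
    "permutation_test_group",
    "wilcoxon_signed_rank",
    "paired_t",
]


@dataclass
class PermutationNull:
    """Label-permutation null for a group-mean decoding score.

    ``p_value`` is the plain exceedance fraction ``#{permuted >= actual}/B``
    (ties count against the actual score), which can legitimately be 0;
    ``p_value_smoothed`` is the (k+1)/(B+1) estimate that cannot.
    """

    B: int
    permuted_scores: np.ndarray
    actual_score: float
    p_value: float
    p_value_smoothed: float
    subject_scores: np.ndarray


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    test_name: str
    n_pairs: int
    degenerate: bool = False


def _subject_entropy(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    return zlib.crc32(str(key).encode())


def _default_decode(X: np.ndarray, y: np.ndarray) -> float:
    return loo_cv_decode(X, y).auroc


def permutation_test_group(
    subjects: Mapping[object, tuple] | Iterable[tuple],
    decode_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
    B: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Group-level label-permutation test of a decoding analysis.

    Parameters
    ----------
    subjects
        Mapping ``subject_id -> (X, y)`` or iterable of ``(X, y)`` pairs.
        With a mapping, each subject's permutation stream is derived from
        ``(seed, subject_id)``, making the p-value invariant to subject
        ordering.
    decode_fn
        Callable ``(X, labels) -> score`` run once with the true labels and
        once per permutation with labels shuffled across trials (shuffling
        all labels shuffles every leave-one-out training set).  Defaults to
        leave-one-out logistic decoding AUROC.
    B
        Number of permutations (1000 for recording-faithful runs; smaller
        values keep desk-scale runs fast).
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    decode_fn = decode_fn or _default_decode
    if isinstance(subjects, Mapping):
        items = [(k, X, y) for k, (X, y) in subjects.items()]
    else:
        items = [(i, X, y) for i, (X, y) in enumerate(subjects)]
    if len(items) < 2:
        raise ValueError("group-level permutation test needs at least two subjects")

    subject_scores = np.array([decode_fn(X, np.asarray(y)) for _, X, y in items])
    actual = float(subject_scores.mean())

    perm = np.zeros((len(items), B))
    for row, (key, X, y) in enumerate(items):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), _subject_entropy(key)])
        )
        y = np.asarray(y)
        for b in range(B):
            perm[row, b] = decode_fn(X, rng.permutation(y))
    perm_means = perm.mean(axis=0)
    k = int((perm_means >= actual).sum())
    return PermutationNull(
        B=B,
        permuted_scores=perm_means,
        actual_score=actual,
        p_value=k / B,
        p_value_smoothed=(k + 1) / (B + 1),
        subject_scores=subject_scores,
    )


def wilcoxon_signed_rank(a, b=None) -> PairedTestResult:
    """Two-tailed Wilcoxon signed-rank test on paired values.

    Accepts either a vector of differences or two paired vectors.
    Zero differences are dropped (the common convention); if every
    difference is zero the result is flagged degenerate with p = 1.
    """
    diffs = np.asarray(a, dtype=float) if b is None else np.asarray(a) - np.asarray(b)
    nonzero = diffs[diffs != 0.0]
    if nonzero.size == 0:
        return PairedTestResult(
            statistic=float("nan"), p_value=1.0,
            test_name="wilcoxon_signed_rank", n_pairs=diffs.size, degenerate=True,
        )
    res = stats.wilcoxon(nonzero, alternative="two-sided", zero_method="wilcox")
    return PairedTestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        test_name="wilcoxon_signed_rank", n_pairs=int(nonzero.size),
    )


def paired_t(a, b=None) -> PairedTestResult:
    """Two-tailed paired t test on paired values (or their differences).

    A difference vector with zero variance has no defined t statistic and
    is reported as degenerate.
    """
    diffs = np.asarray(a, dtype=float) if b is None else np.asarray(a) - np.asarray(b)
    if diffs.size < 2 or np.std(diffs, ddof=1) == 0.0:
        return PairedTestResult(
            statistic=float("nan"), p_value=float("nan"),
            test_name="paired_t", n_pairs=int(diffs.size), degenerate=True,
        )
    res = stats.ttest_1samp(diffs, 0.0)
    return PairedTestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        test_name="paired_t", n_pairs=int(diffs.size),
    )
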