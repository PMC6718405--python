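"""Decoding: penalized logistic fits, AUROC routines, cross-validation,
cross-condition transfer and activation patterns."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from prestim.decode import (
    FittedDecoder,
    activation_pattern,
    auroc_binary,
    auroc_multiclass_avgcurve,
    cross_condition_decode,
    fit_logistic,
    group_activation_pattern,
    loo_cv_decode,
    within_vs_across_category_decode,
)


def brute_force_auroc(scores, labels, pos_label=1):
    """Concordant-pair counting oracle with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == pos_label]
    neg = scores[np.asarray(labels) != pos_label]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestFitLogistic:
    def test_probability_half_at_decision_boundary(self):
        dec = FittedDecoder(classes=np.array([0, 1]),
                            coef=np.array([[1.0, -2.0]]),
                            intercept=np.array([0.5]),
                            mean=np.zeros(2), scale=np.ones(2))
        x = np.array([[0.5, 0.5]])  # coef @ x + b = 0
        assert dec.predict_proba(x)[0, 1] == pytest.approx(0.5)

    def test_separable_toy_sign_and_accuracy(self):
        X = np.array([[-1.0], [-1.0], [-1.0], [1.0], [1.0], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        dec = fit_logistic(X, y)
        assert dec.coef[0, 0] > 0
        assert np.array_equal(dec.predict(X), y)

    def test_gradient_vanishes_at_solution(self, rng):
        """The fitted weights must zero the gradient of the penalized loss
        0.5*||b||^2 + C*sum log(1 + exp(-s*f))."""
        X = rng.standard_normal((60, 5))
        y = (X[:, 0] + 0.5 * rng.standard_normal(60) > 0).astype(int)
        C = 1.0
        dec = fit_logistic(X, y, C=C, standardize=False)
        beta, b = dec.coef[0], dec.intercept[0]
        p = 1.0 / (1.0 + np.exp(-(X @ beta + b)))
        grad_beta = beta + C * X.T @ (p - y)
        grad_b = C * (p - y).sum()
        assert np.abs(np.concatenate([grad_beta, [grad_b]])).max() < 1e-4

    def test_wrapper_matches_sklearn_probabilities(self, rng):
        X = rng.standard_normal((50, 4))
        y = (X @ rng.standard_normal(4) > 0).astype(int)
        dec = fit_logistic(X, y, standardize=False)
        ref = LogisticRegression(C=1.0, solver="lbfgs", tol=1e-6,
                                 max_iter=1000).fit(X, y)
        assert np.allclose(dec.predict_proba(X), ref.predict_proba(X), atol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_logistic(np.zeros((5, 2)), np.ones(5))

    def test_constant_sensor_gets_zero_weight(self, rng):
        X = rng.standard_normal((40, 3))
        X[:, 2] = 7.0
        y = (X[:, 0] > 0).astype(int)
        dec = fit_logistic(X, y)
        assert dec.coef[0, 2] == pytest.approx(0.0, abs=1e-8)


class TestBinaryAuroc:
    def test_worked_example(self):
        assert auroc_binary([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auroc_binary([5, 4, 3, 2, 1], [1, 1, 1, 0, 0], pos_label=1) == 1.0

    def test_all_ties_is_chance(self):
        assert auroc_binary([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle_exhaustively(self, rng):
        """Randomized battery with heavy ties, n <= 12: exact agreement."""
        for _ in range(300):
            n = rng.integers(2, 13)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 4, size=n).astype(float)  # many ties
            assert auroc_binary(scores, labels, pos_label=1) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)),
                    min_size=4, max_size=12),
           st.integers(0, 2**12 - 1))
    def test_invariance_under_monotone_transform(self, scores, label_bits):
        labels = np.array([(label_bits >> i) & 1 for i in range(len(scores))])
        if labels.min() == labels.max():
            return
        scores = np.asarray(scores)
        base = auroc_binary(scores, labels, pos_label=1)
        assert auroc_binary(3.0 * scores + 7.0, labels, pos_label=1) == pytest.approx(base)
        assert auroc_binary(np.tanh(scores / 50.0), labels, pos_label=1) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_binary([1.0, 2.0], [1, 1])


class TestMulticlassAuroc:
    def test_one_hot_perfect(self):
        proba = np.eye(4)[[0, 1, 2, 3, 0, 1]]
        labels = np.array([0, 1, 2, 3, 0, 1])
        assert auroc_multiclass_avgcurve(proba, labels) == pytest.approx(1.0)

    def test_uniform_is_chance(self):
        proba = np.full((8, 4), 0.25)
        labels = np.array([0, 1, 2, 3] * 2)
        assert auroc_multiclass_avgcurve(proba, labels) == pytest.approx(0.5)

    def test_pinned_mixed_instance(self):
        """Frozen value computed with an independent threshold-enumeration
        oracle (per-class operating points, upper envelope at duplicated
        FPR, linear interpolation, averaged, trapezoid)."""
        proba = np.array([[.7, .1, .1, .1], [.4, .3, .2, .1], [.1, .6, .2, .1],
                          [.2, .2, .3, .3], [.05, .15, .7, .1],
                          [.25, .25, .25, .25], [.3, .1, .2, .4], [.1, .2, .3, .4]])
        labels = np.array([0, 1, 1, 0, 2, 2, 3, 3])
        got = auroc_multiclass_avgcurve(proba, labels, classes=np.arange(4))
        assert got == pytest.approx(0.9270875, abs=1e-9)
        # sensitivity variant: mean of per-class pair-counting AUCs
        got_auc = auroc_multiclass_avgcurve(proba, labels, classes=np.arange(4),
                                            average="auc")
        assert got_auc == pytest.approx(0.8958333333333334, abs=1e-9)

    def test_absent_class_excluded_with_warning(self):
        proba = np.full((4, 3), 1 / 3)
        labels = np.array([0, 0, 1, 1])  # class 2 never occurs
        with pytest.warns(UserWarning, match="absent"):
            value = auroc_multiclass_avgcurve(proba, labels, classes=np.arange(3))
        assert value == pytest.approx(0.5)


class TestLooCv:
    def test_one_prediction_per_trial(self, rng):
        X = rng.standard_normal((25, 4))
        y = rng.integers(0, 2, size=25)
        y[:2] = [0, 1]
        res = loo_cv_decode(X, y)
        assert res.proba.shape == (25, 2)
        assert np.allclose(res.proba.sum(axis=1), 1.0)
        assert res.fold_index.tolist() == list(range(25))

    def test_newton_path_matches_per_fold_sklearn(self, rng):
        """The warm-started Newton inner loop must reproduce per-fold
        scikit-learn fits exactly (same objective, same scaling)."""
        X = rng.standard_normal((30, 5))
        y = (X[:, 0] + rng.standard_normal(30) > 0).astype(int)
        res = loo_cv_decode(X, y)
        ref = np.empty(30)
        for i in range(30):
            tr = np.ones(30, dtype=bool)
            tr[i] = False
            mean = X[tr].mean(axis=0)
            scale = X[tr].std(axis=0)
            scale[scale == 0] = 1.0
            est = LogisticRegression(C=1.0, solver="lbfgs", tol=1e-10,
                                     max_iter=5000)
            est.fit((X[tr] - mean) / scale, y[tr])
            ref[i] = est.predict_proba(((X[i] - mean) / scale)[None, :])[0, 1]
        assert np.allclose(res.proba[:, 1], ref, atol=1e-5)

    def test_row_permutation_permutes_predictions(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([0, 1] * 10)
        perm = rng.permutation(20)
        a = loo_cv_decode(X, y)
        b = loo_cv_decode(X[perm], y[perm])
        assert np.allclose(a.proba[perm], b.proba, atol=1e-8)
        assert a.auroc == pytest.approx(b.auroc, abs=1e-10)

    def test_null_labels_give_chance_auroc(self, rng):
        """Out-of-fold AUROC is chance-level on permuted labels.  (At very
        small n, leave-one-out carries a known pessimistic bias, so the
        chance anchor is checked at a few hundred trials.)"""
        scores = []
        for _ in range(8):
            X = rng.standard_normal((160, 6))
            y = rng.permutation([0] * 80 + [1] * 80)
            scores.append(loo_cv_decode(X, y).auroc)
        assert abs(np.mean(scores) - 0.5) < 0.04

    def test_planted_signal_approaches_perfect(self, rng):
        y = np.array([0, 1] * 20)
        X = np.outer(y * 2.0 - 1.0, np.ones(4)) + 0.05 * rng.standard_normal((40, 4))
        assert loo_cv_decode(X, y).auroc > 0.95

    def test_singleton_class_error_names_it(self):
        X = np.zeros((6, 2))
        y = np.array(["a", "a", "a", "a", "a", "rare"])
        with pytest.raises(ValueError, match="rare"):
            loo_cv_decode(X, y)


class TestCrossCondition:
    def test_identical_sets_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="identical"):
            cross_condition_decode(X, y, X.copy(), y)

    def test_overlapping_indices_rejected(self, rng):
        Xa, Xb = rng.standard_normal((10, 3)), rng.standard_normal((5, 3))
        ya, yb = np.array([0, 1] * 5), np.array([0, 1, 0, 1, 0])
        with pytest.raises(ValueError, match="share"):
            cross_condition_decode(Xa, ya, Xb, yb,
                                   train_indices=np.arange(10),
                                   test_indices=np.array([9, 10, 11, 12, 13]))

    def test_shared_signal_transfers(self, rng):
        w = rng.standard_normal(6)
        def make(n):
            y = rng.integers(0, 2, size=n)
            X = np.outer(y * 2.0 - 1.0, w) + 0.5 * rng.standard_normal((n, 6))
            return X, y
        Xa, ya = make(80)
        Xb, yb = make(60)
        res = cross_condition_decode(Xa, ya, Xb, yb)
        assert res.auroc > 0.8

    def test_null_transfer_near_chance(self, rng):
        scores = []
        for _ in range(10):
            Xa = rng.standard_normal((40, 5))
            ya = np.array([0, 1] * 20)
            Xb = rng.standard_normal((40, 5))
            yb = np.array([0, 1] * 20)
            scores.append(cross_condition_decode(Xa, ya, Xb, yb).auroc)
        assert abs(np.mean(scores) - 0.5) < 0.1


class TestWithinAcross:
    def _data(self, rng, category_specific=False):
        n_per = 40
        cats = np.repeat(["a", "b", "c", "d"], n_per)
        rngw = {c: rng.standard_normal(6) for c in "abcd"}
        w = rng.standard_normal(6)
        y = rng.integers(0, 2, size=cats.size)
        X = np.empty((cats.size, 6))
        for i, c in enumerate(cats):
            direction = rngw[c] if category_specific else w
            X[i] = (y[i] * 2.0 - 1.0) * direction + 1.0 * rng.standard_normal(6)
        return X, y, cats

    def test_score_counts(self, rng):
        X, y, cats = self._data(rng)
        res = within_vs_across_category_decode(X, y, cats)
        assert len(res.within) == 4
        assert len(res.across) == 12

    def test_shared_process_gives_similar_scores(self, rng):
        diffs = []
        for _ in range(4):
            X, y, cats = self._data(rng, category_specific=False)
            res = within_vs_across_category_decode(X, y, cats)
            diffs.append(res.within_mean - res.across_mean)
        assert abs(np.mean(diffs)) < 0.08

    def test_category_specific_process_generalizes_worse(self, rng):
        diffs = []
        for _ in range(4):
            X, y, cats = self._data(rng, category_specific=True)
            res = within_vs_across_category_decode(X, y, cats)
            diffs.append(res.within_mean - res.across_mean)
        assert np.mean(diffs) > 0.1

    def test_degenerate_category_skipped_with_warning(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.array([0, 1] * 15)
        cats = np.array(["a"] * 20 + ["b"] * 10)
        y[20:] = 1  # category b has a single outcome
        with pytest.warns(UserWarning, match="b"):
            res = within_vs_across_category_decode(X, y, cats)
        assert list(res.within) == ["a"]
        assert len(res.across) == 0


class TestActivationPattern:
    def test_identity_covariance_returns_weights(self):
        dec = FittedDecoder(classes=np.array([0, 1]),
                            coef=np.array([[1.5, -0.5]]),
                            intercept=np.zeros(1),
                            mean=np.zeros(2), scale=np.ones(2))
        # four points whose sample covariance is exactly the identity
        a = np.sqrt(1.5)
        X = np.array([[a, 0], [-a, 0], [0, a], [0, -a]])
        pat = activation_pattern(dec, X)
        assert np.allclose(pat.sigma, np.eye(2))
        assert np.allclose(pat.A, dec.coef)

    def test_diagonal_covariance_arithmetic(self):
        dec = FittedDecoder(classes=np.array([0, 1]),
                            coef=np.array([[1.0, 1.0]]),
                            intercept=np.zeros(1),
                            mean=np.zeros(2), scale=np.ones(2))
        # sample covariance diag(2, 1): +/-a in col 0, +/-b in col 1
        a, b = np.sqrt(2 * 3 / 4), np.sqrt(1 * 3 / 4)
        X = np.array([[a, b], [a, -b], [-a, b], [-a, -b]])
        pat = activation_pattern(dec, X)
        assert np.allclose(pat.A, [[2.0, 1.0]])

    def test_too_few_trials_rejected(self):
        dec = FittedDecoder(classes=np.array([0, 1]), coef=np.ones((1, 2)),
                            intercept=np.zeros(1), mean=np.zeros(2),
                            scale=np.ones(2))
        with pytest.raises(ValueError, match="covariance"):
            activation_pattern(dec, np.ones((1, 2)))

    def test_recovers_planted_pattern_at_high_snr(self, rng):
        """Covariance projection turns decoder weights back into the planted
        signal pattern as noise vanishes."""
        w = rng.standard_normal(12)
        w /= np.linalg.norm(w)
        g = rng.standard_normal(300)
        X = np.outer(g, w) + 0.02 * rng.standard_normal((300, 12))
        y = (g > 0).astype(int)
        dec = fit_logistic(X, y, standardize=False)
        pat = activation_pattern(dec, X)
        cos = np.dot(pat.A[0], w) / np.linalg.norm(pat.A[0])
        assert abs(cos) > 0.98

    def test_group_pattern_is_elementwise_median(self):
        from prestim.decode import ActivationPattern

        plist = [ActivationPattern(A=np.array([[v, 2.0 * v]]), sigma=np.eye(2))
                 for v in (1.0, 5.0, 100.0)]
        assert np.allclose(group_activation_pattern(plist), [[5.0, 10.0]])
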