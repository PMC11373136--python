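import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepatox.errors import DegenerateLabels, SchemaError, StratificationError
from hepatox.evaluation import (
    ConfusionCounts,
    compute_metrics,
    confusion_counts,
    evaluate_predictions,
    kfold_cross_validate,
    one_way_anova,
    repeated_holdout_summary,
    roc_auc,
    roc_points,
)


# --------------------------------------------------------------------- oracles
def tally_oracle(y_true, y_pred):
    """Element-by-element confusion tally, independent of the implementation."""
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def all_pairs_auc_oracle(y_true, scores):
    """AUC as explicit positive/negative pair concordance, ties counted 1/2."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_direct_count(self):
        c = confusion_counts([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_prediction_has_no_errors(self):
        c = confusion_counts([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_matches_tally_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            y_true = rng.integers(0, 2, 50)
            y_pred = rng.integers(0, 2, 50)
            c = confusion_counts(y_true, y_pred)
            assert (c.tp, c.tn, c.fp, c.fn) == tuple(
                np.array(tally_oracle(y_true, y_pred))[[0, 1, 2, 3]]
            )
            assert c.total == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            confusion_counts([1, 0], [1])


class TestComputeMetrics:
    def test_hand_arithmetic_example(self):
        # TP=3, TN=2, FP=1, FN=0
        r = compute_metrics(ConfusionCounts(tp=3, tn=2, fp=1, fn=0))
        assert r.accuracy == pytest.approx(5 / 6)
        assert r.sensitivity == 1.0
        assert r.precision == pytest.approx(0.75)
        assert r.f1 == pytest.approx(3 / 3.5)
        assert r.specificity == pytest.approx(2 / 3)
        assert r.balanced_accuracy == pytest.approx((1 + 2 / 3) / 2)

    def test_perfect_prediction_all_ones(self):
        r = compute_metrics(ConfusionCounts(tp=4, tn=6, fp=0, fn=0))
        for v in (r.accuracy, r.sensitivity, r.specificity, r.precision, r.f1):
            assert v == 1.0

    def test_zero_over_zero_surfaces_as_undefined_marker(self):
        r = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(r.sensitivity)
        assert math.isnan(r.precision)
        assert r.specificity == 1.0

    @settings(max_examples=100)
    @given(
        tp=st.integers(0, 40), tn=st.integers(0, 40),
        fp=st.integers(0, 40), fn=st.integers(0, 40),
    )
    def test_accuracy_identity_with_prevalence_weights(self, tp, tn, fp, fn):
        # Q = (SE*P + SP*N)/(P+N), P=TP+FN, N=TN+FP
        if tp + tn + fp + fn == 0:
            return
        r = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        P, N = tp + fn, tn + fp
        if P > 0 and N > 0:
            assert r.accuracy == pytest.approx((r.sensitivity * P + r.specificity * N) / (P + N))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(0.75)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 101))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.choice(np.linspace(0, 1, 11), size=n)  # ties likely
            assert roc_auc(y, s) == pytest.approx(all_pairs_auc_oracle(y, s), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabels):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_invariance_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 80)
        y[0], y[1] = 0, 1
        s = rng.random(80)
        base = roc_auc(y, s)
        for transform in (lambda x: 2 * x + 3, np.exp, lambda x: x**3):
            assert roc_auc(y, transform(s)) == pytest.approx(base, abs=1e-12)

    def test_roc_points_table(self):
        df = roc_points([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6])
        assert list(df.columns) == ["fpr", "tpr", "threshold"]
        assert df.fpr.iloc[-1] == 1.0 and df.tpr.iloc[-1] == 1.0


class _ConstantPipeline:
    def __init__(self, value=0.5):
        self.value = value

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        n = X.n_samples if hasattr(X, "n_samples") else len(X)
        return np.full(n, self.value)


class _LogisticPipeline:
    def __init__(self, seed):
        from sklearn.linear_model import LogisticRegression

        self.clf = LogisticRegression(max_iter=200, random_state=seed)

    def fit(self, X, y):
        self.clf.fit(np.asarray(X), y)
        return self

    def predict_proba(self, X):
        return self.clf.predict_proba(np.asarray(X))[:, 1]


class TestKFoldCrossValidate:
    def _data(self, rng, n=25):
        y = np.array([0, 1] * (n // 2) + [1] * (n % 2))
        X = rng.random((n, 3)) + y[:, None]
        return X, y

    def test_fold_sizes_and_partition(self, rng):
        X, y = self._data(rng, 25)
        report = kfold_cross_validate(lambda s: _ConstantPipeline(), X, y, k=10, seed=0)
        fold_sizes = np.bincount(list(report.fold_assignment.values()), minlength=10)
        assert set(fold_sizes) <= {2, 3}
        assert sorted(report.fold_assignment) == list(range(25))

    def test_constant_predictor_degenerate_metrics(self, rng):
        X, y = self._data(rng, 30)
        report = kfold_cross_validate(lambda s: _ConstantPipeline(), X, y, k=5, seed=1)
        for fold in report.fold_reports:
            assert math.isnan(fold.auc) or fold.auc == 0.5  # undefined-or-chance
            assert fold.sensitivity == 1.0  # 0.5 >= 0.5 labels everything 1
        # accuracy spread reflects only class composition of the folds
        assert all(r.accuracy == pytest.approx(y.mean(), abs=0.2) for r in report.fold_reports)

    def test_seed_reproduces_folds_bit_for_bit(self, rng):
        X, y = self._data(rng, 40)
        a = kfold_cross_validate(lambda s: _LogisticPipeline(s), X, y, k=4, seed=9)
        b = kfold_cross_validate(lambda s: _LogisticPipeline(s), X, y, k=4, seed=9)
        assert a.fold_assignment == b.fold_assignment
        assert [r.as_dict() for r in a.fold_reports] == [r.as_dict() for r in b.fold_reports]

    def test_mean_lies_within_fold_extremes(self, rng):
        X, y = self._data(rng, 60)
        report = kfold_cross_validate(lambda s: _LogisticPipeline(s), X, y, k=5, seed=2)
        for metric, mean in report.mean.items():
            values = [getattr(r, metric) for r in report.fold_reports]
            finite = [v for v in values if not math.isnan(v)]
            if finite:
                assert min(finite) - 1e-12 <= mean <= max(finite) + 1e-12

    def test_too_few_class_members_rejected(self, rng):
        X = rng.random((8, 2))
        y = np.array([1, 1, 1, 1, 1, 1, 0, 0])
        with pytest.raises(StratificationError):
            kfold_cross_validate(lambda s: _ConstantPipeline(), X, y, k=5, seed=0)


class TestRepeatedHoldout:
    def test_identical_seeds_give_zero_sd(self, rng):
        X = rng.random((60, 3))
        y = np.array([0, 1] * 30)
        X[:, 0] += y
        mean, sd, reports = repeated_holdout_summary(
            lambda s: _LogisticPipeline(0), X, y, seeds=[7, 7, 7]
        )
        assert all(v == 0 or math.isnan(v) for v in sd.values())
        assert len(reports) == 3

    def test_mean_equals_average_of_reports(self, rng):
        X = rng.random((80, 3))
        y = np.array([0, 1] * 40)
        X[:, 0] += 0.5 * y
        mean, sd, reports = repeated_holdout_summary(
            lambda s: _LogisticPipeline(s), X, y, seeds=[1, 2, 3, 4, 5]
        )
        accs = [r.accuracy for r in reports]
        assert mean["accuracy"] == pytest.approx(np.mean(accs))
        assert sd["accuracy"] == pytest.approx(np.std(accs, ddof=1))


class TestOneWayAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        assert one_way_anova([[1, 2, 3], [1, 2, 3]]) == (0.0, 1.0)

    def test_hand_computed_two_group_example(self):
        # groups [1,2] and [3,4]: SSB=4 (df 1), SSW=1 (df 2) -> F=8
        f, p = one_way_anova([[1, 2], [3, 4]])
        assert f == pytest.approx(8.0)
        assert 0 < p < 1

    def test_zero_within_variance_unequal_means(self):
        f, p = one_way_anova([[1, 1], [2, 2]])
        assert math.isinf(f) and p == 0.0

    def test_type_one_error_rate_under_null(self, rng):
        # ~5% of null replicates should reach p < 0.05
        hits = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 8) for _ in range(3)]
            _, p = one_way_anova(groups)
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2]])
        with pytest.raises(ValueError):
            one_way_anova([[1], [2, 3]])


def test_percent_rendering():
    r = evaluate_predictions([1, 1, 0, 0], [0.9, 0.4, 0.2, 0.1])
    pct = r.as_percent_dict()
    assert pct["accuracy"] == 75.0
    assert pct["auc"] == 100.0
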