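"""Confusion matrix, derived metrics, ROC/AUC and seeded splits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from roughnet.evaluation import (
    ConfusionMatrix,
    SplitSpec,
    confusion,
    kfold,
    metrics,
    roc_auc,
    split,
)


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self):
        y = ["p", "n", "p", "n", "p", "p", "n", "n", "p", "n"]
        cm = confusion(y, y, "p")
        assert cm.fn == 0 and cm.fp == 0
        assert cm.tp == 5 and cm.tn == 5

    def test_complement_prediction_has_no_correct_cells(self):
        y = ["p", "n", "p"]
        flipped = ["n", "p", "n"]
        cm = confusion(y, flipped, "p")
        assert cm.tp == 0 and cm.tn == 0
        assert cm.fn == 2 and cm.fp == 1

    def test_hand_tally_with_each_error_type(self):
        y_true = ["p", "p", "n", "n", "p", "n"]
        y_pred = ["p", "n", "p", "n", "p", "n"]
        cm = confusion(y_true, y_pred, "p")
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 2)

    def test_length_mismatch_and_extra_classes_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            confusion(["p"], ["p", "n"], "p")
        with pytest.raises(ValueError, match="2 labels"):
            confusion(["a", "b"], ["c", "a"], "a")


class TestMetrics:
    # confusion counts of the best-reduct summaries for the three clinical
    # benchmarks, against the printed TPR (2 dp) and FPR (3 dp)
    @pytest.mark.parametrize(
        "tp, fn, tn, fp, tpr, fpr",
        [
            (26, 2, 117, 2, 0.93, 0.017),   # hepatitis
            (238, 3, 451, 7, 0.99, 0.015),  # breast cancer
            (102, 18, 142, 8, 0.85, 0.053), # heart disease
        ],
    )
    def test_published_confusion_matrices(self, tp, fn, tn, fp, tpr, fpr):
        m = metrics(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)).rounded()
        assert m["tpr"] == tpr
        assert m["fpr"] == fpr

    def test_hepatitis_accuracy_recomputed_from_counts(self):
        m = metrics(ConfusionMatrix(tp=26, fn=2, fp=2, tn=117))
        assert m.accuracy == pytest.approx(143 / 147 * 100)
        # the sensitivity/specificity formulas applied literally
        assert m.sensitivity == pytest.approx(26 / 28 * 100)
        assert m.specificity == pytest.approx(117 / 119 * 100)

    def test_undefined_metrics_are_none_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, fn=0, fp=3, tn=7))
        assert m.sensitivity is None and m.tpr is None
        assert m.specificity is not None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    @given(
        st.tuples(*[st.integers(0, 30)] * 4).filter(lambda t: sum(t) > 0)
    )
    def test_identities(self, counts):
        tp, fn, fp, tn = counts
        m = metrics(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
        assert m.accuracy == pytest.approx((tp + tn) / (tp + fn + fp + tn) * 100)
        if m.tpr is not None:
            assert m.tpr == pytest.approx(m.sensitivity / 100)
            assert m.tpr + fn / (tp + fn) == pytest.approx(1.0)
        if m.fpr is not None:
            assert m.fpr == pytest.approx(1 - m.specificity / 100)


def pair_counting_auc(scores, y_true, positive):
    """Mann–Whitney oracle: fraction of (pos, neg) pairs ranked correctly, ties ½."""
    pos = [s for s, t in zip(scores, y_true) if t == positive]
    neg = [s for s, t in zip(scores, y_true) if t != positive]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        curve = roc_auc([0.9, 0.8, 0.2, 0.1], ["p", "p", "n", "n"], "p")
        assert curve.auc == 1.0

    def test_all_equal_scores_give_auc_half(self):
        curve = roc_auc([0.5] * 6, ["p", "n", "p", "n", "p", "n"], "p")
        assert curve.auc == 0.5
        assert curve.points == ((0.0, 0.0), (1.0, 1.0))

    def test_six_point_curve_matches_pair_counting(self):
        scores = [0.9, 0.7, 0.7, 0.4, 0.3, 0.1]
        y = ["p", "p", "n", "p", "n", "n"]
        curve = roc_auc(scores, y, "p")
        assert curve.auc == pytest.approx(pair_counting_auc(scores, y, "p"))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and .* negative"):
            roc_auc([0.1, 0.9], ["p", "p"], "p")

    def test_curve_is_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(0)
        scores = rng.random(30)
        y = rng.integers(0, 2, size=30)
        curve = roc_auc(scores, y.tolist(), 1)
        assert curve.points[0] == (0.0, 0.0) and curve.points[-1] == (1.0, 1.0)
        for (x0, y0), (x1, y1) in zip(curve.points, curve.points[1:]):
            assert x1 >= x0 and y1 >= y0

    @given(st.integers(0, 200))
    def test_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.random(n), 2).tolist()  # rounded to force ties
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        got = roc_auc(scores, y.tolist(), 1).auc
        assert got == pytest.approx(pair_counting_auc(scores, y.tolist(), 1))

    @given(st.integers(0, 50))
    def test_auc_matches_sklearn(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.random(n)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        got = roc_auc(scores.tolist(), y.tolist(), 1).auc
        assert got == pytest.approx(sklearn_metrics.roc_auc_score(y, scores))


class TestSplits:
    def test_round_half_up_train_size(self):
        ids = [f"x{i}" for i in range(147)]
        train, test = split(ids, SplitSpec(train_fraction=0.8, seed=0))
        assert (len(train), len(test)) == (118, 29)  # round-half-up(117.6)

    def test_exact_tenfold_division(self):
        ids = [f"x{i}" for i in range(270)]
        folds = kfold(ids, SplitSpec(k_folds=10, seed=1))
        assert [len(f) for f in folds] == [27] * 10

    def test_uneven_fold_sizes(self):
        ids = [f"x{i}" for i in range(25)]
        folds = kfold(ids, SplitSpec(k_folds=10, seed=1))
        assert sorted(len(f) for f in folds) == [2] * 5 + [3] * 5

    def test_same_seed_reproduces_assignment(self):
        ids = [f"x{i}" for i in range(50)]
        spec = SplitSpec(train_fraction=0.7, seed=42)
        assert split(ids, spec) == split(ids, spec)
        assert kfold(ids, spec) == kfold(ids, spec)

    @given(st.integers(0, 100))
    def test_split_and_folds_are_disjoint_and_covering(self, seed):
        ids = [f"x{i}" for i in range(23)]
        train, test = split(ids, SplitSpec(train_fraction=0.6, seed=seed))
        assert sorted(train + test) == sorted(ids)
        assert not set(train) & set(test)
        folds = kfold(ids, SplitSpec(k_folds=4, seed=seed))
        assert sorted(sum(folds, [])) == sorted(ids)

    def test_stratified_split_preserves_class_shares(self):
        ids = [f"x{i}" for i in range(100)]
        labels = ["a"] * 80 + ["b"] * 20
        train, _ = split(
            ids, SplitSpec(train_fraction=0.8, seed=3, stratified=True), labels
        )
        train_b = sum(1 for o in train if int(o[1:]) >= 80)
        assert len(train) == 80
        assert train_b == 16

    def test_too_few_objects_rejected(self):
        with pytest.raises(ValueError):
            split(["only"], SplitSpec())
        with pytest.raises(ValueError):
            kfold(["a", "b"], SplitSpec(k_folds=3))
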