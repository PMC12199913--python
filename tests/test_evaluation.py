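import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from omsite import ValidationError, confusion, kfold_cv, make_spec, metrics, roc_auc
from omsite.evaluation import (
    ConfusionCounts,
    independent_test,
    report,
    roc,
    split_80_20,
    stratified_fold_indices,
)


def mann_whitney_auc(labels, scores):
    """Pair-count oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_wrong(self):
        c = confusion([1, 0], [0, 1])
        assert c.tp == 0 and c.tn == 0 and c.fp == 1 and c.fn == 1

    def test_mixed_enumeration(self):
        c = confusion([1, 0, 1, 0], [1, 1, 0, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            confusion([1, 0], [1])

    def test_total_equals_rows(self, rng):
        y = rng.integers(0, 2, size=200)
        yhat = rng.integers(0, 2, size=200)
        assert confusion(y, yhat).total == 200


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_worked_example(self):
        m = metrics(ConfusionCounts(tp=40, fn=10, tn=35, fp=15))
        assert m.sn == pytest.approx(0.8)
        assert m.sp == pytest.approx(0.7)
        assert m.acc == pytest.approx(0.75)
        assert m.mcc == pytest.approx(0.5025, abs=5e-5)

    def test_degenerate_all_positive_calls(self):
        m = metrics(ConfusionCounts(tp=50, fn=0, tn=0, fp=50))
        assert m.acc == 0.5 and m.sp == 0.0 and m.mcc == 0.0

    def test_sn_missing_when_no_positives(self):
        m = metrics(ConfusionCounts(tp=0, fn=0, tn=10, fp=2))
        assert m.sn is None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_bounds_and_inversion_antisymmetry_fuzzed(self, rng):
        for _ in range(10_000):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = metrics(ConfusionCounts(tp, tn, fp, fn))
            assert 0.0 <= m.acc <= 1.0
            assert -1.0 <= m.mcc <= 1.0
            assert m.sn is None or 0.0 <= m.sn <= 1.0
            assert m.sp is None or 0.0 <= m.sp <= 1.0
            # swapping the prediction column negates MCC
            inv = metrics(ConfusionCounts(tp=fn, tn=fp, fp=tn, fn=tp))
            assert inv.mcc == pytest.approx(-m.mcc, abs=1e-12)

    def test_agrees_with_sklearn_mcc(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, size=40)
            yhat = rng.integers(0, 2, size=40)
            ours = metrics(confusion(y, yhat)).mcc
            assert ours == pytest.approx(matthews_corrcoef(y, yhat), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_four_point_worked_example(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1], [0.2, 0.4])

    def test_matches_rank_sum_oracle_exhaustively(self):
        # all label patterns of n = 8 with both classes, ties included
        scores = [0.1, 0.4, 0.4, 0.5, 0.6, 0.6, 0.6, 0.9]
        for labels in itertools.product([0, 1], repeat=8):
            if len(set(labels)) < 2:
                continue
            assert roc_auc(labels, scores) == pytest.approx(
                mann_whitney_auc(labels, scores), abs=1e-12
            )

    def test_curve_endpoints(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.uniform(size=50)
        auc, fpr, tpr = roc(y, s)
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0


class TestSplit:
    def test_balanced_100_gives_80_20(self):
        table = pd.DataFrame({"x": np.arange(100.0)})
        y = np.repeat([0, 1], 50)
        tr_t, tr_y, te_t, te_y = split_80_20(table, y, seed=0)
        assert len(tr_t) == 80 and len(te_t) == 20
        assert (te_y == 1).sum() == 10 and (te_y == 0).sum() == 10

    def test_deterministic_under_seed(self):
        table = pd.DataFrame({"x": np.arange(60.0)})
        y = np.repeat([0, 1], 30)
        a = split_80_20(table, y, seed=9)
        b = split_80_20(table, y, seed=9)
        assert a[0].index.equals(b[0].index) and a[2].index.equals(b[2].index)

    def test_partition_is_disjoint_and_exhaustive(self):
        table = pd.DataFrame({"x": np.arange(77.0)})
        y = (np.arange(77) % 3 == 0).astype(int)
        tr_t, _, te_t, _ = split_80_20(table, y, seed=4)
        combined = sorted(tr_t.index.tolist() + te_t.index.tolist())
        assert combined == list(range(77))

    def test_tiny_class_rejected(self):
        table = pd.DataFrame({"x": np.arange(6.0)})
        with pytest.raises(ValidationError):
            split_80_20(table, [0, 0, 0, 0, 0, 1], seed=0)


class TestKFold:
    def test_fold_sizes_n103(self):
        y = np.array([0] * 52 + [1] * 51)
        folds = stratified_fold_indices(y, k=5, seed=0)
        assert sorted(len(f) for f in folds) == [20, 20, 21, 21, 21]

    def test_every_row_tested_exactly_once(self):
        y = np.array([0] * 52 + [1] * 51)
        folds = stratified_fold_indices(y, k=5, seed=3)
        seen = np.concatenate(folds)
        assert sorted(seen.tolist()) == list(range(103))

    def test_class_ratio_within_one_per_fold(self):
        y = np.array([0] * 70 + [1] * 33)
        folds = stratified_fold_indices(y, k=5, seed=1)
        pos_counts = [int((y[f] == 1).sum()) for f in folds]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_k_below_two_rejected(self):
        with pytest.raises(ValidationError):
            stratified_fold_indices(np.repeat([0, 1], 10), k=1)

    def test_mean_accuracy_on_separable_data(self, separable_dataset):
        table, y = separable_dataset
        folds, mean = kfold_cv(table, y, make_spec("bagging", seed=0), k=5, seed=0)
        assert len(folds) == 5
        assert mean.acc >= 0.9


class TestReport:
    def test_rows_and_rendering(self):
        m = metrics(ConfusionCounts(tp=40, fn=10, tn=35, fp=15))
        frame = report({("A-center", "bagging"): m}, protocol="independent_80_20")
        assert len(frame) == 1
        row = frame.iloc[0]
        assert row["mcc_2dp"] == "0.50"
        assert row["mcc"] == pytest.approx(0.502519, abs=1e-5)

    def test_empty_protocol_rejected(self):
        m = metrics(ConfusionCounts(tp=1, tn=1, fp=0, fn=0))
        with pytest.raises(ValidationError):
            report({("d", "m"): m}, protocol="")

    def test_empty_results_rejected(self):
        with pytest.raises(ValidationError):
            report({}, protocol="independent_80_20")


class TestLeakageGuards:
    def test_null_data_scores_near_chance(self, null_dataset):
        # encodings with no class signal must not yield high accuracy;
        # a leak through the scaler or fold logic would fabricate one
        table, y = null_dataset
        m = independent_test(table, y, make_spec("bagging", seed=0), seed=0)
        assert 0.1 <= m.acc <= 0.9
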