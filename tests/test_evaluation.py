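import numpy as np
import pytest

from ramanformer import evaluation as ev
from ramanformer import transformer_model as tm


def auc_pair_counting(scores, positive):
    """Exhaustive concordant-pair oracle; ties count one half."""
    pos = scores[positive]
    neg = scores[~positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedKFold:
    def test_paper_scale_partition_is_exact(self):
        labels = np.repeat(np.arange(8), 500)
        fa = ev.stratified_kfold(labels, k=5, seed=0)
        for f in range(5):
            test = fa.test_indices(f)
            assert test.size == 800
            counts = np.bincount(labels[test], minlength=8)
            assert np.all(counts == 100)

    def test_partition_properties(self):
        labels = np.random.default_rng(0).integers(0, 3, 60)
        labels[:3] = [0, 1, 2]  # every class present
        fa = ev.stratified_kfold(labels, k=4, seed=1)
        all_test = np.concatenate([fa.test_indices(f) for f in range(4)])
        assert sorted(all_test) == list(range(60))

    def test_deterministic(self):
        labels = np.repeat([0, 1], 20)
        a = ev.stratified_kfold(labels, 5, seed=9)
        b = ev.stratified_kfold(labels, 5, seed=9)
        np.testing.assert_array_equal(a.fold_index, b.fold_index)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            ev.stratified_kfold(np.array([0, 0, 0, 1, 1]), k=3, seed=0)


class TestTrainValSplit:
    def test_inner_split_sizes(self):
        labels = np.repeat(np.arange(8), 400)
        indices = np.arange(labels.size)
        tr, va = ev.train_val_split(indices, labels, 0.8, seed=0)
        assert np.all(np.bincount(labels[tr]) == 320)
        assert np.all(np.bincount(labels[va]) == 80)

    def test_partition(self):
        labels = np.repeat([0, 1], 25)
        idx = np.arange(50)
        tr, va = ev.train_val_split(idx, labels, 0.8, seed=2)
        assert set(tr) | set(va) == set(idx)
        assert set(tr) & set(va) == set()

    def test_half_split_of_ten(self):
        labels = np.repeat(np.arange(5), 2)  # 5 balanced classes of 2
        tr, va = ev.train_val_split(np.arange(10), labels, 0.5, seed=3)
        assert tr.size == 5 and va.size == 5

    def test_vanishing_class_rejected(self):
        with pytest.raises(ValueError, match="vanish"):
            ev.train_val_split(np.arange(4), np.array([0, 0, 1, 1]), 0.9, seed=0)


class TestConfusionMatrix:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 2])
        mat = ev.confusion_matrix(y, y, 3)
        np.testing.assert_array_equal(mat, np.diag([1, 1, 2]))
        np.testing.assert_array_equal(ev.per_class_accuracy(mat), [1, 1, 1])

    def test_counting_example(self):
        mat = ev.confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(mat, [[1, 1], [0, 1]])
        np.testing.assert_allclose(ev.per_class_accuracy(mat), [0.5, 1.0])

    def test_row_sums_are_supports(self):
        rng = np.random.default_rng(4)
        true = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        mat = ev.confusion_matrix(true, pred, 4)
        np.testing.assert_array_equal(mat.sum(axis=1), np.bincount(true, minlength=4))
        assert mat.sum() == 200

    def test_out_of_range_label(self):
        with pytest.raises(ValueError, match="out of range"):
            ev.confusion_matrix([0, 3], [0, 1], 3)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([[0.9], [0.8], [0.2], [0.1]])
        labels = np.array([0, 0, 1, 1])
        probs = np.hstack([scores, 1 - scores])
        _, auc = ev.roc_auc_ovr(probs, labels)
        np.testing.assert_allclose(auc, [1.0, 1.0])

    def test_hand_counted_example(self):
        # positives {0.9, 0.3}, negatives {0.5, 0.1}: 3 of 4 pairs concordant
        probs = np.array([[0.9], [0.3], [0.5], [0.1]])
        probs = np.hstack([probs, 1 - probs])
        labels = np.array([0, 0, 1, 1])
        _, auc = ev.roc_auc_ovr(probs, labels)
        assert auc[0] == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        probs = np.full((6, 2), 0.5)
        labels = np.array([0, 0, 0, 1, 1, 1])
        _, auc = ev.roc_auc_ovr(probs, labels)
        np.testing.assert_allclose(auc, [0.5, 0.5])

    def test_absent_class_reported_missing(self):
        probs = np.random.default_rng(5).dirichlet(np.ones(3), size=10)
        labels = np.zeros(10, dtype=int) % 2  # classes 1, 2 absent
        labels[5:] = 1
        curves, auc = ev.roc_auc_ovr(probs, labels)
        assert curves[2] is None and np.isnan(auc[2])

    def test_sweep_equals_pair_counting(self):
        """The swept ROC integral equals the exhaustive pair count."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            positive = rng.random(n) < 0.5
            if positive.all() or not positive.any():
                continue
            probs = np.column_stack([scores, 1 - scores])
            labels = (~positive).astype(int)
            _, auc = ev.roc_auc_ovr(probs, labels)
            assert auc[0] == pytest.approx(auc_pair_counting(scores, positive),
                                           abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        probs = rng.dirichlet(np.ones(4), size=120)
        labels = rng.integers(0, 4, 120)
        _, auc = ev.roc_auc_ovr(probs, labels)
        for c in range(4):
            ref = roc_auc_score((labels == c).astype(int), probs[:, c])
            assert auc[c] == pytest.approx(ref, abs=1e-12)


@pytest.fixture(scope="module")
def cv_result(separable_2class):
    clean = separable_2class["clean"]
    cfg = tm.TransformerConfig(n_classes=2, preset="scaled")
    tcfg = tm.TrainConfig(epochs=10, batch_size=16, seed=0)
    return ev.run_cross_validation(clean, "transformer", cfg, tcfg, k=5, seed=0), clean


class TestCrossValidation:

    def test_five_fold_records(self, cv_result):
        res, _ = cv_result
        assert len(res.folds) == 5
        assert [f.fold for f in res.folds] == list(range(5))

    def test_every_sample_tested_once(self, cv_result):
        res, clean = cv_result
        total = np.sum([f.confusion.sum() for f in res.folds])
        assert total == clean.n_spectra
        for f in res.folds:
            assert f.confusion.sum() == clean.n_spectra // 5

    def test_mean_is_arithmetic_mean(self, cv_result):
        res, _ = cv_result
        assert res.mean_accuracy == pytest.approx(
            np.mean([f.test_accuracy for f in res.folds]), abs=1e-12)
        assert res.best_fold_accuracy == max(f.test_accuracy for f in res.folds)

    def test_confusion_trace_equals_accuracy(self, cv_result):
        res, _ = cv_result
        for f in res.folds:
            assert f.test_accuracy == pytest.approx(
                np.trace(f.confusion) / f.confusion.sum())

    def test_result_serializes(self, cv_result):
        res, _ = cv_result
        blob = res.to_json()
        assert "mean_accuracy" in blob
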