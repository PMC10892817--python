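"""Cross-validation folds, confusion metrics, ROC AUC, and the training loop."""

import numpy as np
import pytest

from osadetect import models, train_eval
from osadetect.errors import ValidationError
from osadetect.train_eval import (ConfusionCounts, TrainConfig,
                                  classification_metrics, confusion_counts,
                                  cross_validate, kfold_indices, predict_proba,
                                  roc_auc, train)


class TestKfold:
    def test_singleton_folds(self):
        folds = kfold_indices(10, 10, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_partition_property(self, rng):
        folds = kfold_indices(53, 7, seed=1)
        combined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(combined, np.arange(53))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_stratified_class_counts(self):
        labels = np.array([1] * 30 + [0] * 70)
        folds = kfold_indices(100, 10, seed=2, labels=labels)
        for fold in folds:
            assert abs(int(labels[fold].sum()) - 3) <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            kfold_indices(5, 6, seed=0)


class TestConfusion:
    def test_enumerated_example(self):
        cc = confusion_counts(["A", "A", "N", "N"], ["A", "N", "N", "N"])
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (1, 1, 2, 0)

    def test_perfect_predictions(self):
        cc = confusion_counts(["A", "N"], ["A", "N"])
        assert cc.fp == 0 and cc.fn == 0

    def test_all_negative_predictions_kill_sensitivity(self):
        cc = confusion_counts(["A", "A", "N", "N"], ["N", "N", "N", "N"])
        assert cc.tp == 0
        assert classification_metrics(cc).sensitivity == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(["A"], ["A", "N"])


class TestMetrics:
    def test_substitution_example(self):
        rep = classification_metrics(ConfusionCounts(tp=2, tn=3, fp=1, fn=0))
        assert rep.accuracy == pytest.approx(5 / 6)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.75

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_accuracy_is_prevalence_weighted_mean_of_se_sp(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 50, size=4)
            cc = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            rep = classification_metrics(cc)
            pos, neg = tp + fn, tn + fp
            expected = (pos * rep.sensitivity + neg * rep.specificity) / (pos + neg)
            assert rep.accuracy == pytest.approx(expected)

    def test_undefined_ratio_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            rep = classification_metrics(ConfusionCounts(tp=0, tn=3, fp=1, fn=0))
        assert np.isnan(rep.sensitivity)


def auc_bruteforce(scores, y):
    """O(n^2) pairwise oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, size=50)
            if y.sum() in (0, 50):
                y[0] = 1 - y[0]
            scores = np.round(rng.random(50), 2)   # induce some ties
            assert roc_auc(scores, y) == pytest.approx(
                auc_bruteforce(scores, y), abs=1e-12)

    def test_score_negation_complements_auc(self, rng):
        y = np.array([0, 1] * 25)
        scores = rng.standard_normal(50)   # continuous: no ties
        assert roc_auc(-scores, y) == pytest.approx(1.0 - roc_auc(scores, y),
                                                    abs=1e-12)

    def test_permutation_invariance(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        scores = rng.random(40)
        perm = rng.permutation(40)
        assert roc_auc(scores[perm], y[perm]) == pytest.approx(
            roc_auc(scores, y), abs=1e-14)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.9], [1, 1])


def toy_image_set(rng, n=24):
    """Linearly separable toy set: bright (A) versus dark (N) images."""
    y = np.arange(n) % 2
    base = np.where(y[:, None, None, None] == 1, 0.8, 0.2)
    x = base + 0.05 * rng.standard_normal((n, 224, 224, 3))
    return np.clip(x, 0, 1).astype(np.float32), y


class TestTraining:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(99)
        return toy_image_set(rng)

    def test_separable_toy_set_reaches_full_training_accuracy(self, toy):
        x, y = toy
        clf = models.instantiate(models.residual_spec(), seed=0,
                                 width_multiplier=0.125)
        cfg = TrainConfig(epochs=5, batch_size=8, seed=0,
                          width_multiplier=0.125)
        train(clf, x, y, cfg)
        assert clf.history["accuracy"][-1] == 1.0
        assert len(clf.history["loss"]) == 5

    def test_same_seed_reproduces_loss_curve(self, toy):
        x, y = toy
        curves = []
        for _ in range(2):
            clf = models.instantiate(models.residual_spec(), seed=1,
                                     width_multiplier=0.125)
            cfg = TrainConfig(epochs=2, batch_size=8, seed=1,
                              width_multiplier=0.125)
            train(clf, x, y, cfg)
            curves.append(clf.history["loss"])
        assert curves[0] == curves[1]

    def test_predict_proba_contract_and_eval_determinism(self, toy):
        x, y = toy
        clf = models.instantiate(models.residual_spec(), seed=2,
                                 width_multiplier=0.125)
        p1 = predict_proba(clf, x[:6])
        p2 = predict_proba(clf, x[:6])
        assert p1.shape == (6, 2)
        np.testing.assert_allclose(p1.sum(axis=1), np.ones(6), atol=1e-6)
        np.testing.assert_array_equal(p1, p2)   # dropout off in eval mode

    def test_empty_dataset_rejected(self):
        clf = models.instantiate(models.residual_spec(), seed=0,
                                 width_multiplier=0.125)
        with pytest.raises(ValidationError):
            train(clf, np.zeros((0, 224, 224, 3), dtype=np.float32), [],
                  TrainConfig(epochs=1))


def test_cross_validation_folds_pool_to_overall_confusion(rng):
    """Per-fold confusions must sum to the pooled evaluation."""
    x, y = toy_image_set(rng, n=20)

    def make(seed):
        return models.instantiate(models.residual_spec(), seed,
                                  width_multiplier=0.125)

    cfg = TrainConfig(epochs=2, batch_size=8, seed=0, width_multiplier=0.125)
    results = cross_validate(make, x, y, 2, cfg)
    total = sum(r.counts.total for r in results)
    assert total == 20
    covered = np.sort(np.concatenate([r.test_indices for r in results]))
    np.testing.assert_array_equal(covered, np.arange(20))
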