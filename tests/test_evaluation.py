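"""Metrics, ROC/PR curves, CV, bootstrap and jackknife protocols."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from herbres.evaluation import (
    BinaryConfusion,
    BootstrapCVConfig,
    balanced_overall_accuracy,
    bootstrap_balanced_cv,
    class_correlation,
    composition_summary,
    compute_metrics,
    jackknife_multiclass,
    pr_points_and_auc,
    roc_points_and_auc,
    stratified_kfold_cv,
)
from herbres.seqio import LabeledDataset, SequenceRecord
from herbres.svm_core import KernelConfig


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics(BinaryConfusion(tp=10, tn=10, fp=0, fn=0))
        assert (m.sen, m.spe, m.acc, m.pre, m.mcc) == (1, 1, 1, 1, 1)

    def test_total_disagreement(self):
        m = compute_metrics(BinaryConfusion(tp=0, tn=0, fp=10, fn=10))
        assert m.mcc == -1 and m.sen == 0 and m.spe == 0

    def test_independent_set_confusion_counts(self):
        # resistant 36/44 recovered, non-resistant 1220/1324
        m = compute_metrics(BinaryConfusion(tp=36, fn=8, tn=1220, fp=104))
        assert m.sen == pytest.approx(0.8182, abs=5e-5)
        assert m.spe == pytest.approx(0.9215, abs=5e-5)

    def test_undefined_ratios_are_none_not_zero(self):
        m = compute_metrics(BinaryConfusion(tp=0, tn=5, fp=0, fn=0))
        assert m.sen is None and m.pre is None and m.mcc is None
        assert m.spe == 1.0

    def test_mcc_range_and_extremes(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(BinaryConfusion(int(tp), int(tn), int(fp), int(fn)))
            if m.mcc is not None:
                assert -1 - 1e-12 <= m.mcc <= 1 + 1e-12
                if m.mcc == 1:
                    assert fp == fn == 0 and tp > 0 and tn > 0


class TestBalancedOverallAccuracy:
    def test_two_stage_worked_example(self):
        assert balanced_overall_accuracy([36 / 44, 1220 / 1324]) == pytest.approx(
            0.8698, abs=1e-4
        )

    def test_single_stage_worked_example(self):
        assert balanced_overall_accuracy([32 / 44, 1287 / 1324]) == pytest.approx(
            0.8496, abs=1e-4
        )

    def test_perfect_and_empty(self):
        assert balanced_overall_accuracy([1.0, 1.0]) == 1.0
        with pytest.raises(ValueError):
            balanced_overall_accuracy([])


def oracle_auc_pair_counting(scores, labels):
    """Tie-corrected Mann-Whitney concordance, the AUC-ROC oracle."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        _, auc = roc_points_and_auc([3, 2, 1, 0], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        _, auc = roc_points_and_auc([1, 1, 1, 1], [1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_pair_counting_example(self):
        scores = [0.8, 0.4, 0.6, 0.2]
        labels = [1, 1, 0, 0]
        _, auc = roc_points_and_auc(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_curve_anchored_at_corners(self):
        points, _ = roc_points_and_auc([0.9, 0.1], [1, 0])
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_trapezoid_equals_pair_counting_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 200))
            scores = np.round(rng.normal(size=n), 1)   # rounding forces ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            _, auc = roc_points_and_auc(scores, labels)
            assert auc == pytest.approx(
                oracle_auc_pair_counting(scores, labels), abs=1e-12
            )

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_points_and_auc([1, 2], [1, 1])


class TestPr:
    def test_perfect_separation(self):
        _, auc = pr_points_and_auc([3, 2, 1, 0], [1, 1, 0, 0])
        assert auc == 1.0

    def test_single_positive_ranked_last(self):
        n = 8
        scores = list(range(n, 0, -1))
        labels = [0] * (n - 1) + [1]
        _, auc = pr_points_and_auc(scores, labels)
        assert auc == pytest.approx(1 / n)

    def test_all_tied_scores_give_prevalence(self):
        _, auc = pr_points_and_auc([1, 1, 1, 1, 1], [1, 0, 0, 0, 1])
        assert auc == pytest.approx(2 / 5)

    def test_matches_average_precision_reference(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(10):
            scores = rng.normal(size=60)
            labels = rng.random(60) < 0.3
            if not labels.any():
                continue
            _, auc = pr_points_and_auc(scores, labels)
            assert auc == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )

    def test_no_positives_is_error(self):
        with pytest.raises(ValueError):
            pr_points_and_auc([1, 2], [0, 0])


@pytest.fixture(scope="module")
def encoded_binary(tiny_benchmark):
    from herbres.features import KmerEncodingSpec, encode_dataset

    binary, _, _ = tiny_benchmark
    fm, _ = encode_dataset(binary, KmerEncodingSpec(k_set=(1, 2, 3)))
    return fm.values, np.asarray(binary.labels, dtype=object)


class TestStratifiedKfoldCV:
    def test_fold_balance_and_conservation(self, encoded_binary):
        X, y = encoded_binary
        result = stratified_kfold_cv(X, y, n_folds=4, seed=0)
        assert sum(c.total for c in result.fold_confusions) == len(y)
        for conf in result.fold_confusions:
            assert conf.tp + conf.fn == conf.tn + conf.fp   # balanced folds
        assert not any(p is None for p in result.predictions)

    def test_same_seed_reproducible(self, encoded_binary):
        X, y = encoded_binary
        r1 = stratified_kfold_cv(X, y, n_folds=4, seed=3)
        r2 = stratified_kfold_cv(X, y, n_folds=4, seed=3)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        assert r1.pooled.as_dict() == r2.pooled.as_dict()

    def test_separable_data_high_accuracy(self, encoded_binary):
        X, y = encoded_binary
        result = stratified_kfold_cv(X, y, n_folds=4, seed=0)
        assert result.pooled.acc >= 0.95

    def test_class_smaller_than_folds_is_error(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = ["a"] * 4 + ["b"] * 2
        with pytest.raises(ValueError, match=">= 3"):
            stratified_kfold_cv(X, y, n_folds=3)


class TestBootstrapBalancedCV:
    def test_identical_seed_bit_identical(self, encoded_binary):
        X, y = encoded_binary
        pos, neg = X[y == "resistant"], X[y == "non-resistant"]
        config = BootstrapCVConfig(n_bootstrap=3, per_class_n=20, n_folds=4, seed=9)
        r1 = bootstrap_balanced_cv(pos, neg, config)
        r2 = bootstrap_balanced_cv(pos, neg, config)
        pd.testing.assert_frame_equal(r1, r2)

    def test_pool_too_small_is_error(self, encoded_binary):
        X, y = encoded_binary
        pos, neg = X[y == "resistant"], X[y == "non-resistant"]
        with pytest.raises(ValueError, match="pools"):
            bootstrap_balanced_cv(
                pos, neg, BootstrapCVConfig(per_class_n=10_000)
            )

    def test_report_covers_all_metrics(self, encoded_binary):
        X, y = encoded_binary
        pos, neg = X[y == "resistant"], X[y == "non-resistant"]
        report = bootstrap_balanced_cv(
            pos, neg, BootstrapCVConfig(n_bootstrap=2, per_class_n=20, n_folds=4, seed=1)
        )
        assert set(report.index) == {
            "sen", "spe", "acc", "pre", "mcc", "auc_roc", "auc_pr"
        }
        assert report["mean"].between(-1, 1).all()


class TestJackknife:
    def test_every_observation_predicted_once(self, three_clusters):
        X, y = three_clusters
        report = jackknife_multiclass(X, y, KernelConfig("rbf", gamma=0.5))
        assert report.confusion.to_numpy().sum() == len(y)
        assert (report.confusion.sum(axis=1).to_numpy()
                == [int((y == c).sum()) for c in report.classes]).all()

    def test_separable_clusters_perfect_per_class_sensitivity(self, three_clusters):
        X, y = three_clusters
        report = jackknife_multiclass(X, y, KernelConfig("rbf", gamma=0.5))
        assert all(m.sen == 1.0 for m in report.per_class.values())

    def test_matches_naive_loo_oracle_on_20_items(self):
        """Independent leave-one-out loop built directly on the reference solver."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(4)
        X = np.vstack([
            rng.normal((0, 0), 0.4, (7, 2)),
            rng.normal((6, 0), 0.4, (7, 2)),
            rng.normal((0, 6), 0.4, (6, 2)),
        ])
        y = np.array(["a"] * 7 + ["b"] * 7 + ["c"] * 6, dtype=object)
        config = KernelConfig("rbf", gamma=0.5)
        report = jackknife_multiclass(X, y, config)
        ours = []
        for cls in report.classes:
            ours.append(report.confusion.loc[cls].to_numpy())
        oracle_preds = []
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            mu = X[mask].mean(axis=0)
            sd = X[mask].std(axis=0, ddof=1)
            svc = SVC(kernel="rbf", C=1.0, gamma=0.5, decision_function_shape="ovo")
            svc.fit((X[mask] - mu) / sd, y[mask].astype(str))
            oracle_preds.append(svc.predict(((X[i] - mu) / sd)[None, :])[0])
        oracle_conf = np.zeros((3, 3), dtype=int)
        classes = report.classes
        for t, p in zip(y, oracle_preds):
            oracle_conf[classes.index(t), classes.index(p)] += 1
        np.testing.assert_array_equal(np.vstack(ours), oracle_conf)

    def test_singleton_class_is_error(self):
        X = np.eye(5)
        y = ["a", "a", "b", "b", "c"]
        with pytest.raises(ValueError, match="single member"):
            jackknife_multiclass(X, y)


class TestComposition:
    def test_single_record_class_mean(self):
        ds = LabeledDataset([SequenceRecord("s", "", "ACGT")], ["x"])
        summary = composition_summary(ds, 1)
        np.testing.assert_allclose(summary.loc["x"].to_numpy(), 0.25)

    def test_identical_classes_fully_correlated(self):
        records = [
            SequenceRecord("s1", "", "AACGTT"),
            SequenceRecord("s2", "", "AACGTT"),
        ]
        ds = LabeledDataset(records, ["x", "y"])
        corr = class_correlation(composition_summary(ds, 1))
        assert corr.loc["x", "y"] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_matches_textbook_pearson(self, rng):
        summary = pd.DataFrame(
            rng.random((4, 16)), index=list("wxyz")
        )
        corr = class_correlation(summary)
        expected = np.corrcoef(summary.to_numpy())
        np.testing.assert_allclose(corr.to_numpy(), expected, atol=1e-12)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-15)

    def test_zero_variance_class_flagged(self):
        summary = pd.DataFrame(
            [[0.25, 0.25, 0.25, 0.25], [0.4, 0.3, 0.2, 0.1]], index=["flat", "ok"]
        )
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            corr = class_correlation(summary)
        assert np.isnan(corr.loc["flat", "ok"])
        assert corr.loc["ok", "ok"] == 1.0
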