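import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from ecgstress.dataset import WindowedDataset
from ecgstress.evaluation import (auc_from_roc, compare_regimes,
                                  compute_metrics, embed_2d,
                                  extract_stage_features, make_folds,
                                  metrics_from_counts, pr_curve, roc_curve,
                                  run_baselines)
from ecgstress.model import ModelConfig, build_model, he_initialize


class TestFolds:
    def test_17_subjects_k10(self):
        plan = make_folds([f"s{i}" for i in range(17)], k=10, seed=0)
        assert plan.k == 10
        sizes = sorted(len(f) for f in plan.folds)
        assert sizes == [1, 1, 1, 2, 2, 2, 2, 2, 2, 2]
        all_subjects = [s for f in plan.folds for s in f]
        assert len(all_subjects) == len(set(all_subjects)) == 17

    def test_leakage_probe(self):
        plan = make_folds([f"s{i}" for i in range(17)], k=10, seed=1)
        for train, test in plan.splits():
            assert not train & test

    def test_every_subject_exactly_one_test_fold(self):
        plan = make_folds([f"s{i}" for i in range(13)], k=10, seed=2)
        seen = [s for _, test in plan.splits() for s in test]
        assert len(seen) == 13
        assert set(seen) == {f"s{i}" for i in range(13)}

    def test_determinism(self):
        ids = [f"s{i}" for i in range(12)]
        assert make_folds(ids, 10, seed=7) == make_folds(ids, 10, seed=7)

    def test_k_reduced_with_warning(self):
        with pytest.warns(UserWarning, match="reducing k"):
            plan = make_folds(["a", "b", "c"], k=10, seed=0)
        assert plan.k == 3

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], k=1, seed=0)


class TestMetrics:
    def test_hand_confusion_algebra(self):
        m = metrics_from_counts(tp=3, fp=2, tn=2, fn=1)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.5)
        assert m.precision == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 / 3, abs=1e-4)
        assert m.accuracy == pytest.approx(5 / 8)

    def test_perfect_classifier(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.0, 0.0, 1.0, 1.0])
        m = compute_metrics(scores, labels)
        assert m.accuracy == 1.0
        assert m.auc_roc == pytest.approx(1.0)

    def test_uninformative_scores_auc_half(self):
        labels = np.array([0, 1, 0, 1])
        m = compute_metrics(np.full(4, 0.7), labels)
        assert m.auc_roc == pytest.approx(0.5)

    def test_two_column_probabilities_argmax(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        m = compute_metrics(probs, np.array([0, 1]))
        assert m.accuracy == 1.0

    def test_single_class_flagged(self):
        with pytest.warns(UserWarning, match="AUC undefined"):
            m = compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))
        assert m.auc_roc is None

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    @settings(max_examples=200, deadline=None)
    def test_metric_algebra_vs_recount(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = metrics_from_counts(tp, fp, tn, fn)
        total = tp + fp + tn + fn
        assert m.accuracy == pytest.approx((tp + tn) / total)
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(tn / (tn + fp))
        if tp + fp:
            assert m.precision == pytest.approx(tp / (tp + fp))
        if m.precision + m.sensitivity > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.sensitivity
                / (m.precision + m.sensitivity))


class TestRocPr:
    def test_auc_equals_mann_whitney(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 2)  # force score ties
            fpr, tpr, _ = roc_curve(scores, labels)
            auc = auc_from_roc(fpr, tpr)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.random(200)
        fpr, tpr, _ = roc_curve(scores, labels)
        assert auc_from_roc(fpr, tpr) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_roc_endpoints(self, rng):
        labels = np.array([0, 1, 1, 0, 1])
        fpr, tpr, thr = roc_curve(rng.random(5), labels)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)

    def test_roc_needs_both_classes(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_pr_brute_force_sweep(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.2])
        labels = np.array([1, 1, 0, 1, 0, 0])
        recall, precision, thresholds = pr_curve(scores, labels)
        n_pos = labels.sum()
        for t in np.unique(scores):
            pred = scores >= t
            r = (pred & (labels == 1)).sum() / n_pos
            p = (pred & (labels == 1)).sum() / pred.sum()
            i = np.argmin(np.abs(thresholds - t))
            assert recall[i] == pytest.approx(r)
            assert precision[i] == pytest.approx(p)

    def test_pr_perfect_passes_through_1_1(self):
        labels = np.array([0, 0, 1, 1])
        recall, precision, _ = pr_curve(np.array([.1, .2, .8, .9]), labels)
        assert any(r == 1.0 and p == 1.0 for r, p in zip(recall, precision))

    def test_pr_lowest_threshold_precision_is_prevalence(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        recall, precision, _ = pr_curve(rng.random(40), labels)
        assert recall[-1] == 1.0
        assert precision[-1] == pytest.approx(labels.mean())

    def test_pr_recall_monotone_in_threshold(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        recall, _, thresholds = pr_curve(rng.random(30), labels)
        # thresholds descend, recall ascends -> recall non-increasing
        # as the threshold rises
        assert (np.diff(thresholds) <= 0).all()
        assert (np.diff(recall) >= 0).all()

    def test_pr_no_positives_error(self):
        with pytest.raises(ValueError):
            pr_curve(np.array([0.5]), np.array([0]))


class TestCompareRegimes:
    def test_identical_groups_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cmp = compare_regimes({"I": [0.9] * 3, "II": [0.9] * 3})
        assert cmp.f_stat == 0.0
        assert not any(p.significant_05 for p in cmp.pairs)

    def test_separated_groups_all_significant(self, rng):
        j = 1e-4 * rng.normal(size=(3, 6))
        cmp = compare_regimes({"I": (0.9 + j[0]).tolist(),
                               "II": (0.5 + j[1]).tolist(),
                               "III": (0.7 + j[2]).tolist()})
        assert len(cmp.pairs) == 3
        assert all(p.significant_05 for p in cmp.pairs)
        assert all(p.significant_001 for p in cmp.pairs)

    def test_two_groups_equals_t_test(self, rng):
        a = rng.normal(0.7, 0.05, 8)
        b = rng.normal(0.75, 0.05, 8)
        cmp = compare_regimes({"A": a.tolist(), "B": b.tolist()})
        t = sps.ttest_ind(a, b, equal_var=True)
        assert cmp.f_stat == pytest.approx(t.statistic ** 2, rel=1e-9)
        assert cmp.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            compare_regimes({"A": [0.5, 0.6]})
        with pytest.raises(ValueError):
            compare_regimes({"A": [0.5, 0.6], "B": [0.4]})


def _flat_dataset(rng, n=80, separable=False):
    x = rng.normal(size=(n, 2560, 1)).astype(np.float32)
    y = rng.integers(0, 2, n)
    if separable:
        x[y == 1] += 2.0
    subj = np.array([f"s{i % 8}" for i in range(n)])
    return WindowedDataset(x, y, subj, 10)


class TestBaselines:
    def test_chance_level_on_random_labels(self, rng):
        ds = _flat_dataset(rng, n=80)
        plan = make_folds(ds.subjects(), k=4, seed=0)
        res = run_baselines(ds, plan, seed=0)
        for name, r in res.items():
            assert 0.35 <= r.mean <= 0.65, (name, r.mean)

    def test_separable_toy_logistic_regression(self, rng):
        ds = _flat_dataset(rng, n=80, separable=True)
        plan = make_folds(ds.subjects(), k=4, seed=0)
        res = run_baselines(ds, plan, seed=0,
                            classifiers=["logistic_regression"])
        assert res["logistic_regression"].mean >= 0.95

    def test_determinism(self, rng):
        ds = _flat_dataset(rng, n=40)
        plan = make_folds(ds.subjects(), k=4, seed=0)
        a = run_baselines(ds, plan, seed=1, classifiers=["random_forest"])
        b = run_baselines(ds, plan, seed=1, classifiers=["random_forest"])
        assert a["random_forest"].per_fold == b["random_forest"].per_fold


@pytest.fixture(scope="module")
def net():
    return he_initialize(build_model(ModelConfig(window_s=10)), 2)


class TestStageFeatures:
    def test_feature_lengths(self, net, rng):
        x = rng.normal(size=(4, 2560, 1)).astype(np.float32)
        assert extract_stage_features(net, x, 8).shape == (4, 640)
        assert extract_stage_features(net, x, 1).shape == (4, 10240)

    def test_identical_windows_identical_features(self, net):
        x = np.tile(np.random.default_rng(0).normal(
            size=(1, 2560, 1)).astype(np.float32), (3, 1, 1))
        f = extract_stage_features(net, x, 5)
        np.testing.assert_array_equal(f[0], f[1])
        np.testing.assert_array_equal(f[1], f[2])

    def test_stage_out_of_range(self, net):
        with pytest.raises(ValueError):
            extract_stage_features(net, np.zeros((1, 2560, 1)), 9)

    def test_embed_2d_shape_and_determinism(self, rng):
        feats = rng.normal(size=(30, 64)).astype(np.float32)
        a = embed_2d(feats, seed=3)
        b = embed_2d(feats, seed=3)
        assert a.shape == (30, 2)
        np.testing.assert_array_equal(a, b)
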