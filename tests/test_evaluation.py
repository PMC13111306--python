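"""Fold plans, confusion metrics, ROC/AUC oracle checks and Cohen's kappa."""

import itertools
import math
import warnings

import numpy as np
import pytest

import kerasym as ks


def auc_pair_oracle(labels, scores):
    """Exhaustive positive-negative pair enumeration, ties half-credit."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMakeFolds:
    def test_twenty_eyes_five_folds_of_four(self):
        plan = ks.make_folds([f"e{i}" for i in range(20)], k=5, seed=0)
        sizes = [len(plan.fold_ids(f)) for f in range(5)]
        assert sizes == [4, 4, 4, 4, 4]

    def test_same_seed_same_plan(self):
        ids = [f"e{i}" for i in range(17)]
        assert ks.make_folds(ids, 5, seed=3) == ks.make_folds(ids, 5, seed=3)

    def test_stratified_balance(self):
        ids = [f"e{i}" for i in range(20)]
        labels = ["kc"] * 10 + ["normal"] * 10
        plan = ks.make_folds(ids, 5, seed=1, labels=labels)
        for fold in range(5):
            members = plan.fold_ids(fold)
            assert sum(1 for m in members if labels[ids.index(m)] == "kc") == 2
            assert len(members) == 4

    def test_sizes_differ_by_at_most_one(self):
        for n, k in [(23, 5), (7, 3), (10, 4)]:
            ids = [f"e{i}" for i in range(n)]
            plan = ks.make_folds(ids, k, seed=0)
            sizes = [len(plan.fold_ids(f)) for f in range(k)]
            assert max(sizes) - min(sizes) <= 1
            assert sum(sizes) == n

    def test_too_few_eyes_rejected(self):
        with pytest.raises(ValueError):
            ks.make_folds(["a", "b"], k=3, seed=0)


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        m = ks.compute_confusion_metrics([1, 1, 1, 0, 0], [1, 1, 0, 0, 0])
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == 1.0
        assert m.accuracy == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)
        assert (m.tp, m.fp, m.tn, m.fn) == (2, 0, 2, 1)

    def test_perfect_predictions(self):
        m = ks.compute_confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (m.sensitivity, m.specificity, m.accuracy, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_accuracy_consistent_with_counts(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        m = ks.compute_confusion_metrics(y, p)
        assert m.accuracy == (m.tp + m.tn) / 50

    def test_no_positives_gives_nan_sentinel_and_warning(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = ks.compute_confusion_metrics([0, 0, 0], [0, 0, 1])
        assert math.isnan(m.sensitivity)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks.compute_confusion_metrics([], [])


class TestRocAuc:
    def test_hand_computed_auc(self):
        _, auc, _ = ks.roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2], n_boot=0)
        assert auc == pytest.approx(0.75)  # 4 pairs: 1 + 0 + 1 + 1 over 4... enumerated

    def test_perfect_separation(self):
        _, auc, _ = ks.roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], n_boot=0)
        assert auc == 1.0

    def test_all_tied_scores_half(self):
        _, auc, _ = ks.roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5], n_boot=0)
        assert auc == 0.5

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            _, auc, _ = ks.roc_auc(y, scores, n_boot=0)
            assert auc == pytest.approx(auc_pair_oracle(y, scores), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.normal(size=100) + y
        _, auc, _ = ks.roc_auc(y, s, n_boot=0)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.uniform(size=60)
        _, auc_base, _ = ks.roc_auc(y, s, n_boot=0)
        for transform in (lambda x: 3 * x + 1, np.exp, lambda x: x**3, lambda x: 1 / (1 + np.exp(-5 * x))):
            _, auc_t, _ = ks.roc_auc(y, transform(s), n_boot=0)
            assert auc_t == pytest.approx(auc_base, abs=1e-12)

    def test_curve_monotone_with_endpoints(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        curve, _, _ = ks.roc_auc(y, rng.uniform(size=40), n_boot=0)
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_bootstrap_ci_seeded_and_ordered(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        s = rng.normal(size=80) + 1.2 * y
        _, _, ci_a = ks.roc_auc(y, s, n_boot=300, seed=9)
        _, _, ci_b = ks.roc_auc(y, s, n_boot=300, seed=9)
        assert ci_a == ci_b
        assert ci_a[0] <= ci_a[1]

    def test_bootstrap_ci_narrows_with_n(self):
        rng = np.random.default_rng(11)
        widths = []
        for n in (50, 200, 800):
            y = np.array([0, 1] * (n // 2))
            s = rng.normal(size=n) + 1.0 * y
            _, _, ci = ks.roc_auc(y, s, n_boot=300, seed=1)
            widths.append(ci[1] - ci[0])
        assert widths[2] < widths[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ks.roc_auc([1, 1, 1], [0.1, 0.2, 0.3], n_boot=0)


class TestCohensKappa:
    def test_identical_ratings(self):
        assert ks.cohens_kappa([1, 0, 2, 1], [1, 0, 2, 1]) == 1.0

    def test_hand_computed_zero(self):
        # p_obs = 0.5, p_exp = 0.5 -> kappa = 0
        assert ks.cohens_kappa([1, 1, 0, 0], [1, 0, 0, 1]) == pytest.approx(0.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(21)
        a = rng.integers(0, 2, 20_000)
        b = rng.integers(0, 2, 20_000)
        assert abs(ks.cohens_kappa(a, b)) < 0.03

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 200)
        b = np.where(rng.uniform(size=200) < 0.7, a, rng.integers(0, 3, 200))
        assert ks.cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_constant_equal_raters_sentinel(self):
        with pytest.warns(UserWarning, match="kappa"):
            assert math.isnan(ks.cohens_kappa([1, 1, 1], [1, 1, 1]))


@pytest.fixture(scope="module")
def cohort_dir(tmp_path_factory):
    eyes = ks.sample_cohort(ks.CohortSpec(n_eyes=40, seed=55))
    scans = [ks.simulate_repeat_scans(e, seed=ks.derive_seed(55, e.eye_id)) for e in eyes]
    maps = [ks.render_curvature_map(e) for e in eyes]
    out = tmp_path_factory.mktemp("cohort40")
    ks.write_cohort(eyes, scans, maps, out)
    return out


class TestRunCvExperiment:
    def test_symbolic_mode_structure_and_determinism(self, cohort_dir, default_graph, tmp_path):
        kwargs = dict(k=5, seed=9, n_boot=50)
        a = ks.run_cv_experiment(cohort_dir, default_graph, out_dir=tmp_path / "a", **kwargs)
        b = ks.run_cv_experiment(cohort_dir, default_graph, out_dir=tmp_path / "b", **kwargs)
        assert a == b
        assert (tmp_path / "a" / "metrics.json").read_bytes() == (tmp_path / "b" / "metrics.json").read_bytes()
        assert len(a["per_fold"]) == 5
        assert all(row["n_test"] == 8 for row in a["per_fold"])
        assert 0.0 <= a["pooled"]["auc"] <= 1.0

    def test_results_directory_contents(self, cohort_dir, default_graph, tmp_path):
        ks.run_cv_experiment(cohort_dir, default_graph, k=4, seed=2, n_boot=0, out_dir=tmp_path / "r")
        for name in ("metrics.json", "roc_points.csv", "folds.json", "config_snapshot.json"):
            assert (tmp_path / "r" / name).exists()

    def test_symbolic_identical_with_or_without_encoder_module(self, cohort_dir, default_graph):
        # alpha = 0 path never touches the encoder; summary must not depend on it
        summary = ks.run_cv_experiment(cohort_dir, default_graph, k=5, seed=9, n_boot=0)
        assert summary["mode"] == "symbolic"
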