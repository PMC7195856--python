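"""Feature assembly and the nested-CV SVM with forward selection."""

import numpy as np
import pytest
from sklearn.svm import LinearSVC

from restconn.classify import (balanced_subsample_repeat,
                               compare_accuracy_distributions,
                               feature_selection_frequency,
                               permutation_null_accuracy, sffs_svm_cv)
from restconn.features import (FeatureTable, assemble_features,
                               expected_feature_count)
from restconn.svm import LinearSVM


def _dummy_subject(n_bins, n_channels, n_nodes, estimators, value=0.0):
    rng_like = np.full
    return {
        "peak": 10.0,
        "spectrum": rng_like(n_bins, value),
        "local_power": {b: rng_like(n_channels, value)
                        for b in ("theta", "alpha", "beta", "gamma")},
        "strength": {(e, b): rng_like(n_nodes, value)
                     for e in estimators
                     for b in ("theta", "alpha", "beta", "gamma")},
        "degree": {(e, b): rng_like(n_nodes, value)
                   for e in estimators
                   for b in ("theta", "alpha", "beta", "gamma")},
        "local_cc": {(e, b): rng_like(n_nodes, value)
                     for e in estimators
                     for b in ("theta", "alpha", "beta", "gamma")},
        "global_graph": {(e, b): rng_like(4, value)
                         for e in estimators
                         for b in ("theta", "alpha", "beta", "gamma")},
    }


def _noise_table(n_subjects=40, n_features=50, seed=0, planted=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_subjects, n_features))
    labels = np.array(["patient", "control"] * (n_subjects // 2))
    if planted is not None:
        X[:, planted] = np.where(labels == "patient", 1.0, -1.0) \
            + 0.1 * rng.normal(size=n_subjects)
    return FeatureTable(X, [f"f{i:03d}" for i in range(n_features)], labels)


class TestFeatureAssembly:
    def test_full_study_dimensions_give_73228_columns(self):
        ests = ("plv", "dwpli", "aec")
        subs = [_dummy_subject(199, 65, 2020, ests) for _ in range(2)]
        table = assemble_features(subs, ["patient", "control"])
        assert table.n_features == 73228
        assert expected_feature_count(199, 65, 2020) == 73228

    def test_reduced_dimensions_column_formula(self):
        ests = ("plv", "dwpli", "aec")
        subs = [_dummy_subject(20, 4, 10, ests) for _ in range(2)]
        table = assemble_features(subs, ["patient", "control"])
        assert table.n_features == 1 + 20 + 16 + 3 * (3 * 4 * 10) + 3 * 4 * 4
        assert table.n_features == 445

    def test_subject_permutation_permutes_rows_only(self):
        ests = ("plv",)
        subs = [_dummy_subject(5, 2, 3, ests, value=float(i))
                for i in range(4)]
        labels = ["patient", "patient", "control", "control"]
        t1 = assemble_features(subs, labels, estimators=ests)
        order = [2, 0, 3, 1]
        t2 = assemble_features([subs[i] for i in order],
                               [labels[i] for i in order], estimators=ests)
        np.testing.assert_array_equal(t2.matrix, t1.matrix[order])
        assert t2.feature_names == t1.feature_names

    def test_missing_component_names_subject_and_family(self):
        ests = ("plv",)
        subs = [_dummy_subject(5, 2, 3, ests) for _ in range(2)]
        del subs[1]["strength"][("plv", "beta")]
        with pytest.raises(RuntimeError, match="subject 1"):
            assemble_features(subs, ["patient", "control"], estimators=ests)

    def test_non_finite_entries_rejected(self):
        ests = ("plv",)
        subs = [_dummy_subject(5, 2, 3, ests)]
        subs[0]["peak"] = float("nan")
        with pytest.raises(RuntimeError, match="non-finite"):
            assemble_features(subs, ["patient"], estimators=ests)


class TestLinearSvmEngine:
    def test_predictions_match_sklearn_hinge_svm(self):
        """The in-package dual coordinate-descent solver solves the same
        problem as LinearSVC(loss='hinge'); predictions must agree."""
        agree, total = 0, 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            d = int(rng.integers(1, 8))
            X = rng.normal(size=(120, d))
            beta = rng.normal(size=d)
            y = np.sign(X @ beta + 0.5 * rng.normal(size=120))
            y[y == 0] = 1
            ours = LinearSVM(max_iter=4000, tol=1e-5).fit(X, y)
            ref = LinearSVC(C=1.0, loss="hinge", max_iter=50000).fit(X, y)
            Xt = rng.normal(size=(200, d))
            agree += (ours.predict(Xt) == ref.predict(Xt)).sum()
            total += 200
        assert agree / total > 0.99

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = np.where(rng.uniform(size=50) < 0.5, 1.0, -1.0)
        w1 = LinearSVM().fit(X, y).w_
        w2 = LinearSVM().fit(X, y).w_
        np.testing.assert_array_equal(w1, w2)


class TestSffsSvmCv:
    def test_planted_feature_found_and_accurate(self):
        table = _noise_table(80, 500, seed=2, planted=137)
        res = sffs_svm_cv(table, seed=3)
        assert res.mean_accuracy > 0.9
        hits = sum("f137" in sel for sel in res.selected_features)
        assert hits / len(res.selected_features) >= 0.8
        freq = feature_selection_frequency(res)
        assert freq[0][0] == "f137"

    def test_all_noise_selects_few_features(self):
        table = _noise_table(60, 80, seed=4)
        res = sffs_svm_cv(table, seed=5)
        assert np.mean([len(s) for s in res.selected_features]) <= 10

    def test_no_leakage_selection_ignores_test_folds(self):
        """Corrupting test-fold labels changes accuracy but not which
        features the training folds select."""
        table = _noise_table(40, 30, seed=6, planted=7)
        y = table.labels.copy()
        idx = np.arange(40)
        folds = [(idx[idx % 4 != k], idx[idx % 4 == k]) for k in range(4)]
        res1 = sffs_svm_cv(table, n_folds=4, seed=7, outer_folds=folds)
        corrupted = table.labels.copy()
        test_of_fold0 = folds[0][1]
        corrupted[test_of_fold0] = np.where(
            corrupted[test_of_fold0] == "patient", "control", "patient")
        table2 = FeatureTable(table.matrix, table.feature_names, corrupted)
        res2 = sffs_svm_cv(table2, n_folds=4, seed=7, outer_folds=[folds[0]])
        assert res2.selected_features[0] == res1.selected_features[0]
        assert res2.accuracies[0] != res1.accuracies[0]

    def test_small_class_redraws_with_fewer_folds(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 5))
        labels = np.array(["patient"] * 4 + ["control"] * 4)
        table = FeatureTable(X, [f"f{i}" for i in range(5)], labels)
        with pytest.warns(UserWarning):
            res = sffs_svm_cv(table, n_folds=10, seed=9)
        assert res.n_folds == 4


class TestNullAndSubsampling:
    def test_label_permutation_centres_at_chance(self):
        table = _noise_table(40, 30, seed=10)
        null = permutation_null_accuracy(table, n_repeats=30, seed=11)
        assert abs(null.mean() - 0.5) < 0.05

    def test_null_reproducible_for_fixed_seed(self):
        table = _noise_table(24, 10, seed=12)
        a = permutation_null_accuracy(table, n_repeats=3, seed=13)
        b = permutation_null_accuracy(table, n_repeats=3, seed=13)
        np.testing.assert_array_equal(a, b)

    def test_balanced_subsample_identity_when_equal(self):
        table = _noise_table(20, 8, seed=14)
        from restconn.classify import _subsample_balanced
        sub = _subsample_balanced(table, np.random.default_rng(0))
        assert sub.n_subjects == 20
        np.testing.assert_array_equal(np.sort(sub.matrix.ravel()),
                                      np.sort(table.matrix.ravel()))

    def test_balanced_subsample_reduces_majority(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(30, 6))
        labels = np.array(["patient"] * 20 + ["control"] * 10)
        table = FeatureTable(X, [f"f{i}" for i in range(6)], labels)
        res = balanced_subsample_repeat(table, n_repeats=2, seed=16, n_folds=5)
        assert len(res.accuracies) == 2
        res2 = balanced_subsample_repeat(table, n_repeats=2, seed=16, n_folds=5)
        np.testing.assert_array_equal(res.accuracies, res2.accuracies)

    def test_distribution_comparison(self):
        rng = np.random.default_rng(17)
        null = rng.normal(0.5, 0.05, size=60)
        real = rng.normal(0.7, 0.05, size=60)
        assert compare_accuracy_distributions(real, null, seed=1) < 0.05
        assert compare_accuracy_distributions(null, null, seed=2) > 0.9


class TestSelectionFrequency:
    def test_always_and_never_selected(self):
        from restconn.classify import CVResult
        res = CVResult(np.array([0.5]), 0.5, 0.5,
                       selected_features=[["a"], ["a", "b"]],
                       feature_names=["a", "b", "c"])
        freq = dict(feature_selection_frequency(res))
        assert freq["a"] == 1.0
        assert freq["b"] == 0.5
        assert freq["c"] == 0.0
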