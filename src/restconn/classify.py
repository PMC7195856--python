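"""Nested cross-validated SVM classification with sequential forward selection.

The outer loop is a stratified 10-fold cross-validation. Within each outer
training fold, features are standardised with training-fold statistics and a
greedy sequential forward selection adds, at each step, the feature whose
inclusion maximises inner 10-fold CV accuracy of a linear SVM (C=1),
stopping when accuracy no longer strictly improves. Test-fold subjects never
influence selection. Group imbalance is handled by repeated balanced
subsampling of the majority class, and chance level is established by
repeating the whole procedure with permuted labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable
from .stats import scalar_permutation_test
from .svm import score_candidates, svm_decision, svm_fit


@dataclass
class CVResult:
    accuracies: np.ndarray          # per outer fold (or per repeat, aggregated)
    sensitivity: float
    specificity: float
    selected_features: list = field(default_factory=list)  # per fold-model
    n_folds: int = 10
    n_repeats: int = 1
    seed: int = 0
    feature_names: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 \
            else 0.0


def _stratified_fold_ids(y: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Per-sample fold assignment, balanced within each class."""
    fold_id = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        fold_id[idx] = np.arange(len(idx)) % n_folds
    return fold_id


def _standardize(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (other - mu) / sd


def _forward_select(X: np.ndarray, y: np.ndarray, inner_folds: int, rng,
                    max_features: int | None, C: float,
                    max_iter: int, tol: float) -> list[int]:
    """Greedy forward selection scored by inner-CV accuracy; strict improvement."""
    n, n_feat = X.shape
    fold_id = _stratified_fold_ids(y, inner_folds, rng)
    selected: list[int] = []
    remaining = np.arange(n_feat, dtype=np.int64)
    best = -np.inf
    cap = n_feat if max_features is None else min(max_features, n_feat)
    while remaining.size and len(selected) < cap:
        scores = score_candidates(X, y, fold_id, inner_folds,
                                  np.asarray(selected, dtype=np.int64),
                                  remaining, C, max_iter, tol)
        j = int(np.argmax(scores))  # first of equals -> lowest feature index
        if scores[j] > best + 1e-12:
            best = float(scores[j])
            selected.append(int(remaining[j]))
            remaining = np.delete(remaining, j)
        else:
            break
    return selected


def sffs_svm_cv(table: FeatureTable, n_folds: int = 10, seed: int = 0,
                inner_folds: int = 10, max_features: int | None = None,
                C: float = 1.0, inner_max_iter: int = 40,
                inner_tol: float = 1e-2, outer_folds=None) -> CVResult:
    """Outer stratified k-fold CV around forward-selected linear SVMs.

    Reports the mean outer-fold accuracy, sensitivity and specificity (true
    positive/negative counts relative to the number of patient/control
    classifications made) and the per-fold selected feature lists.
    ``outer_folds`` may supply precomputed (train_idx, test_idx) pairs,
    bypassing the internal stratified split.
    """
    X = np.ascontiguousarray(table.matrix, dtype=np.float64)
    y = table.y_signed()
    counts = [int((y == v).sum()) for v in (1.0, -1.0)]
    if min(counts) < 2:
        raise ValueError("need at least two subjects per class")
    if min(counts) < n_folds:
        warnings.warn(f"class of size {min(counts)} smaller than {n_folds} folds; "
                      "re-drawing with fewer folds")
        n_folds = min(counts)
    rng = np.random.default_rng(seed)
    if outer_folds is None:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(0, 2 ** 31 - 1)))
        outer_folds = list(skf.split(X, y))
    fold_acc = []
    sel_lists = []
    tp = fp = tn = fn = 0
    for train_idx, test_idx in outer_folds:
        Xtr, Xte = _standardize(X[train_idx], X[test_idx])
        ytr, yte = y[train_idx], y[test_idx]
        sel = _forward_select(Xtr, ytr, inner_folds, rng, max_features, C,
                              inner_max_iter, inner_tol)
        cols = np.asarray(sel, dtype=np.int64)
        if cols.size == 0:
            pred = np.full(len(yte), 1.0 if (ytr == 1).sum() >= (ytr == -1).sum()
                           else -1.0)
        else:
            w = svm_fit(np.ascontiguousarray(Xtr[:, cols]), ytr, C, 2000, 1e-4)
            pred = np.where(svm_decision(
                np.ascontiguousarray(Xte[:, cols]), w) >= 0, 1.0, -1.0)
        fold_acc.append(float((pred == yte).mean()))
        tp += int(((pred == 1) & (yte == 1)).sum())
        fp += int(((pred == 1) & (yte == -1)).sum())
        tn += int(((pred == -1) & (yte == -1)).sum())
        fn += int(((pred == -1) & (yte == 1)).sum())
        sel_lists.append([table.feature_names[i] for i in sel])
    sens = tp / (tp + fp) if (tp + fp) else float("nan")
    spec = tn / (tn + fn) if (tn + fn) else float("nan")
    return CVResult(np.asarray(fold_acc), sens, spec, sel_lists,
                    n_folds=n_folds, seed=seed,
                    feature_names=list(table.feature_names))


def _subsample_balanced(table: FeatureTable, rng) -> FeatureTable:
    y = table.labels
    groups, counts = np.unique(y, return_counts=True)
    k = counts.min()
    keep = []
    for g in groups:
        idx = np.nonzero(y == g)[0]
        if len(idx) > k:
            idx = rng.choice(idx, size=k, replace=False)
        keep.append(np.sort(idx))
    keep = np.concatenate(keep)
    return FeatureTable(table.matrix[keep], table.feature_names, y[keep])


def balanced_subsample_repeat(table: FeatureTable, n_repeats: int = 100,
                              seed: int = 0, **cv_kwargs) -> CVResult:
    """Repeatedly subsample the majority class to balance, then run the CV."""
    rng = np.random.default_rng(seed)
    accs, sels = [], []
    sens, spec = [], []
    for _ in range(n_repeats):
        sub = _subsample_balanced(table, rng)
        res = sffs_svm_cv(sub, seed=int(rng.integers(0, 2 ** 31 - 1)), **cv_kwargs)
        accs.append(res.mean_accuracy)
        sens.append(res.sensitivity)
        spec.append(res.specificity)
        sels.extend(res.selected_features)
    return CVResult(np.asarray(accs), float(np.nanmean(sens)),
                    float(np.nanmean(spec)), sels,
                    n_folds=cv_kwargs.get("n_folds", 10),
                    n_repeats=n_repeats, seed=seed,
                    feature_names=list(table.feature_names))


def permutation_null_accuracy(table: FeatureTable, n_repeats: int = 100,
                              seed: int = 0, **cv_kwargs) -> np.ndarray:
    """Accuracy distribution with labels randomly shuffled on each repeat.

    The majority class is balanced by subsampling first (as in the real
    analysis); the returned distribution estimates chance level.
    """
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_repeats):
        sub = _subsample_balanced(table, rng)
        shuffled = FeatureTable(sub.matrix, sub.feature_names,
                                sub.labels[rng.permutation(sub.n_subjects)])
        res = sffs_svm_cv(shuffled, seed=int(rng.integers(0, 2 ** 31 - 1)),
                          **cv_kwargs)
        accs.append(res.mean_accuracy)
    return np.asarray(accs)


def compare_accuracy_distributions(real, null, n_perm: int = 10000,
                                   seed: int = 0) -> float:
    """Two-sample permutation p-value on the mean accuracy difference."""
    return scalar_permutation_test(np.asarray(real), np.asarray(null),
                                   n_perm=n_perm, seed=seed,
                                   statistic="meandiff", exhaustive=False)


def feature_selection_frequency(result: CVResult):
    """Selection counts normalised by the number of fold-models, ranked.

    Returns a list of (feature_name, frequency) sorted by descending
    frequency with deterministic ties by feature name.
    """
    n_models = len(result.selected_features)
    if n_models == 0:
        return []
    counts: dict = {}
    for sel in result.selected_features:
        for name in sel:
            counts[name] = counts.get(name, 0) + 1
    for name in result.feature_names:
        counts.setdefault(name, 0)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, cnt / n_models) for name, cnt in ranked]
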