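"""Linear support vector machine via dual coordinate descent (numba-compiled).

The nested cross-validated forward feature selection requires millions of
SVM fits on small feature subsets, so the hinge-loss linear SVM is solved
in-package with the standard dual coordinate-descent algorithm (the same
optimisation problem liblinear solves for an L2-regularised L1-loss SVM with
an augmented bias feature). Prediction agreement with scikit-learn's
``LinearSVC(loss='hinge')`` is verified in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def svm_fit(X, y, C, max_iter, tol):
    """Dual coordinate descent for the L1-loss linear SVM.

    X: n x d float64, y: n float64 in {-1, +1}. Returns weights of length
    d + 1 (the last entry is the bias, implemented as an augmented constant
    feature). Coordinate order is shuffled each pass with a deterministic
    LCG so results are reproducible.
    """
    n, d = X.shape
    w = np.zeros(d + 1)
    alpha = np.zeros(n)
    qd = np.empty(n)
    for i in range(n):
        s = 1.0  # bias feature contributes 1
        for j in range(d):
            s += X[i, j] * X[i, j]
        qd[i] = s
    idx = np.arange(n)
    for it in range(max_iter):
        max_pg = 0.0
        for k in range(n - 1, 0, -1):
            r = (1103515245 * (it * n + k) + 12345) % (k + 1)
            tmp = idx[k]
            idx[k] = idx[r]
            idx[r] = tmp
        for kk in range(n):
            i = idx[kk]
            g = y[i] * w[d]
            for j in range(d):
                g += y[i] * w[j] * X[i, j]
            g -= 1.0
            a = alpha[i]
            pg = g
            if a <= 0.0 and g > 0.0:
                pg = 0.0
            elif a >= C and g < 0.0:
                pg = 0.0
            if abs(pg) > max_pg:
                max_pg = abs(pg)
            if pg != 0.0:
                an = min(max(a - g / qd[i], 0.0), C)
                da = (an - a) * y[i]
                for j in range(d):
                    w[j] += da * X[i, j]
                w[d] += da
                alpha[i] = an
        if max_pg < tol:
            break
    return w


@njit(cache=True, fastmath=True)
def svm_decision(X, w):
    n, d = X.shape
    out = np.empty(n)
    for i in range(n):
        s = w[d]
        for j in range(d):
            s += w[j] * X[i, j]
        out[i] = s
    return out


@njit(cache=True, fastmath=True)
def _cv_accuracy_subset(X, y, fold_id, n_folds, cols, C, max_iter, tol):
    """Mean CV accuracy of the SVM restricted to feature columns ``cols``."""
    n = X.shape[0]
    k = cols.shape[0]
    acc_sum = 0.0
    n_used = 0
    for f in range(n_folds):
        n_tr = 0
        n_te = 0
        for i in range(n):
            if fold_id[i] == f:
                n_te += 1
            else:
                n_tr += 1
        if n_te == 0 or n_tr == 0:
            continue
        Xtr = np.empty((n_tr, k))
        ytr = np.empty(n_tr)
        Xte = np.empty((n_te, k))
        yte = np.empty(n_te)
        a = 0
        b = 0
        for i in range(n):
            if fold_id[i] == f:
                for j in range(k):
                    Xte[b, j] = X[i, cols[j]]
                yte[b] = y[i]
                b += 1
            else:
                for j in range(k):
                    Xtr[a, j] = X[i, cols[j]]
                ytr[a] = y[i]
                a += 1
        w = svm_fit(Xtr, ytr, C, max_iter, tol)
        correct = 0
        for i in range(n_te):
            s = w[k]
            for j in range(k):
                s += w[j] * Xte[i, j]
            pred = 1.0 if s >= 0.0 else -1.0
            if pred == yte[i]:
                correct += 1
        acc_sum += correct / n_te
        n_used += 1
    if n_used == 0:
        return 0.0
    return acc_sum / n_used


@njit(cache=True, fastmath=True)
def score_candidates(X, y, fold_id, n_folds, selected, candidates, C,
                     max_iter, tol):
    """Inner-CV accuracy of selected + each candidate feature, per candidate."""
    m = candidates.shape[0]
    k = selected.shape[0]
    scores = np.empty(m)
    cols = np.empty(k + 1, dtype=np.int64)
    for j in range(k):
        cols[j] = selected[j]
    for c in range(m):
        cols[k] = candidates[c]
        scores[c] = _cv_accuracy_subset(X, y, fold_id, n_folds, cols, C,
                                        max_iter, tol)
    return scores


class LinearSVM:
    """Thin object interface over the compiled solver (C=1, hinge loss)."""

    def __init__(self, C: float = 1.0, max_iter: int = 2000, tol: float = 1e-4):
        self.C = C
        self.max_iter = max_iter
        self.tol = tol
        self.w_ = None

    def fit(self, X, y):
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("labels must be -1/+1")
        self.w_ = svm_fit(X, y, self.C, self.max_iter, self.tol)
        return self

    def decision_function(self, X):
        X = np.ascontiguousarray(X, dtype=np.float64)
        return svm_decision(X, self.w_)

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, 1.0, -1.0)
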