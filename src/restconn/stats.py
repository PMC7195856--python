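"""Group statistics: cluster-based and scalar permutation tests, Holm correction,
Cohen's d, power analysis and brain-clinical correlations.

All permutation tests use the unpaired two-sample t statistic and permute
group labels. The cluster-based test thresholds feature-wise t values at the
two-sided critical value for the cluster-forming alpha, groups supra-threshold
features into spatially contiguous clusters (positive and negative signs
separately) under a supplied adjacency, scores each cluster by its summed t
(cluster mass), and compares observed masses against the permutation null of
the maximal absolute cluster mass — controlling family-wise error over
features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    members: np.ndarray
    mass: float
    p_value: float


@dataclass
class ClusterTestResult:
    clusters: list = field(default_factory=list)
    max_t: float = float("nan")
    min_t: float = float("nan")
    n_permutations: int = 0

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=float("nan"))

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_value <= alpha]


# ---------------------------------------------------------------------------
# basic statistics
# ---------------------------------------------------------------------------

def ttest_power(n1: int, n2: int, effect_size: float = 0.5,
                alpha: float = 0.05) -> float:
    """Closed-form power of a two-sided two-sample t test (pooled variance)."""
    return float(TTestIndPower().power(effect_size=effect_size, nobs1=n1,
                                       ratio=n2 / n1, alpha=alpha,
                                       alternative="two-sided"))


def cohens_d(a, b) -> float:
    """(mean_a - mean_b) / pooled SD, pooled with n-1 weights."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        warnings.warn("zero pooled SD; Cohen's d undefined")
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def holm_bonferroni(p, method: str = "holm") -> np.ndarray:
    """Step-down Holm (default) or plain Bonferroni corrected p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def _tstats(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance unpaired t per feature column."""
    a = x[labels]
    b = x[~labels]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / se
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _clusters_from_mask(mask: np.ndarray, adjacency: csr_matrix) -> list[np.ndarray]:
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, lab = connected_components(sub, directed=False)
    return [idx[lab == c] for c in range(n_comp)]


def _cluster_masses(t: np.ndarray, tcrit: float, adjacency: csr_matrix):
    out = []
    for sign in (1.0, -1.0):
        for members in _clusters_from_mask(sign * t > tcrit, adjacency):
            out.append((members, float(t[members].sum())))
    return out


def cluster_permutation_test(a: np.ndarray, b: np.ndarray, adjacency,
                             alpha_cluster: float = 0.05, n_perm: int = 1000,
                             seed: int = 0) -> ClusterTestResult:
    """Two-sided cluster-based permutation test over features.

    ``a``, ``b``: subjects x features per group. ``adjacency``: symmetric
    feature x feature connectivity (dense or sparse); with no edges the test
    degenerates to a max-statistic correction over single features. Reports
    t_max/t_min always, so null outcomes remain interpretable.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two subjects per group")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; p-values are coarse")
    adjacency = csr_matrix(adjacency)
    if (adjacency != adjacency.T).nnz:
        raise ValueError("adjacency must be symmetric")
    x = np.vstack([a, b])
    labels = np.zeros(x.shape[0], dtype=bool)
    labels[: a.shape[0]] = True
    df = x.shape[0] - 2
    tcrit = float(sps.t.ppf(1.0 - alpha_cluster / 2.0, df))
    t_obs = _tstats(x, labels)
    observed = _cluster_masses(t_obs, tcrit, adjacency)
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for i in range(n_perm):
        perm = labels[rng.permutation(x.shape[0])]
        t = _tstats(x, perm)
        masses = _cluster_masses(t, tcrit, adjacency)
        null[i] = max((abs(m) for _, m in masses), default=0.0)
    clusters = [
        Cluster(members, mass,
                (1.0 + np.sum(null >= abs(mass))) / (1.0 + n_perm))
        for members, mass in observed
    ]
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterTestResult(clusters, float(t_obs.max()), float(t_obs.min()),
                             n_perm)


def scalar_permutation_test(a, b, n_perm: int = 1000, seed: int = 0,
                            statistic: str = "t",
                            exhaustive: str | bool = "auto") -> float:
    """Two-tailed permutation p for a scalar group difference.

    Uses the pooled-variance t statistic (or the raw mean difference).
    When the number of distinct group splits is small (``exhaustive`` auto),
    all splits are enumerated and the p-value is exact; otherwise labels are
    permuted ``n_perm`` times with +1 smoothing.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)

    def stat(idx_a_mask: np.ndarray) -> float:
        if statistic == "t":
            return float(_tstats(pooled[:, None], idx_a_mask)[0])
        return float(pooled[idx_a_mask].mean() - pooled[~idx_a_mask].mean())

    mask_obs = np.zeros(n, dtype=bool)
    mask_obs[:na] = True
    t_obs = abs(stat(mask_obs))
    n_splits = math.comb(n, na)
    do_exhaustive = exhaustive is True or (exhaustive == "auto" and
                                           n_splits <= max(n_perm, 20000))
    eps = 1e-12
    if do_exhaustive:
        count = 0
        for idx in combinations(range(n), na):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            if abs(stat(m)) >= t_obs - eps:
                count += 1
        return count / n_splits
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, size=na, replace=False)] = True
        if abs(stat(m)) >= t_obs - eps:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# adjacency helpers
# ---------------------------------------------------------------------------

def grid_adjacency(positions: np.ndarray, spacing: float = 1.0) -> csr_matrix:
    """6-connectivity on a regular grid of 3-D positions (distance == spacing)."""
    pos = np.asarray(positions, dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d > 0) & (d <= spacing * 1.001)
    return csr_matrix(adj)


def layout_adjacency(positions2d: np.ndarray, quantile: float = 0.12) -> csr_matrix:
    """Sensor adjacency from a 2-D layout: neighbours within a distance quantile."""
    pos = np.asarray(positions2d, dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    off = d[np.triu_indices_from(d, k=1)]
    thresh = np.quantile(off, quantile)
    adj = (d > 0) & (d <= thresh)
    return csr_matrix(adj | adj.T)


def chain_adjacency(n: int) -> csr_matrix:
    """1-D adjacency for ordered features such as frequency bins."""
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = True
    return csr_matrix(adj | adj.T)


def no_adjacency(n: int) -> csr_matrix:
    return csr_matrix((n, n))


# ---------------------------------------------------------------------------
# brain-clinical correlations
# ---------------------------------------------------------------------------

def correlate_clinical(measures: pd.DataFrame, covariates: pd.DataFrame,
                       band_groups: dict | None = None) -> pd.DataFrame:
    """Pearson correlations of each brain measure with each clinical covariate.

    Missing values are pairwise-deleted; rows with fewer than 3 complete
    pairs are flagged NaN. ``band_groups`` maps a measure family name to the
    list of its per-band measure columns; Holm correction is then applied
    across the bands of each family (separately per covariate). Measures not
    listed in any family keep their uncorrected p.
    """
    rows = []
    for mcol in measures.columns:
        for ccol in covariates.columns:
            x = measures[mcol].to_numpy(dtype=float)
            y = covariates[ccol].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append((mcol, ccol, float("nan"), float("nan")))
                continue
            r, p = sps.pearsonr(x[ok], y[ok])
            rows.append((mcol, ccol, float(r), float(p)))
    table = pd.DataFrame(rows, columns=["measure", "covariate", "r", "p_uncorrected"])
    table["p_corrected"] = table["p_uncorrected"]
    if band_groups:
        for _, cols in band_groups.items():
            for ccol in covariates.columns:
                sel = table["measure"].isin(cols) & (table["covariate"] == ccol)
                p = table.loc[sel, "p_uncorrected"].to_numpy()
                finite = np.isfinite(p)
                if finite.sum():
                    corr = p.copy()
                    corr[finite] = holm_bonferroni(p[finite])
                    table.loc[sel, "p_corrected"] = corr
    return table
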