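"""Proportional thresholding and graph-theoretical network measures.

Connectivity matrices are reduced to binary graphs by keeping a fixed
fraction of the strongest undirected edges (edge density). Measures follow
the standard binary-graph definitions: degree, local/global clustering
coefficient, global efficiency (mean inverse shortest-path length, finite
under disconnection), small-worldness relative to degree-preserving rewired
surrogates, and the hub disruption index (regression slope of per-node
degree differences against a control-group reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix


@dataclass
class BinaryGraph:
    adjacency: np.ndarray            # node x node in {0, 1}
    density: float
    weights: np.ndarray = None       # retained weights (weighted variant)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency)
        np.fill_diagonal(self.adjacency, 0)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class NodeMetrics:
    degree: np.ndarray
    weighted_degree: np.ndarray
    local_cc: np.ndarray = None


def proportional_threshold(m, density: float, binarize: bool = True) -> BinaryGraph:
    """Retain exactly round(density * n(n-1)/2) strongest undirected edges.

    Ties spanning the cut are resolved deterministically by ascending
    node-pair index after a stable descending sort on weight; an all-equal
    matrix (retained set defined solely by the tie-break) raises a warning.
    """
    vals = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    n = vals.shape[0]
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    iu, ju = np.triu_indices(n, k=1)
    w = vals[iu, ju]
    k = int(round(density * len(w)))
    if np.all(w == w[0]) and len(w) > 1:
        warnings.warn("all edge weights equal; retained set determined by tie-break")
    # lexsort: last key is primary -> descending weight, then ascending pair index
    order = np.lexsort((np.arange(len(w)), -w))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj = adj + adj.T
    weights = None
    if not binarize:
        weights = np.zeros((n, n))
        weights[iu[keep], ju[keep]] = w[keep]
        weights = weights + weights.T
    return BinaryGraph(adj, density, weights=weights)


def node_degree(g: BinaryGraph) -> NodeMetrics:
    """Binary degree (edge counts) and weighted degree (retained-weight sums)."""
    deg = g.adjacency.sum(axis=1).astype(float)
    wdeg = g.weights.sum(axis=1) if g.weights is not None else deg.copy()
    return NodeMetrics(degree=deg, weighted_degree=wdeg)


def clustering_coefficients(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Local clustering coefficient per node and its mean (global CC).

    local_cc_i = 2 t_i / (k_i (k_i - 1)) with t_i the number of triangles at
    node i; nodes of degree < 2 have local CC 0 by convention.
    """
    a = g.adjacency.astype(float)
    k = a.sum(axis=1)
    t = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    local = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1.0), 0.0)
    return local, float(local.mean()) if len(local) else 0.0


def global_efficiency(g: BinaryGraph) -> float:
    """Mean over ordered node pairs of 1/d(i,j); disconnected pairs contribute 0."""
    n = g.n_nodes
    if n < 2:
        return 0.0
    d = shortest_path(csr_matrix(g.adjacency), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _rewired_surrogate(g: BinaryGraph, rng_seed: int) -> BinaryGraph:
    gx = nx.from_numpy_array(g.adjacency)
    n_edges = gx.number_of_edges()
    if n_edges < 2:
        return g
    try:
        nx.double_edge_swap(gx, nswap=10 * n_edges, max_tries=200 * n_edges,
                            seed=rng_seed)
    except nx.NetworkXException:
        pass  # too few swappable pairs (e.g. complete or tiny graph); keep as-is
    adj = nx.to_numpy_array(gx, nodelist=range(g.n_nodes), dtype=np.int8)
    return BinaryGraph(adj, g.density)


def small_worldness(g: BinaryGraph, n_random: int = 20, seed: int = 0) -> float:
    """S = (gCC / gCC_rand) * (gEff / gEff_rand) against degree-preserving surrogates.

    Reference values are means over ``n_random`` rewired surrogates
    (networkx double edge swaps preserve the degree sequence). Returns NaN
    for degenerate graphs whose reference clustering or efficiency is zero.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    _, gcc = clustering_coefficients(g)
    geff = global_efficiency(g)
    rng = np.random.default_rng(seed)
    gcc_r, geff_r = [], []
    for _ in range(n_random):
        sur = _rewired_surrogate(g, int(rng.integers(0, 2 ** 31 - 1)))
        _, c = clustering_coefficients(sur)
        gcc_r.append(c)
        geff_r.append(global_efficiency(sur))
    gcc_ref, geff_ref = float(np.mean(gcc_r)), float(np.mean(geff_r))
    if gcc_ref <= 0 or geff_ref <= 0:
        return float("nan")
    return (gcc / gcc_ref) * (geff / geff_ref)


def hub_disruption_index(subject_degrees: np.ndarray,
                         control_mean_degrees: np.ndarray) -> float:
    """OLS slope of (subject - control mean) regressed on the control mean.

    Negative values mean hubs lose and peripheral nodes gain connections
    (a shift toward a less structured network). NaN when the control means
    have zero variance.
    """
    x = np.asarray(control_mean_degrees, dtype=float)
    y = np.asarray(subject_degrees, dtype=float) - x
    if len(x) != len(y):
        raise ValueError("node counts must match")
    if np.ptp(x) == 0:
        warnings.warn("control mean degrees have zero variance; kd undefined")
        return float("nan")
    return float(np.polyfit(x, y, 1)[0])


def cohort_hub_disruption(degrees: np.ndarray, is_control: np.ndarray) -> np.ndarray:
    """Per-subject kd against the control-group mean degree profile.

    For control subjects the reference excludes the subject's own degrees
    (leave-one-out), avoiding self-reference bias.
    """
    degrees = np.asarray(degrees, dtype=float)   # subjects x nodes
    is_control = np.asarray(is_control, dtype=bool)
    ctl = degrees[is_control]
    n_ctl = ctl.shape[0]
    mean_all = ctl.mean(axis=0)
    kd = np.empty(degrees.shape[0])
    ctl_rank = np.cumsum(is_control) - 1
    for i in range(degrees.shape[0]):
        if is_control[i] and n_ctl > 1:
            ref = (mean_all * n_ctl - ctl[ctl_rank[i]]) / (n_ctl - 1)
        else:
            ref = mean_all
        kd[i] = hub_disruption_index(degrees[i], ref)
    return kd


GLOBAL_METRICS = ("gcc", "geff", "smallworldness", "kd")
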