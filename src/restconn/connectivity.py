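"""All-to-all functional connectivity: PLV, debiased wPLI and orthogonalized AEC.

All three estimators operate on complex analytic signals obtained by
band-pass filtering each epoch and applying the Hilbert transform, with
filter-transient samples trimmed at the epoch edges.

* PLV (phase locking value): ``|mean_t exp(i dphi(t))|`` per epoch, averaged
  over epochs. Captures both zero-lag and lagged coupling; for independent
  uniform phases E[PLV] = sqrt(pi)/(2 sqrt(N)) at N samples.
* dwPLI (debiased weighted phase lag index): built from imaginary
  cross-spectral terms pooled over epochs and samples; blind to zero-lag
  coupling and debiased for sample size (individual estimates may be
  slightly negative).
* AEC (orthogonalized amplitude envelope correlation): each signal's
  component collinear with the other is removed sample-wise in the complex
  domain before enveloping; the two directed correlations are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from ._filters import bandpass
from .beamformer import SourceTimeSeries
from .spectral import BandDefinition, EpochSet


@dataclass
class AnalyticEpochs:
    """Complex analytic signals: epoch x node x sample (edge-trimmed)."""

    data: np.ndarray
    band: BandDefinition
    rate_hz: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("analytic data must be epoch x node x sample")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node association values for one band and estimator."""

    values: np.ndarray
    estimator: str
    band: BandDefinition
    degenerate: bool = False  # e.g. dwPLI with vanishing imaginary parts

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _default_trim(band: BandDefinition, rate_hz: float, n_samples: int) -> int:
    # one cycle of the band's low edge (at least 50 ms), capped to keep data
    trim = max(round(rate_hz / band.lo_hz), round(0.05 * rate_hz))
    return min(trim, (n_samples - 2) // 4)


def analytic_signal(series, band: BandDefinition, rate_hz: float | None = None,
                    trim_s: float | None = None) -> AnalyticEpochs:
    """Band-pass + Hilbert transform per epoch, with edge-sample trimming.

    ``series`` may be an EpochSet, a SourceTimeSeries, an epoch x node x
    sample array, or a single node x sample array (treated as one epoch).
    """
    if isinstance(series, EpochSet):
        data, rate = series.kept, series.rate_hz
        filtered = bandpass(data, band.lo_hz, band.hi_hz, rate, axis=-1)
    elif isinstance(series, SourceTimeSeries):
        data, rate = series.data[None], series.rate_hz
        if series.band.name == band.name:
            filtered = data  # already band-limited by the beamformer stage
        else:
            filtered = bandpass(data, band.lo_hz, band.hi_hz, rate, axis=-1)
    else:
        arr = np.asarray(series, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz required for raw arrays")
        rate = rate_hz
        data = arr[None] if arr.ndim == 2 else arr
        filtered = bandpass(data, band.lo_hz, band.hi_hz, rate, axis=-1)
    if band.hi_hz >= rate / 2.0:
        raise ValueError("band extends beyond the Nyquist frequency")
    analytic = hilbert(filtered, axis=-1)
    n = analytic.shape[-1]
    trim = _default_trim(band, rate, n) if trim_s is None else round(trim_s * rate)
    if trim > 0:
        analytic = analytic[..., trim:n - trim]
    return AnalyticEpochs(analytic, band, rate)


def plv(x: AnalyticEpochs) -> ConnectivityMatrix:
    """Phase locking value per epoch (over time samples), averaged over epochs."""
    if x.n_epochs < 1:
        raise ValueError("need at least one epoch")
    z = x.data / np.abs(x.data)
    n = x.n_samples
    acc = np.zeros((x.n_nodes, x.n_nodes))
    for e in range(x.n_epochs):
        acc += np.abs(z[e] @ z[e].conj().T) / n
    vals = acc / x.n_epochs
    np.fill_diagonal(vals, 0.0)
    vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)
    return ConnectivityMatrix(vals, "plv", x.band)


def dwpli(x: AnalyticEpochs) -> ConnectivityMatrix:
    """Debiased squared weighted phase lag index over pooled cross-spectral terms.

    With imaginary cross-spectral observations I_j per pair, the estimator is
    sum_{j!=k} I_j I_k / sum_{j!=k} |I_j I_k|, equal to
    ((sum I)^2 - sum I^2) / ((sum |I|)^2 - sum I^2). Pairs whose imaginary
    parts vanish identically (pure zero-lag coupling) are defined as 0 and
    the matrix is flagged degenerate.
    """
    if x.n_epochs * x.n_samples < 2:
        raise ValueError("need at least two observations")
    R = np.real(x.data).reshape(-1, x.n_nodes, x.n_samples)
    I = np.imag(x.data).reshape(-1, x.n_nodes, x.n_samples)
    # pool epochs along the sample axis
    R = np.concatenate(list(R), axis=1)
    I = np.concatenate(list(I), axis=1)
    sum_im = I @ R.T - R @ I.T
    sum_sq = (I ** 2) @ (R ** 2).T - 2 * (I * R) @ (R * I).T + (R ** 2) @ (I ** 2).T
    n_nodes = x.n_nodes
    sum_abs = np.empty((n_nodes, n_nodes))
    for a in range(n_nodes):
        sum_abs[a] = np.abs(I[a] * R - R[a] * I).sum(axis=1)
    num = sum_im ** 2 - sum_sq
    den = sum_abs ** 2 - sum_sq
    degenerate = bool(np.any(den <= 1e-12 * np.abs(num).max() if np.abs(num).max() > 0
                             else den <= 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    return ConnectivityMatrix(np.clip(vals, -1.0, 1.0), "dwpli", x.band,
                              degenerate=degenerate)


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between matching rows of a and b."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a ** 2).sum(axis=1))
    sb = np.sqrt((b ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a * b).sum(axis=1) / (sa * sb)
    return r


def aec(x: AnalyticEpochs) -> ConnectivityMatrix:
    """Orthogonalized amplitude envelope correlation, averaged over directions.

    For the ordered pair (a, b), the component of b collinear with a is
    removed sample-wise, Y_orth(t) = Im(y(t) conj(x(t)) / |x(t)|); the
    envelope |Y_orth| is then correlated with |x|. Epochs are concatenated
    before correlation. Entries with a zero-variance envelope are NaN.
    """
    X = np.concatenate(list(x.data), axis=1)   # node x pooled samples
    if X.shape[1] < 2:
        raise ValueError("need at least two samples")
    env = np.abs(X)
    n = x.n_nodes
    c_dir = np.full((n, n), np.nan)
    scale = np.abs(X).max()
    for a in range(n):
        xa = X[a]
        with np.errstate(divide="ignore", invalid="ignore"):
            orth = np.abs(np.imag(X * np.conj(xa)[None, :]) / np.abs(xa)[None, :])
        # rows whose orthogonalized part is numerically zero (e.g. a signal
        # against itself) have an undefined envelope correlation
        degenerate = orth.max(axis=1) < 1e-10 * scale
        c_dir[a] = _corr_rows(np.broadcast_to(env[a], orth.shape), orth)
        c_dir[a, degenerate] = np.nan
    vals = (c_dir + c_dir.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(np.clip(vals, -1.0, 1.0), "aec", x.band)


ESTIMATORS = {"plv": plv, "dwpli": dwpli, "aec": aec}


def connectivity_strength(m: ConnectivityMatrix) -> np.ndarray:
    """Per-node mean connectivity to all other nodes (diagonal excluded)."""
    vals = m.values.copy()
    n = vals.shape[0]
    np.fill_diagonal(vals, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(vals, axis=1) if n > 1 else np.zeros(n)
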