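"""LCMV beamformer: band-specific covariance, spatial filters, source projection.

The linearly constrained minimum variance (LCMV) beamformer passes activity
from a target source location with unit gain while minimising total output
variance. For a source with oriented lead-field column ``l`` and regularised
sensor covariance ``C``, the filter is ``w = (l' C^-1 l)^-1 l' C^-1``.
Regularisation adds a fraction of the mean covariance diagonal to the
diagonal (diagonal loading); the dipole orientation per source is the
direction of maximal beamformer output variance, found by eigendecomposition
of the 3-orientation output covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._filters import bandpass
from .cohort import LeadFieldModel
from .spectral import BandDefinition, EpochSet


@dataclass
class CovarianceMatrix:
    values: np.ndarray
    band: BandDefinition
    n_samples_used: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("covariance must be square")


@dataclass
class SpatialFilter:
    weights: np.ndarray       # sources x channels
    orientations: np.ndarray  # sources x 3 unit vectors
    band: BandDefinition


@dataclass
class SourceTimeSeries:
    data: np.ndarray          # sources x samples
    rate_hz: float
    band: BandDefinition


def band_covariance(epochs: EpochSet, band: BandDefinition) -> CovarianceMatrix:
    """Covariance of band-pass filtered, epoch-concatenated sensor data."""
    kept = epochs.kept
    if kept.shape[0] == 0:
        raise RuntimeError("no kept epochs; cannot estimate covariance")
    filt = bandpass(kept, band.lo_hz, band.hi_hz, epochs.rate_hz, axis=-1)
    x = np.concatenate(list(filt), axis=1)  # channels x (epochs*samples)
    x = x - x.mean(axis=1, keepdims=True)
    c = x @ x.T / (x.shape[1] - 1)
    c = (c + c.T) / 2.0
    return CovarianceMatrix(c, band, n_samples_used=x.shape[1])


def _regularized_inverse(cov: np.ndarray, reg_fraction: float) -> np.ndarray:
    n = cov.shape[0]
    creg = cov + reg_fraction * np.mean(np.diag(cov)) * np.eye(n)
    # average-referenced data are rank-deficient by one; fall back to the
    # pseudo-inverse when diagonal loading leaves the matrix ill-conditioned
    cond = np.linalg.cond(creg)
    if not np.isfinite(cond) or cond > 1e12:
        if reg_fraction > 0:
            raise np.linalg.LinAlgError(
                f"regularized covariance is singular (cond={cond:.3g}); "
                "the sensor data may be degenerate")
        warnings.warn("covariance ill-conditioned; using pseudo-inverse")
        return np.linalg.pinv(creg, hermitian=True)
    return np.linalg.inv(creg)


def lcmv_spatial_filter(cov: CovarianceMatrix, leadfield: LeadFieldModel,
                        reg_fraction: float = 0.05) -> SpatialFilter:
    """Unit-gain LCMV filters with SVD orientation selection per source."""
    if not 0 <= reg_fraction < 1:
        raise ValueError("reg_fraction must lie in [0, 1)")
    c = cov.values
    if c.shape[0] != leadfield.n_sensors:
        raise ValueError("covariance channels do not match lead-field sensors")
    cinv = _regularized_inverse(c, reg_fraction)
    n_src = leadfield.n_sources
    weights = np.empty((n_src, c.shape[0]))
    orients = np.empty((n_src, 3))
    for s in range(n_src):
        L = leadfield.gain[:, s, :]               # channels x 3
        A = L.T @ cinv @ L                        # 3 x 3
        # pinv: the 3x3 system can be rank-deficient when few sources are active
        W3 = np.linalg.pinv(A) @ (L.T @ cinv)     # 3 x channels, unit-gain per axis
        out_cov = W3 @ c @ W3.T
        # orientation of most variance via SVD of the output covariance
        u, _, _ = np.linalg.svd((out_cov + out_cov.T) / 2.0)
        ori = u[:, 0]
        if ori[np.argmax(np.abs(ori))] < 0:       # deterministic sign
            ori = -ori
        l = L @ ori
        denom = l @ cinv @ l
        w = (cinv @ l) / denom
        weights[s] = w
        orients[s] = ori
    return SpatialFilter(weights, orients, cov.band)


def project_sources(data, filt: SpatialFilter, rate_hz: float | None = None):
    """Project sensor data through the spatial filter.

    ``data`` may be an EpochSet (returns epoch x source x sample, band-pass
    filtered to the filter's band first, matching how the covariance was
    built) or a channels x samples array (returns a SourceTimeSeries).
    Projection is linear: project(aX + bY) = a project(X) + b project(Y).
    """
    if isinstance(data, EpochSet):
        kept = data.kept
        if kept.shape[0] and filt.weights.shape[1] != kept.shape[1]:
            raise ValueError("channel count does not match spatial filter")
        filtered = bandpass(kept, filt.band.lo_hz, filt.band.hi_hz,
                            data.rate_hz, axis=-1)
        return np.einsum("sc,ect->est", filt.weights, filtered)
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != filt.weights.shape[1]:
        raise ValueError("expected channels x samples matching the filter")
    return SourceTimeSeries(filt.weights @ arr, rate_hz or 0.0, filt.band)
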