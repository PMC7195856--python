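"""Subject-level feature assembly for the multivariate classifier.

Each subject contributes one feature vector concatenating: the alpha peak
frequency (1), the global power spectrum (one feature per frequency bin),
local band power (bands x channels), and — per connectivity estimator and
band — connectivity strength, node degree and local clustering coefficient
(nodes each), plus the four global graph measures. At the full study
dimensions (199 bins, 65 channels, 2020 nodes, 4 bands, 3 estimators) this
is 1 + 199 + 4*65 + 3*(3*4*2020) + 3*4*4 = 73,228 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import GLOBAL_METRICS
from .spectral import BANDS

BAND_ORDER = tuple(BANDS)
FAMILIES = ("strength", "degree", "local_cc")


@dataclass
class FeatureTable:
    matrix: np.ndarray          # subjects x features
    feature_names: list
    labels: np.ndarray          # group per subject ("patient"/"control")

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("one label per subject required")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("one name per feature column required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def y_signed(self) -> np.ndarray:
        """Labels as ±1 with 'patient' the positive class."""
        return np.where(self.labels == "patient", 1.0, -1.0)


def expected_feature_count(n_bins: int, n_channels: int, n_nodes: int,
                           n_bands: int = 4, n_estimators: int = 3,
                           n_global: int = 4) -> int:
    """Column count of the assembled table at the given dimensions."""
    return (1 + n_bins + n_bands * n_channels
            + 3 * (n_estimators * n_bands * n_nodes)
            + n_estimators * n_bands * n_global)


def assemble_features(subject_features: list, labels,
                      estimators: tuple = ("plv", "dwpli", "aec"),
                      bands: tuple = BAND_ORDER) -> FeatureTable:
    """Concatenate per-subject results into a subjects x features table.

    ``subject_features`` is a list of dicts with keys ``peak`` (scalar),
    ``spectrum`` (bins,), ``local_power`` ({band: (channels,)}),
    ``strength``/``degree``/``local_cc`` ({(estimator, band): (nodes,)}) and
    ``global_graph`` ({(estimator, band): (4,)} ordered gcc, geff,
    smallworldness, kd). Column order is deterministic; a missing component
    raises an error naming the subject and family.
    """
    if not subject_features:
        raise ValueError("no subjects")
    rows = []
    names = None
    for s, feats in enumerate(subject_features):
        row = []
        cols = []
        try:
            row.append(float(feats["peak"]))
            cols.append("peak")
            spec = np.asarray(feats["spectrum"], dtype=float).ravel()
            row.extend(spec)
            cols.extend(f"spectrum_b{i:03d}" for i in range(spec.size))
            for band in bands:
                lp = np.asarray(feats["local_power"][band], dtype=float).ravel()
                row.extend(lp)
                cols.extend(f"power_{band}_ch{c:02d}" for c in range(lp.size))
            for family in FAMILIES:
                for est in estimators:
                    for band in bands:
                        v = np.asarray(feats[family][(est, band)],
                                       dtype=float).ravel()
                        row.extend(v)
                        cols.extend(f"{family}_{est}_{band}_n{i:03d}"
                                    for i in range(v.size))
            for est in estimators:
                for band in bands:
                    g = np.asarray(feats["global_graph"][(est, band)],
                                   dtype=float).ravel()
                    if g.size != len(GLOBAL_METRICS):
                        raise KeyError("global_graph")
                    row.extend(g)
                    cols.extend(f"global_{est}_{band}_{m}" for m in GLOBAL_METRICS)
        except KeyError as exc:
            raise RuntimeError(
                f"subject {s}: missing feature component {exc}") from exc
        if names is None:
            names = cols
        elif cols != names:
            raise RuntimeError(f"subject {s}: inconsistent feature layout")
        rows.append(row)
    matrix = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(matrix)):
        bad = np.nonzero(~np.isfinite(matrix))
        raise RuntimeError(
            f"non-finite feature values, e.g. subject {bad[0][0]} "
            f"column {names[bad[1][0]]}")
    return FeatureTable(matrix, names, np.asarray(labels))
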