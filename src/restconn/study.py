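"""Desk-scale study configurations and end-to-end experiment helpers.

These helpers run the full analysis chain — cohort simulation, epoching,
multitaper power, LCMV source projection, connectivity, graph metrics,
feature assembly — at reduced problem sizes chosen so that repeated
cross-validation experiments complete on a single workstation: 60-second
recordings, 8 sensors, 5 sources, PLV connectivity and a decimated power
spectrum, giving a 122-column feature table. Correctness of every estimator
is node-count- and duration-invariant, so these sizes only trade statistical
resolution, not behaviour.
"""

from __future__ import annotations

import numpy as np

from . import beamformer, connectivity, graphs, spectral
from .classify import permutation_null_accuracy
from .cohort import PlantedEffect, SimulationConfig, generate_cohort, \
    generate_lead_field
from .connectivity import ESTIMATORS
from .features import FeatureTable, assemble_features
from .spectral import BANDS


def reduced_effects() -> list[PlantedEffect]:
    """The standard planted effects, on node indices valid for 5 sources."""
    return [
        PlantedEffect("theta", (0, 1, 2), "phase", strength_a=0.45,
                      strength_b=0.30),
        PlantedEffect("gamma", (0, 1, 3), "phase", strength_a=0.50,
                      strength_b=0.30),
        PlantedEffect("alpha", (2, 3), "amplitude", strength_a=0.40,
                      strength_b=0.40),
    ]


def reduced_config(n_patients: int, n_controls: int, seed: int,
                   duration_s: float = 60.0) -> SimulationConfig:
    return SimulationConfig(
        n_per_group=(n_patients, n_controls), duration_s=duration_s,
        n_sources=5, n_sensors=8, planted_effects=reduced_effects(), seed=seed)


def subject_feature_dict(recording, lead_field, bands=tuple(BANDS),
                         estimators=("plv",), density: float = 0.3,
                         n_surrogates: int = 10, surrogate_seed: int = 0,
                         spectrum_decimate: int = 16) -> dict:
    """Full spectral/source/connectivity/graph feature set for one subject.

    The ``global_graph`` kd slot is NaN here; it is a cohort-level quantity
    filled in by the caller once the control reference exists.
    """
    eps = spectral.segment_epochs(recording)
    eps = spectral.reject_jump_epochs(eps)
    spec = spectral.multitaper_power(eps)
    peak = spectral.peak_frequency(spec, "local_max")
    if not np.isfinite(peak):
        peak = spectral.peak_frequency(spec, "cog")
    out = {
        "peak": peak,
        "spectrum": spec.mean_over_channels()[::spectrum_decimate],
        "local_power": {b: spectral.band_power(spec, BANDS[b]) for b in bands},
        "strength": {}, "degree": {}, "local_cc": {}, "global_graph": {},
    }
    rng = np.random.default_rng(surrogate_seed)
    for bname in bands:
        band = BANDS[bname]
        cov = beamformer.band_covariance(eps, band)
        filt = beamformer.lcmv_spatial_filter(cov, lead_field)
        src = beamformer.project_sources(eps, filt)
        an = connectivity.analytic_signal(src, band, recording.rate_hz)
        for est in estimators:
            m = ESTIMATORS[est](an)
            out["strength"][(est, bname)] = connectivity.connectivity_strength(m)
            g = graphs.proportional_threshold(m, density)
            out["degree"][(est, bname)] = graphs.node_degree(g).degree
            local, gcc = graphs.clustering_coefficients(g)
            out["local_cc"][(est, bname)] = local
            sw = graphs.small_worldness(g, n_random=n_surrogates,
                                        seed=int(rng.integers(0, 2 ** 31 - 1)))
            out["global_graph"][(est, bname)] = np.array(
                [gcc, graphs.global_efficiency(g), sw, np.nan])
    return out


def reduced_feature_table(n_patients: int = 84, n_controls: int = 84,
                          seed: int = 0, duration_s: float = 60.0,
                          estimators=("plv",), density: float = 0.3,
                          spectrum_decimate: int = 16) -> FeatureTable:
    """Simulate a cohort and assemble the reduced feature table end to end."""
    cfg = reduced_config(n_patients, n_controls, seed, duration_s)
    lf = generate_lead_field(cfg.n_sensors, cfg.n_sources, seed=cfg.seed)
    subjects = generate_cohort(cfg, lead_field=lf)
    rng = np.random.default_rng(seed + 1)
    feats = []
    degrees: dict = {}
    for sub in subjects:
        d = subject_feature_dict(sub.recording, lf, estimators=estimators,
                                 density=density,
                                 surrogate_seed=int(rng.integers(0, 2 ** 31 - 1)),
                                 spectrum_decimate=spectrum_decimate)
        for key, deg in d["degree"].items():
            degrees.setdefault(key, []).append(deg)
        feats.append(d)
    is_control = np.array([s.group_label == "control" for s in subjects])
    for key, degs in degrees.items():
        kd = graphs.cohort_hub_disruption(np.asarray(degs), is_control)
        for i, d in enumerate(feats):
            d["global_graph"][key][3] = kd[i]
    labels = [s.group_label for s in subjects]
    # degenerate tiny graphs: undefined small-worldness falls back to 1
    # (self-similar reference) and undefined kd to 0 (no disruption)
    for d in feats:
        for key, g in d["global_graph"].items():
            if not np.isfinite(g[2]):
                g[2] = 1.0
            if not np.isfinite(g[3]):
                g[3] = 0.0
    return assemble_features(feats, labels, estimators=estimators)


def classifier_null_experiment(n_per_group: int = 84, n_repeats: int = 100,
                               seed: int = 0, duration_s: float = 60.0,
                               max_features: int = 10) -> np.ndarray:
    """Label-permutation accuracy distribution of the nested-CV SVM.

    Builds the reduced feature table from a balanced synthetic cohort, then
    repeats the full 10-fold nested forward-selection CV with labels
    shuffled on every repeat. The mean of the returned distribution
    estimates the classifier's chance level.
    """
    table = reduced_feature_table(n_per_group, n_per_group, seed=seed,
                                  duration_s=duration_s)
    return permutation_null_accuracy(table, n_repeats=n_repeats,
                                     seed=seed + 17,
                                     max_features=max_features)
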