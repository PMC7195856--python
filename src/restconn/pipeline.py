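"""Configuration-driven orchestration of the full analysis on a cohort.

The pipeline runs, per subject: epoching and jump rejection, multitaper
power (peak frequency, band power), LCMV projection to source space per
frequency band, all-to-all connectivity per estimator, and graph metrics at
the configured edge density. Cohort-level stages then run cluster-based and
scalar permutation statistics, brain-clinical correlations, and the nested
cross-validated SVM classification. All stage outputs are pure functions of
the inputs and seeds; re-running with an identical configuration reproduces
the JSON results byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import beamformer, connectivity, graphs, spectral, stats
from .classify import (balanced_subsample_repeat, compare_accuracy_distributions,
                       feature_selection_frequency, permutation_null_accuracy)
from .cohort import SimulationConfig, generate_cohort, generate_lead_field
from .connectivity import ESTIMATORS
from .features import assemble_features
from .io import load_lead_field, load_recordings, save_cohort
from .spectral import BANDS


class StageError(RuntimeError):
    """A pipeline stage failed or its inputs are missing."""


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    epoch_length_s: float = 2.0
    overlap_s: float = 1.0
    jump_threshold_uv: float = 100.0
    jump_margin_s: float = 0.4
    bands: tuple = tuple(BANDS)
    estimators: tuple = ("plv", "dwpli", "aec")
    densities: tuple = (0.05, 0.10, 0.20)
    graph_density: float = 0.10          # density used for features and stats
    n_surrogates: int = 10               # small-worldness reference graphs
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    spectrum_decimate: int = 1           # keep every k-th spectrum bin as feature
    run_classification: bool = True
    classify_n_repeats: int = 10
    classify_null_repeats: int = 10
    classify_max_features: int = 10
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        for est in self.estimators:
            if est not in ESTIMATORS:
                raise ValueError(f"unknown estimator {est!r}")
        for b in self.bands:
            if b not in BANDS:
                raise ValueError(f"unknown band {b!r}")
        for d in list(self.densities) + [self.graph_density]:
            if not 0 < d <= 1:
                raise ValueError("edge densities must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["planted_effects"] = [
            dataclasses.asdict(e) for e in self.simulation.planted_effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .cohort import PlantedEffect
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "planted_effects" in sim:
            sim["planted_effects"] = [
                PlantedEffect(**{**e, "nodes": tuple(e["nodes"])})
                for e in sim["planted_effects"]]
        if "n_per_group" in sim:
            sim["n_per_group"] = tuple(sim["n_per_group"])
        for key in ("bands", "estimators", "densities"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(simulation=SimulationConfig(**sim), **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=1, sort_keys=True)
        f.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    lf = generate_lead_field(cfg.simulation.n_sensors, cfg.simulation.n_sources,
                             seed=cfg.simulation.seed)
    subjects = generate_cohort(cfg.simulation, lead_field=lf)
    save_cohort(out, subjects, lf)


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise StageError(f"stage '{stage}' requires missing input {name}; "
                         "run the earlier stages first")
    return p


def _epochs_for(rec, cfg: PipelineConfig):
    eps = spectral.segment_epochs(rec, cfg.epoch_length_s, cfg.overlap_s)
    return spectral.reject_jump_epochs(eps, cfg.jump_threshold_uv,
                                       cfg.jump_margin_s)


def stage_spectral(cfg: PipelineConfig, out: Path) -> None:
    ids, groups, recs = load_recordings(_require(out, "recordings.h5", "spectral"))
    with h5py.File(out / "spectral.h5", "w") as f:
        for sid, rec in zip(ids, recs):
            eps = _epochs_for(rec, cfg)
            spec = spectral.multitaper_power(eps)
            peak = spectral.peak_frequency(spec, "local_max")
            if not np.isfinite(peak):  # no strict local maximum: centre of gravity
                peak = spectral.peak_frequency(spec, "cog")
            g = f.create_group(sid)
            g.create_dataset("power", data=spec.power.astype(np.float32))
            g.create_dataset("freqs", data=spec.freqs_hz)
            g.attrs["peak_hz"] = peak
            g.attrs["group"] = groups[ids.index(sid)]
            total = spectral.total_power(spec)
            for bname in cfg.bands:
                band = BANDS[bname]
                g.create_dataset(f"power_{bname}",
                                 data=spectral.band_power(spec, band))
                g.create_dataset(f"relpower_{bname}",
                                 data=spectral.band_power(spec, band,
                                                          relative=True,
                                                          total=total))


def stage_connectivity(cfg: PipelineConfig, out: Path) -> None:
    ids, groups, recs = load_recordings(
        _require(out, "recordings.h5", "connectivity"))
    lf = load_lead_field(_require(out, "leadfield.h5", "connectivity"))
    with h5py.File(out / "connectivity.h5", "w") as f:
        f.attrs["subjects"] = ids
        f.attrs["groups"] = groups
        for sid, rec in zip(ids, recs):
            eps = _epochs_for(rec, cfg)
            g = f.create_group(sid)
            for bname in cfg.bands:
                band = BANDS[bname]
                cov = beamformer.band_covariance(eps, band)
                filt = beamformer.lcmv_spatial_filter(cov, lf)
                src = beamformer.project_sources(eps, filt)
                an = connectivity.analytic_signal(src, band, rec.rate_hz)
                for est in cfg.estimators:
                    m = ESTIMATORS[est](an)
                    g.create_dataset(f"{est}_{bname}",
                                     data=m.values.astype(np.float32))
                    g.create_dataset(
                        f"strength_{est}_{bname}",
                        data=connectivity.connectivity_strength(m))


def stage_graph(cfg: PipelineConfig, out: Path) -> None:
    rng = np.random.default_rng(cfg.seed + 1)
    with h5py.File(_require(out, "connectivity.h5", "graph"), "r") as fc, \
            h5py.File(out / "graph.h5", "w") as fg:
        ids = [str(x) for x in fc.attrs["subjects"]]
        groups = [str(x) for x in fc.attrs["groups"]]
        fg.attrs["subjects"] = ids
        fg.attrs["groups"] = groups
        degree_store: dict = {}
        for sid in ids:
            g = fg.create_group(sid)
            for est in cfg.estimators:
                for bname in cfg.bands:
                    vals = fc[sid][f"{est}_{bname}"][()].astype(float)
                    bg = graphs.proportional_threshold(vals, cfg.graph_density)
                    nm = graphs.node_degree(bg)
                    local, gcc = graphs.clustering_coefficients(bg)
                    geff = graphs.global_efficiency(bg)
                    sw = graphs.small_worldness(
                        bg, n_random=cfg.n_surrogates,
                        seed=int(rng.integers(0, 2 ** 31 - 1)))
                    gg = g.create_group(f"{est}_{bname}")
                    gg.create_dataset("degree", data=nm.degree)
                    gg.create_dataset("local_cc", data=local)
                    gg.attrs["gcc"] = gcc
                    gg.attrs["geff"] = geff
                    gg.attrs["smallworldness"] = sw
                    degree_store.setdefault((est, bname), []).append(nm.degree)
        is_control = np.array([g == "control" for g in groups])
        for (est, bname), degs in degree_store.items():
            kd = graphs.cohort_hub_disruption(np.asarray(degs), is_control)
            fg.create_dataset(f"kd_{est}_{bname}", data=kd)


def stage_stats(cfg: PipelineConfig, out: Path) -> None:
    lf = load_lead_field(_require(out, "leadfield.h5", "stats"))
    adjacency = stats.grid_adjacency(lf.source_positions)
    results: dict = {"config_hash": cfg.config_hash(), "cluster_tests": {},
                     "global_tests": {}, "correlations": None}
    with h5py.File(_require(out, "connectivity.h5", "stats"), "r") as fc, \
            h5py.File(_require(out, "graph.h5", "stats"), "r") as fg:
        ids = [str(x) for x in fc.attrs["subjects"]]
        groups = np.array([str(x) for x in fc.attrs["groups"]])
        pat = groups == "patient"
        rng = np.random.default_rng(cfg.seed + 2)
        for est in cfg.estimators:
            for bname in cfg.bands:
                strength = np.array(
                    [fc[sid][f"strength_{est}_{bname}"][()] for sid in ids])
                res = stats.cluster_permutation_test(
                    strength[pat], strength[~pat], adjacency,
                    alpha_cluster=cfg.cluster_alpha, n_perm=cfg.n_perm,
                    seed=int(rng.integers(0, 2 ** 31 - 1)))
                strength_d = stats.cohens_d(
                    strength[pat].mean(axis=1), strength[~pat].mean(axis=1))
                results["cluster_tests"][f"strength_{est}_{bname}"] = {
                    "min_p": res.min_p, "t_max": res.max_t, "t_min": res.min_t,
                    "n_clusters": len(res.clusters), "cohens_d": strength_d,
                }
        for est in cfg.estimators:
            for metric in ("gcc", "geff", "smallworldness"):
                pvals = []
                for bname in cfg.bands:
                    vals = np.array(
                        [fg[sid][f"{est}_{bname}"].attrs[metric] for sid in ids])
                    p = stats.scalar_permutation_test(
                        vals[pat], vals[~pat], n_perm=cfg.n_perm,
                        seed=int(rng.integers(0, 2 ** 31 - 1)))
                    pvals.append(p)
                corr = stats.holm_bonferroni(pvals)
                for bname, p_u, p_c in zip(cfg.bands, pvals, corr):
                    results["global_tests"][f"{metric}_{est}_{bname}"] = {
                        "p_uncorrected": float(p_u), "p_corrected": float(p_c)}
            pvals = []
            for bname in cfg.bands:
                kd = fg[f"kd_{est}_{bname}"][()]
                p = stats.scalar_permutation_test(
                    kd[pat], kd[~pat], n_perm=cfg.n_perm,
                    seed=int(rng.integers(0, 2 ** 31 - 1)))
                pvals.append(p)
            corr = stats.holm_bonferroni(pvals)
            for bname, p_u, p_c in zip(cfg.bands, pvals, corr):
                results["global_tests"][f"kd_{est}_{bname}"] = {
                    "p_uncorrected": float(p_u), "p_corrected": float(p_c)}
        # brain-clinical correlations among patients
        cov = pd.read_csv(_require(out, "covariates.csv", "stats"))
        cov = cov.set_index("subject_id").loc[ids]
        with h5py.File(_require(out, "spectral.h5", "stats"), "r") as fs:
            peaks = np.array([fs[sid].attrs["peak_hz"] for sid in ids])
            meas = {"peak_hz": peaks}
            for bname in cfg.bands:
                meas[f"power_{bname}"] = np.array(
                    [fs[sid][f"power_{bname}"][()].mean() for sid in ids])
        est0 = cfg.estimators[0]
        for bname in cfg.bands:
            meas[f"kd_{est0}_{bname}"] = fg[f"kd_{est0}_{bname}"][()]
        measures = pd.DataFrame(meas, index=ids)[pat]
        clinical = cov.loc[pat, [c for c in cov.columns if c != "group"]]
        band_groups = {
            "power": [f"power_{b}" for b in cfg.bands],
            "kd": [f"kd_{est0}_{b}" for b in cfg.bands],
        }
        table = stats.correlate_clinical(measures, clinical, band_groups)
        table.to_csv(out / "correlations.csv", index=False)
        results["correlations"] = "correlations.csv"
    _json_dump(results, out / "stats.json")


def _subject_features(cfg: PipelineConfig, out: Path):
    with h5py.File(_require(out, "spectral.h5", "classify"), "r") as fs, \
            h5py.File(_require(out, "connectivity.h5", "classify"), "r") as fc, \
            h5py.File(_require(out, "graph.h5", "classify"), "r") as fg:
        ids = [str(x) for x in fc.attrs["subjects"]]
        groups = [str(x) for x in fc.attrs["groups"]]
        kd = {key: fg[f"kd_{key[0]}_{key[1]}"][()]
              for key in [(e, b) for e in cfg.estimators for b in cfg.bands]}
        feats = []
        for si, sid in enumerate(ids):
            d = {
                "peak": float(fs[sid].attrs["peak_hz"]),
                "spectrum": fs[sid]["power"][()].mean(axis=0)
                [::cfg.spectrum_decimate],
                "local_power": {b: fs[sid][f"power_{b}"][()] for b in cfg.bands},
                "strength": {}, "degree": {}, "local_cc": {}, "global_graph": {},
            }
            for est in cfg.estimators:
                for b in cfg.bands:
                    gg = fg[sid][f"{est}_{b}"]
                    d["strength"][(est, b)] = fc[sid][f"strength_{est}_{b}"][()]
                    d["degree"][(est, b)] = gg["degree"][()]
                    d["local_cc"][(est, b)] = gg["local_cc"][()]
                    gvec = np.array([
                        gg.attrs["gcc"], gg.attrs["geff"],
                        gg.attrs["smallworldness"], kd[(est, b)][si]])
                    # degenerate tiny graphs: undefined small-worldness falls
                    # back to 1 (self-similar reference), undefined kd to 0
                    if not np.isfinite(gvec[2]):
                        gvec[2] = 1.0
                    if not np.isfinite(gvec[3]):
                        gvec[3] = 0.0
                    d["global_graph"][(est, b)] = gvec
            feats.append(d)
    return feats, groups


def stage_classify(cfg: PipelineConfig, out: Path) -> None:
    feats, groups = _subject_features(cfg, out)
    table = assemble_features(feats, groups, estimators=cfg.estimators,
                              bands=cfg.bands)
    rng = np.random.default_rng(cfg.seed + 3)
    real = balanced_subsample_repeat(
        table, n_repeats=cfg.classify_n_repeats,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
        max_features=cfg.classify_max_features)
    null = permutation_null_accuracy(
        table, n_repeats=cfg.classify_null_repeats,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
        max_features=cfg.classify_max_features)
    p = compare_accuracy_distributions(real.accuracies, null,
                                       seed=int(rng.integers(0, 2 ** 31 - 1)))
    top = feature_selection_frequency(real)[:10]
    _json_dump({
        "config_hash": cfg.config_hash(),
        "n_features": table.n_features,
        "mean_accuracy": real.mean_accuracy,
        "sd_accuracy": real.sd_accuracy,
        "sensitivity": real.sensitivity,
        "specificity": real.specificity,
        "null_mean_accuracy": float(np.mean(null)),
        "null_sd_accuracy": float(np.std(null, ddof=1)) if len(null) > 1 else 0.0,
        "p_vs_null": p,
        "top_features": top,
    }, out / "classification.json")


STAGES = {
    "simulate": stage_simulate,
    "spectral": stage_spectral,
    "connectivity": stage_connectivity,
    "graph": stage_graph,
    "stats": stage_stats,
    "classify": stage_classify,
}


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Run all stages into ``out_dir``; deterministic for a fixed config."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = ["simulate", "spectral", "connectivity", "graph", "stats"]
    if cfg.run_classification:
        order.append("classify")
    log_lines = [f"config_hash: {cfg.config_hash()}", f"seed: {cfg.seed}",
                 f"simulation_seed: {cfg.simulation.seed}"]
    for name in order:
        try:
            STAGES[name](cfg, out)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        log_lines.append(f"stage {name}: ok")
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=True)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
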