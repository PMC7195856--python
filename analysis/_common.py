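"""Shared configuration for the demo analysis: a 20+20 synthetic cohort with
planted frontal theta/gamma phase-coupling increases in the patient group."""

from pathlib import Path

from restconn.cohort import PlantedEffect, SimulationConfig
from restconn.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "demo_run"
RESULTS = ROOT / "results"


def demo_config(seed: int = 0) -> PipelineConfig:
    sim = SimulationConfig(
        n_per_group=(20, 20), duration_s=60.0, n_sources=8, n_sensors=16,
        planted_effects=[
            PlantedEffect("theta", (0, 1, 2), "phase", 0.55, 0.30),
            PlantedEffect("gamma", (0, 1, 3), "phase", 0.60, 0.30),
            PlantedEffect("alpha", (4, 5), "amplitude", 0.40, 0.40),
        ],
        seed=seed)
    return PipelineConfig(
        simulation=sim, graph_density=0.2, n_surrogates=10, n_perm=500,
        spectrum_decimate=4, classify_n_repeats=10, classify_null_repeats=10,
        classify_max_features=8, seed=seed)


def ensure_dirs():
    RUN_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
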