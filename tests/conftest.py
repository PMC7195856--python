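import numpy as np
import pytest

from restconn.cohort import (PlantedEffect, SimulationConfig, generate_lead_field,
                             simulate_subject)
from restconn.spectral import Recording, segment_epochs


@pytest.fixture(scope="session")
def lead_field():
    return generate_lead_field(24, 6, seed=11)


@pytest.fixture(scope="session")
def rate():
    return 250.0


def make_recording(signal_fn, rate=250.0, duration=60.0, n_channels=1):
    t = np.arange(int(rate * duration)) / rate
    data = np.stack([signal_fn(t) for _ in range(n_channels)])
    return Recording(data, rate)


@pytest.fixture(scope="session")
def sine_epochs(rate):
    """2 s epochs of a pure 10 Hz, amplitude-2 sinusoid."""
    rec = make_recording(lambda t: 2.0 * np.cos(2 * np.pi * 10.0 * t), rate)
    return segment_epochs(rec)


def phase_coupled_subject(strength, lag_rad=0.0, band="theta", seed=7,
                          duration=60.0, coupling="phase"):
    cfg = SimulationConfig(
        n_per_group=(1, 1), duration_s=duration, n_sources=4, n_sensors=16,
        planted_effects=[PlantedEffect(band, (0, 1), coupling,
                                       strength, strength, lag_rad=lag_rad)],
        strength_jitter=0.0, seed=5)
    return simulate_subject(cfg, "patient", seed)
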