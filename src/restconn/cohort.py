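"""Synthetic two-group cohorts of multichannel oscillatory recordings.

The generator emulates the structure of a resting-state EEG case-control
study: two groups of subjects, 5-minute recordings at 250 Hz, sources with
1/f background spectra and an alpha peak near 10 Hz, a shared forward model
(lead field) mapping sources to sensors, auxiliary EMG channels, and clinical
covariate tables. Group differences are *planted* as frequency-specific
phase or amplitude coupling between chosen source nodes, with group-specific
coupling strengths, so that every downstream estimator can be validated
against known ground truth.

Phase coupling mixes a shared band-limited process into each coupled node
with weight equal to the coupling strength (plus an optional fixed phase
lag); within the planted band the node's independent background is removed
first, so strength 1 with zero lag yields perfectly locked phases and
strength 0 recovers independence. Amplitude coupling imposes a common slow
envelope modulation on independent narrowband carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.signal import butter, hilbert, sosfiltfilt

from ._filters import bandpass
from .spectral import BANDS, BandDefinition, Recording


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LeadFieldModel:
    """Forward model: gain (sensors x sources x 3 orientations), unit norm per source."""

    gain: np.ndarray
    source_positions: np.ndarray  # sources x 3, cm
    sensor_labels: list[str]
    sensor_positions: np.ndarray = None  # sensors x 2, synthetic flat layout (cm)

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim == 2:
            self.gain = self.gain[:, :, None]
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field contains non-finite entries")
        norms = np.linalg.norm(self.gain, axis=(0, 2))
        if np.any(norms <= 0):
            raise ValueError("every source must have positive gain norm")
        if self.source_positions.shape[0] != self.n_sources:
            raise ValueError("source_positions inconsistent with gain")
        if len(self.sensor_labels) != self.n_sensors:
            raise ValueError("sensor_labels inconsistent with gain")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass(frozen=True)
class PlantedEffect:
    """A planted coupling effect: band, node set, type, group-specific strengths."""

    band: str                      # key into BANDS
    nodes: tuple                   # indices of coupled source nodes
    coupling: str = "phase"        # "phase" | "amplitude"
    strength_a: float = 0.4        # group A ("patient") coupling weight in [0, 1]
    strength_b: float = 0.4        # group B ("control") coupling weight in [0, 1]
    lag_rad: float = 0.0           # fixed phase lag applied to nodes after the first

    def __post_init__(self):
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.coupling not in ("phase", "amplitude"):
            raise ValueError("coupling must be 'phase' or 'amplitude'")
        for s in (self.strength_a, self.strength_b):
            if not 0.0 <= s <= 1.0:
                raise ValueError("coupling strengths must lie in [0, 1]")
        if len(self.nodes) < 2:
            raise ValueError("a planted effect needs at least two nodes")


def default_planted_effects() -> list[PlantedEffect]:
    """The cohort's standard condition: stronger frontal phase coupling in the
    patient group at theta and gamma, and amplitude coupling of equal strength
    in both groups (no planted amplitude difference)."""
    return [
        PlantedEffect("theta", (0, 1, 2), "phase", strength_a=0.45, strength_b=0.30),
        PlantedEffect("gamma", (0, 1, 3), "phase", strength_a=0.50, strength_b=0.30),
        PlantedEffect("alpha", (4, 5), "amplitude", strength_a=0.40, strength_b=0.40),
    ]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort; defaults encode the study conditions."""

    n_per_group: tuple = (101, 84)
    duration_s: float = 300.0
    rate_hz: float = 250.0
    n_sources: int = 200
    n_sensors: int = 64
    background_slope: float = 1.0      # 1/f exponent of the source background
    alpha_peak_hz: float = 10.0
    alpha_amp: float = 1.0             # alpha oscillation SD relative to background
    planted_effects: list = field(default_factory=default_planted_effects)
    planted_amp: float = 1.0           # planted-band oscillation SD
    strength_jitter: float = 0.05      # per-subject uniform jitter on strengths
    noise_sd: float = 0.1              # sensor white-noise SD relative to signal SD
    n_emg: int = 2
    emg_leakage: float = 0.0           # fraction of EMG mixed into sensors
    covariate_link: float = 0.0        # coupling of pain intensity to planted strength
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("subject counts must be positive")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")
        if self.n_sources < 1 or self.n_sensors < 2:
            raise ValueError("need at least 1 source and 2 sensors")
        for eff in self.planted_effects:
            if max(eff.nodes) >= self.n_sources:
                raise ValueError(
                    f"planted node index {max(eff.nodes)} >= n_sources {self.n_sources}")


@dataclass
class SyntheticSubject:
    recording: Recording
    source_truth: np.ndarray           # sources x samples
    emg: np.ndarray                    # emg channels x samples (may be empty)
    covariates: dict
    group_label: str                   # "patient" | "control"
    subject_id: str = ""


# ---------------------------------------------------------------------------
# lead field
# ---------------------------------------------------------------------------

def _source_grid(n_sources: int) -> np.ndarray:
    """Regular 3-D grid with 1 cm spacing, centred; first n_sources in raster order."""
    side = int(np.ceil(n_sources ** (1 / 3)))
    ax = np.arange(side, dtype=float)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])[:n_sources]
    return pos - pos.mean(axis=0)


def _sensor_layout(n_sensors: int) -> np.ndarray:
    """Flat square grid of sensor positions spanning roughly a head radius (cm)."""
    side = int(np.ceil(np.sqrt(n_sensors)))
    ax = np.linspace(-8.0, 8.0, side)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])[:n_sensors]


def generate_lead_field(n_sensors: int, n_sources: int, seed: int = 0,
                        depth_cm: float = 4.0) -> LeadFieldModel:
    """Deterministic synthetic lead field with spatially smooth dipolar gain patterns.

    Each source/orientation projects a dipole-like field onto the flat sensor
    layout (tangential dipole at depth ``depth_cm`` under a jittered location),
    so nearby sensors see similar gains. The sensors x 3 gain block of every
    source is normalised to unit Frobenius norm.
    """
    if n_sensors < 2 or n_sources < 1:
        raise ValueError("need n_sensors >= 2 and n_sources >= 1")
    rng = np.random.default_rng(seed)
    sens = _sensor_layout(n_sensors)
    span = sens[:, 0].max() - sens[:, 0].min() or 1.0
    src = _source_grid(n_sources)
    # map source grid xy onto the sensor sheet
    sxy = src[:, :2]
    if np.ptp(sxy, axis=0).max() > 0:
        sxy = sxy / max(np.ptp(sxy, axis=0).max(), 1.0) * span * 0.7
    gain = np.empty((n_sensors, n_sources, 3))
    for s in range(n_sources):
        centre = sxy[s] + rng.normal(scale=0.5, size=2)
        depth = depth_cm + src[s, 2] * 0.5 + rng.uniform(0, 1)
        rel = sens - centre
        r2 = (rel ** 2).sum(axis=1) + depth ** 2
        # two orthogonal tangential dipole patterns plus a radial pattern,
        # so the three orientation columns are mutually distinguishable
        phi = rng.uniform(0, 2 * np.pi)
        d1 = np.array([np.cos(phi), np.sin(phi)])
        d2 = np.array([-d1[1], d1[0]])
        gain[:, s, 0] = (rel @ d1) / r2 ** 1.5
        gain[:, s, 1] = (rel @ d2) / r2 ** 1.5
        gain[:, s, 2] = depth / r2 ** 1.5
        gain[:, s, :] /= np.linalg.norm(gain[:, s, :])
    labels = [f"ch{i:02d}" for i in range(n_sensors)]
    return LeadFieldModel(gain, src, labels, sensor_positions=sens)


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng, n_samples: int, rate_hz: float, slope: float,
                      size: int) -> np.ndarray:
    """Gaussian processes with power spectrum proportional to 1/f**slope, unit SD."""
    freqs = rfftfreq(n_samples, 1.0 / rate_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-slope / 2.0)
    spec = (rng.normal(size=(size, freqs.size)) +
            1j * rng.normal(size=(size, freqs.size))) * shape
    x = irfft(spec, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _narrowband(rng, n_samples: int, rate_hz: float, lo: float, hi: float,
                size: int = 1) -> np.ndarray:
    """Unit-SD band-limited Gaussian noise."""
    x = bandpass(rng.normal(size=(size, n_samples)), lo, hi, rate_hz)
    x /= x.std(axis=1, keepdims=True)
    return x


def _band_stop(data: np.ndarray, band: BandDefinition, rate_hz: float) -> np.ndarray:
    nyq = rate_hz / 2.0
    sos = butter(4, [band.lo_hz / nyq, band.hi_hz / nyq], btype="bandstop",
                 output="sos")
    return sosfiltfilt(sos, data, axis=-1)


def _phase_shift(x: np.ndarray, lag_rad: float) -> np.ndarray:
    """Shift the phase of a narrowband real signal by ``lag_rad``."""
    if lag_rad == 0.0:
        return x
    return np.real(hilbert(x) * np.exp(-1j * lag_rad))


# ---------------------------------------------------------------------------
# subject and cohort generation
# ---------------------------------------------------------------------------

def _draw_covariates(rng, group: str) -> dict:
    patient = group == "patient"
    return {
        "current_pain": rng.uniform(4, 9) if patient else 0.0,
        "average_pain": rng.uniform(4, 9) if patient else 0.0,
        "pain_duration_y": rng.uniform(0.5, 30) if patient else 0.0,
        "pain_disability": rng.uniform(10, 60) if patient else 0.0,
        "depression_bdi": rng.uniform(2, 28) if patient else rng.uniform(0, 8),
        "medication_mqs": rng.uniform(0, 20) if patient else 0.0,
        "qol_mental": rng.uniform(25, 55) if patient else rng.uniform(45, 62),
        "qol_physical": rng.uniform(20, 50) if patient else rng.uniform(45, 62),
    }


def simulate_subject(config: SimulationConfig, group: str, seed: int,
                     lead_field: LeadFieldModel | None = None) -> SyntheticSubject:
    """Simulate one subject: sources -> lead field projection -> sensor noise.

    Sources are 1/f background plus an alpha-band oscillation; nodes listed in
    the config's planted effects additionally receive phase- or amplitude-
    coupled band-limited oscillations with the group's coupling strength.
    """
    config.validate()
    if group not in ("patient", "control"):
        raise ValueError("group must be 'patient' or 'control'")
    rng = np.random.default_rng(seed)
    if lead_field is None:
        lead_field = generate_lead_field(config.n_sensors, config.n_sources,
                                         seed=config.seed)
    n = round(config.duration_s * config.rate_hz)
    rate = config.rate_hz
    ns = config.n_sources

    sources = _one_over_f_noise(rng, n, rate, config.background_slope, ns)
    lo = max(config.alpha_peak_hz - 1.5, 6.0)
    hi = min(config.alpha_peak_hz + 1.5, 14.0)
    alpha = _narrowband(rng, n, rate, lo, hi, size=ns)
    amp_scale = rng.uniform(0.5, 1.5, size=(ns, 1))
    sources = sources + config.alpha_amp * amp_scale * alpha

    strength_used = []
    for eff in config.planted_effects:
        band = BANDS[eff.band]
        base = eff.strength_a if group == "patient" else eff.strength_b
        c = base + rng.uniform(-config.strength_jitter, config.strength_jitter)
        c = float(np.clip(c, 0.0, 1.0))
        strength_used.append(c)
        nodes = list(eff.nodes)
        if eff.coupling == "phase":
            shared = _narrowband(rng, n, rate, band.lo_hz, band.hi_hz)[0]
            own = _narrowband(rng, n, rate, band.lo_hz, band.hi_hz, size=len(nodes))
            # remove the nodes' independent background content in this band so the
            # mixing weight alone controls phase locking
            sources[nodes] = _band_stop(sources[nodes], band, rate)
            for k, node in enumerate(nodes):
                sh = shared if k == 0 else _phase_shift(shared, eff.lag_rad)
                mix = np.sqrt(max(1.0 - c ** 2, 0.0)) * own[k] + c * sh
                sources[node] = sources[node] + config.planted_amp * mix
        else:  # amplitude coupling: common slow envelope on independent carriers
            carriers = _narrowband(rng, n, rate, band.lo_hz, band.hi_hz,
                                   size=len(nodes))
            slow = bandpass(rng.normal(size=n), 0.1, 1.0, rate)
            slow = slow / slow.std()
            sources[nodes] = _band_stop(sources[nodes], band, rate)
            for k, node in enumerate(nodes):
                modul = 1.0 + 0.5 * c * slow
                sources[node] = (sources[node] +
                                 config.planted_amp * carriers[k] * modul)

    # fixed dipole orientation per source, drawn once per subject
    orient = rng.normal(size=(ns, 3))
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)
    mixing = np.einsum("cso,so->cs", lead_field.gain, orient)
    sensor = mixing @ sources
    sensor = sensor / sensor.std() * 10.0  # ~10 µV scale
    sensor = sensor + config.noise_sd * 10.0 * rng.normal(size=sensor.shape)

    emg = rng.normal(size=(config.n_emg, n)) if config.n_emg else np.empty((0, n))
    if config.n_emg and config.emg_leakage:
        sensor = sensor + config.emg_leakage * 10.0 * emg[0]

    cov = _draw_covariates(rng, group)
    if config.covariate_link and strength_used:
        cov["current_pain"] += config.covariate_link * float(np.mean(strength_used))

    rec = Recording(sensor, rate, list(lead_field.sensor_labels))
    return SyntheticSubject(rec, sources, emg, cov, group)


def generate_cohort(config: SimulationConfig,
                    lead_field: LeadFieldModel | None = None) -> list[SyntheticSubject]:
    """Generate the full two-group cohort with deterministic per-subject seeds."""
    config.validate()
    if lead_field is None:
        lead_field = generate_lead_field(config.n_sensors, config.n_sources,
                                         seed=config.seed)
    n_pat, n_ctl = config.n_per_group
    master = np.random.default_rng(np.random.SeedSequence(config.seed))
    seeds = master.integers(0, 2 ** 31 - 1, size=n_pat + n_ctl)
    subjects = []
    for i in range(n_pat + n_ctl):
        group = "patient" if i < n_pat else "control"
        subj = simulate_subject(config, group, int(seeds[i]), lead_field=lead_field)
        subj.subject_id = f"sub-{i:03d}"
        subjects.append(subj)
    return subjects


def cohort_covariates(subjects: list[SyntheticSubject]):
    """Covariate table: one row per subject (id, group, covariates)."""
    import pandas as pd

    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "group": s.group_label}
        row.update(s.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
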