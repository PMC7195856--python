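"""Epoching, artifact-jump rejection, multitaper power and peak-frequency estimation.

All estimators in the package operate on overlapping fixed-length epochs of a
continuous multichannel recording. Power spectral densities are computed with
Slepian (DPSS) multitapers on each epoch and averaged over the epochs that
survive artifact rejection; the canonical analysis grid is 1–100 Hz in steps
of 0.5 Hz (199 bins), which a 2-second epoch at any integer rate resolves
natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A multichannel recording: channels x samples (µV) with rate and labels."""

    data: np.ndarray
    rate_hz: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be channels x samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not self.labels:
            self.labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class EpochSet:
    """Overlapping fixed-length segments: epoch x channel x sample, plus a keep mask."""

    epochs: np.ndarray
    rate_hz: float
    epoch_length_s: float
    overlap_s: float
    kept_mask: np.ndarray = None
    starts: np.ndarray = None  # absolute start sample of each epoch

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.starts is None:
            step = round((self.epoch_length_s - self.overlap_s) * self.rate_hz)
            self.starts = np.arange(self.epochs.shape[0]) * step
        self.starts = np.asarray(self.starts)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def kept(self) -> np.ndarray:
        """Epoch array restricted to epochs that survived rejection."""
        return self.epochs[self.kept_mask]


@dataclass
class PowerSpectrum:
    """Per-channel power (µV²) on a frequency grid, with the taper half-bandwidth."""

    freqs_hz: np.ndarray
    power: np.ndarray  # channels x freqs
    smoothing_hz: float = 1.0

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))

    def mean_over_channels(self) -> np.ndarray:
        return self.power.mean(axis=0)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float


#: The four analysis bands. Theta and alpha share the 8 Hz edge; bin selection
#: is half-open [lo, hi) except for gamma, which is closed [60, 100].
BANDS = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 14.0, 30.0),
    "gamma": BandDefinition("gamma", 60.0, 100.0),
}


def band_mask(freqs_hz: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Boolean mask of grid bins belonging to ``band`` ([lo, hi); gamma closed)."""
    freqs_hz = np.asarray(freqs_hz)
    if band.name == "gamma":
        return (freqs_hz >= band.lo_hz) & (freqs_hz <= band.hi_hz)
    return (freqs_hz >= band.lo_hz) & (freqs_hz < band.hi_hz)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def segment_epochs(recording: Recording, length_s: float = 2.0,
                   overlap_s: float = 1.0) -> EpochSet:
    """Cut a recording into overlapping epochs; the trailing remainder is dropped."""
    if not (0 <= overlap_s < length_s):
        raise ValueError("require 0 <= overlap_s < length_s")
    rate = recording.rate_hz
    ns = round(length_s * rate)
    step = round((length_s - overlap_s) * rate)
    total = recording.n_samples
    if total < ns:
        warnings.warn("recording shorter than one epoch; empty EpochSet")
        return EpochSet(np.empty((0, recording.n_channels, ns)), rate,
                        length_s, overlap_s, starts=np.empty(0, dtype=int))
    n_ep = (total - ns) // step + 1
    starts = np.arange(n_ep) * step
    epochs = np.stack([recording.data[:, s:s + ns] for s in starts])
    return EpochSet(epochs, rate, length_s, overlap_s, starts=starts)


def reject_jump_epochs(epochs: EpochSet, threshold_uv: float = 100.0,
                       margin_s: float = 0.4) -> EpochSet:
    """Reject epochs overlapping ±margin around any sample-to-sample jump > threshold.

    A jump is a first difference exceeding ``threshold_uv`` in magnitude on any
    channel. Because epochs may overlap in time, absolute sample positions are
    used, so a jump near an epoch edge also invalidates the neighbouring epoch
    that shares those samples. Idempotent: kept epochs contain no jumps.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    margin = round(margin_s * epochs.rate_hz)
    ns = epochs.n_samples
    bad_positions = set()
    for e in range(epochs.n_epochs):
        d = np.abs(np.diff(epochs.epochs[e], axis=1))
        ch, pos = np.nonzero(d > threshold_uv)
        for p in pos:
            bad_positions.add(int(epochs.starts[e]) + int(p))
    kept = epochs.kept_mask.copy()
    if bad_positions:
        bad = np.array(sorted(bad_positions))
        for e in range(epochs.n_epochs):
            lo = epochs.starts[e] - margin
            hi = epochs.starts[e] + ns - 1 + margin
            if np.any((bad >= lo) & (bad <= hi)):
                kept[e] = False
    return EpochSet(epochs.epochs, epochs.rate_hz, epochs.epoch_length_s,
                    epochs.overlap_s, kept_mask=kept, starts=epochs.starts)


def _taper_count(epoch_length_s: float, smoothing_hz: float) -> int:
    # time-bandwidth NW = T * W; K = 2NW - 1 tapers (2 s x ±1 Hz -> 3 tapers)
    nw = epoch_length_s * smoothing_hz
    return max(1, int(round(2 * nw - 1)))


def multitaper_power(epochs: EpochSet, smoothing_hz: float = 1.0,
                     fmin: float = 1.0, fmax: float = 100.0) -> PowerSpectrum:
    """Slepian-multitaper power spectrum averaged over kept epochs.

    The estimate is scaled so that the sum of the one-sided spectrum over all
    frequency bins equals the signal variance (Parseval). For 2-second epochs
    the native grid restricted to 1–100 Hz is exactly the 199-bin, 0.5 Hz grid.
    """
    data = epochs.kept
    if data.shape[0] == 0:
        raise RuntimeError("no kept epochs; cannot estimate power")
    n = epochs.n_samples
    nw = epochs.epoch_length_s * smoothing_hz
    k = _taper_count(epochs.epoch_length_s, smoothing_hz)
    tapers = dpss(n, nw, Kmax=k)  # unit-energy windows, shape k x n
    freqs = rfftfreq(n, d=1.0 / epochs.rate_hz)
    # epoch x channel x taper x freq
    tapered = data[:, :, None, :] * tapers[None, None, :, :]
    spec = np.abs(rfft(tapered, axis=-1)) ** 2
    # one-sided scaling: double everything except DC (and Nyquist if present)
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    psd = spec.mean(axis=2) * scale / n  # mean over tapers; Parseval scaling
    psd = psd.mean(axis=0)           # mean over epochs -> channel x freq
    sel = (freqs >= fmin) & (freqs <= fmax)
    return PowerSpectrum(freqs[sel], psd[:, sel], smoothing_hz=smoothing_hz)


def line_noise_mask(spectrum: PowerSpectrum, lo_hz: float = 45.0,
                    hi_hz: float = 55.0) -> np.ndarray:
    """Boolean mask of bins OUTSIDE the line-noise exclusion band.

    The exclusion is a mask on the spectral grid (it keeps the full grid
    intact); it is intended for display and for spectra contaminated by
    nonstationary mains noise, not a time-domain filter.
    """
    f = spectrum.freqs_hz
    return (f < lo_hz) | (f > hi_hz)


def total_power(spectrum: PowerSpectrum) -> float:
    """Total power: sum over all grid bins and all channels."""
    return float(spectrum.power.sum())


def band_power(spectrum: PowerSpectrum, band: BandDefinition,
               relative: bool = False, total: float | None = None) -> np.ndarray:
    """Mean power over the band's bins, per channel; optionally relative.

    Relative power divides by the subject's total power (summed over the full
    1–100 Hz grid and all channels), supplied via ``total`` or computed here.
    """
    m = band_mask(spectrum.freqs_hz, band)
    if not m.any():
        raise ValueError(f"band {band.name} outside the spectrum grid")
    bp = spectrum.power[:, m].mean(axis=1)
    if relative:
        t = total_power(spectrum) if total is None else total
        bp = bp / t
    return bp


def _local_max_peak(freqs: np.ndarray, amp: np.ndarray,
                    lo: float, hi: float) -> float:
    """Frequency of the highest strict local maximum of ``amp`` within [lo, hi].

    Returns NaN when no strict local maximum exists in the range (e.g. a
    monotonic spectrum); ties go to the lowest frequency.
    """
    interior = np.arange(1, len(freqs) - 1)
    is_max = (amp[interior] > amp[interior - 1]) & (amp[interior] > amp[interior + 1])
    cand = interior[is_max]
    cand = cand[(freqs[cand] >= lo) & (freqs[cand] <= hi)]
    if cand.size == 0:
        return float("nan")
    best = cand[np.argmax(amp[cand])]  # argmax returns first of equals -> lowest f
    return float(freqs[best])


def peak_frequency(obj, method: str = "local_max", lo_hz: float = 6.0,
                   hi_hz: float = 14.0, smoothing_hz: float = 1.0,
                   long_window_s: float = 5.0, recording: Recording = None) -> float:
    """Dominant peak frequency in [6, 14] Hz, by one of four methods.

    ``local_max``
        Highest strict local maximum (larger than both neighbours) of the
        channel-averaged amplitude spectrum; NaN when no local maximum exists.
    ``cog``
        Centre of gravity sum(f*P)/sum(P) of the channel-averaged power over
        the range.
    ``long_window``
        Re-estimates the spectrum on 5-second windows of the original
        recording (finer frequency resolution) and applies ``local_max``.
    ``per_epoch``
        ``local_max`` on each single kept epoch, then the mean of the defined
        per-epoch peaks.

    ``obj`` is a PowerSpectrum for ``local_max``/``cog`` and an EpochSet for
    ``per_epoch`` (a PowerSpectrum is also computed from an EpochSet when
    needed); ``long_window`` additionally requires ``recording``.
    """
    if method in ("local_max", "cog"):
        spec = obj if isinstance(obj, PowerSpectrum) else multitaper_power(obj, smoothing_hz)
        p = spec.mean_over_channels()
        if method == "cog":
            m = (spec.freqs_hz >= lo_hz) & (spec.freqs_hz <= hi_hz)
            if not m.any():
                raise ValueError("spectrum does not cover the peak search range")
            return float(np.sum(spec.freqs_hz[m] * p[m]) / np.sum(p[m]))
        return _local_max_peak(spec.freqs_hz, np.sqrt(p), lo_hz, hi_hz)
    if method == "long_window":
        rec = recording if recording is not None else obj
        if not isinstance(rec, Recording):
            raise ValueError("long_window requires the original Recording")
        eps = segment_epochs(rec, length_s=long_window_s, overlap_s=long_window_s / 2)
        spec = multitaper_power(eps, smoothing_hz)
        return _local_max_peak(spec.freqs_hz, np.sqrt(spec.mean_over_channels()),
                               lo_hz, hi_hz)
    if method == "per_epoch":
        if not isinstance(obj, EpochSet):
            raise ValueError("per_epoch requires an EpochSet")
        peaks = []
        for e in np.nonzero(obj.kept_mask)[0]:
            one = EpochSet(obj.epochs[e:e + 1], obj.rate_hz, obj.epoch_length_s,
                           obj.overlap_s, starts=obj.starts[e:e + 1])
            spec = multitaper_power(one, smoothing_hz)
            pk = _local_max_peak(spec.freqs_hz, np.sqrt(spec.mean_over_channels()),
                                 lo_hz, hi_hz)
            if np.isfinite(pk):
                peaks.append(pk)
        return float(np.mean(peaks)) if peaks else float("nan")
    raise ValueError(f"unknown peak-frequency method: {method!r}")
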