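"""Zero-phase band-pass filtering shared by the beamformer and connectivity stages."""

from __future__ import annotations

import numpy as np
from scipy import signal


def bandpass_sos(lo_hz: float, hi_hz: float, rate_hz: float, order: int = 4):
    """Second-order sections of a Butterworth band-pass filter.

    Applied forward-backward (``sosfiltfilt``) so that phase relations between
    channels are preserved, which matters for phase-coupling estimators.
    """
    nyq = rate_hz / 2.0
    if hi_hz >= nyq:
        raise ValueError(
            f"band upper edge {hi_hz} Hz is at or above Nyquist ({nyq} Hz)"
        )
    if lo_hz <= 0 or lo_hz >= hi_hz:
        raise ValueError(f"invalid band [{lo_hz}, {hi_hz}] Hz")
    return signal.butter(order, [lo_hz / nyq, hi_hz / nyq], btype="band", output="sos")


def bandpass(data: np.ndarray, lo_hz: float, hi_hz: float, rate_hz: float,
             order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass along ``axis``; pad length capped for short epochs."""
    sos = bandpass_sos(lo_hz, hi_hz, rate_hz, order=order)
    n = data.shape[axis]
    padlen = min(3 * (2 * sos.shape[0] + 1) * 10, n - 1)
    return signal.sosfiltfilt(sos, data, axis=axis, padlen=padlen)
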