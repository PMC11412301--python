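"""Surface-EMG preprocessing: low-pass, notch, rectify, RMS envelope,
MVC normalization.

All filters are applied forward-backward (zero phase).  The low-pass is a
4th-order Butterworth (effective 8th order after filtfilt); the notch is a
2nd-order IIR with Q = 30.  The RMS envelope uses a centered sliding
window, truncated at the edges, so the envelope carries no group delay
and preserves signal length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

#: chain defaults
LOWPASS_CUTOFF_HZ = 250.0
NOTCH_CENTER_HZ = 60.0
NOTCH_Q = 30.0
RMS_WINDOW_S = 0.25


@dataclass
class EnvelopeSeries:
    """A nonnegative EMG envelope (percent MVC once normalized)."""

    values: np.ndarray
    sample_rate: float
    muscle: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


def lowpass_filter(x: np.ndarray, cutoff: float,
                   sample_rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass; length preserved."""
    nyq = sample_rate / 2.0
    if not 0.0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = sps.butter(4, cutoff, btype="lowpass", fs=sample_rate,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def notch_filter(x: np.ndarray, center: float,
                 sample_rate: float, q: float = NOTCH_Q) -> np.ndarray:
    """Zero-phase IIR notch suppressing the line-frequency component."""
    nyq = sample_rate / 2.0
    if not 0.0 < center < nyq:
        raise ValueError(f"notch center must lie in (0, {nyq}) Hz")
    b, a = sps.iirnotch(center, q, fs=sample_rate)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value."""
    return np.abs(np.asarray(x, dtype=float))


def rms_envelope(x: np.ndarray, window: float,
                 sample_rate: float) -> np.ndarray:
    """Sliding-window RMS with a centered window, truncated at the edges.

    Each output sample is sqrt(mean(x^2)) over a window of ``window``
    seconds centered on it; near the edges the window shrinks to the
    available samples.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window * sample_rate))
    if w < 1:
        raise ValueError("window must span at least one sample")
    if w > len(x):
        raise ValueError("window longer than signal")
    kernel = np.ones(w)
    sumsq = np.convolve(x * x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return np.sqrt(sumsq / counts)


def normalize_to_mvc(envelope: EnvelopeSeries | np.ndarray,
                     mvc_peak: float) -> EnvelopeSeries:
    """Express an envelope in percent of the MVC peak envelope."""
    if mvc_peak <= 0:
        raise ValueError("mvc_peak must be strictly positive")
    if isinstance(envelope, EnvelopeSeries):
        values, fs, muscle = envelope.values, envelope.sample_rate, \
            envelope.muscle
    else:
        values, fs, muscle = np.asarray(envelope, dtype=float), 0.0, ""
    return EnvelopeSeries(values=values / mvc_peak * 100.0,
                          sample_rate=fs, muscle=muscle)


def process_channel(raw: np.ndarray, mvc_peak: float, sample_rate: float, *,
                    lowpass_cutoff: float = LOWPASS_CUTOFF_HZ,
                    notch_center: float = NOTCH_CENTER_HZ,
                    rms_window: float = RMS_WINDOW_S,
                    muscle: str = "") -> EnvelopeSeries:
    """Full chain: low-pass -> notch -> rectify -> RMS -> percent MVC."""
    x = lowpass_filter(raw, lowpass_cutoff, sample_rate)
    x = notch_filter(x, notch_center, sample_rate)
    x = rms_envelope(rectify(x), rms_window, sample_rate)
    env = EnvelopeSeries(values=x, sample_rate=sample_rate, muscle=muscle)
    return normalize_to_mvc(env, mvc_peak)
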