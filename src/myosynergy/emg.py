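"""Raw EMG to normalized activation envelopes.

The processing chain follows the standard surface-EMG recipe: a 20 Hz
fourth-order zero-lag (forward-backward) Butterworth high-pass to remove
motion artefact and DC, full-wave rectification, a 5 Hz fourth-order zero-lag
Butterworth low-pass to form the linear envelope, and per-muscle division by
calibrated maxima.  "Fourth-order zero-lag" is read as a 4th-order design
applied forward and backward (effective 8th-order magnitude response); edges
are handled with reflective padding of three times the filter order.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy import signal as sps

from .recording import Recording

#: Per-muscle calibrated maximum envelope amplitudes (strictly positive).
CalibrationMaxima = Mapping[str, float]


def _zero_lag_butter(x: np.ndarray, cutoff: float, fs: float, order: int, btype: str) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = sps.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=3 * order * 2)


def highpass_filter(raw: Recording, cutoff: float = 20.0, order: int = 4) -> Recording:
    """High-pass filter a raw recording (zero-phase Butterworth)."""
    if raw.domain != "raw":
        raise ValueError("highpass_filter expects a raw-domain recording")
    out = _zero_lag_butter(raw.signal, cutoff, raw.sample_rate, order, "highpass")
    return raw.with_signal(out, domain="raw")


def compute_envelope(filtered: Recording, cutoff: float = 5.0, order: int = 4) -> Recording:
    """Full-wave rectify and low-pass filter to obtain activation envelopes.

    Negative low-pass ringing is clipped to zero so the envelope honours the
    non-negativity contract of the synergy model.
    """
    if filtered.domain != "raw":
        raise ValueError("compute_envelope expects a raw-domain recording")
    rect = np.abs(filtered.signal)
    env = _zero_lag_butter(rect, cutoff, filtered.sample_rate, order, "lowpass")
    return filtered.with_signal(np.clip(env, 0.0, None), domain="envelope")


def normalize_envelope(env: Recording, maxima: CalibrationMaxima) -> Recording:
    """Divide each channel by its calibrated maximum; clip to [0, 1]."""
    if env.domain != "envelope":
        raise ValueError("normalize_envelope expects an envelope-domain recording")
    scale = np.empty(len(env.channel_labels))
    for k, label in enumerate(env.channel_labels):
        if label not in maxima:
            raise ValueError(f"no calibration maximum for channel {label!r}")
        m = float(maxima[label])
        if not m > 0:
            raise ValueError(f"calibration maximum for {label!r} must be positive")
        scale[k] = m
    out = np.clip(env.signal / scale[:, None], 0.0, 1.0)
    return env.with_signal(out, domain="envelope")


def process_raw(raw: Recording, maxima: CalibrationMaxima,
                hp_cutoff: float = 20.0, lp_cutoff: float = 5.0,
                order: int = 4) -> Recording:
    """Full chain: high-pass, rectify + low-pass, normalize."""
    return normalize_envelope(
        compute_envelope(highpass_filter(raw, hp_cutoff, order), lp_cutoff, order),
        maxima,
    )
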