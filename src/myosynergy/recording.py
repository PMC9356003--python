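"""Core containers for multichannel EMG recordings and trial annotations.

A :class:`Recording` holds a channels x samples signal matrix together with the
labelled trial windows that the downstream synergy analysis consumes.  Signals
live either in the ``raw`` domain (band-limited interference-pattern EMG) or in
the ``envelope`` domain (rectified, low-pass filtered, non-negative activation
envelopes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Canonical channel ordering: tibialis anterior, tibialis posterior,
#: lateral gastrocnemius, peroneus longus.
MUSCLES = ("TA", "TP", "GA", "PL")

#: The four principal ankle/subtalar movements.
MOVEMENTS = ("PF", "DF", "IN", "EV")


@dataclass(frozen=True)
class TrialWindow:
    """A labelled task interval within a recording.

    ``time_constraint`` is set only for speed-accuracy trials and
    ``rom_fraction`` only for perception trials (commanded fraction of the
    range of motion).
    """

    movement: str
    t_start: float
    t_end: float
    time_constraint: Optional[float] = None
    rom_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement {self.movement!r}")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.rom_fraction is not None and not 0.0 < self.rom_fraction <= 1.0:
            raise ValueError("rom_fraction must lie in (0, 1]")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Recording:
    """Multichannel time series with trial annotations."""

    sample_rate: float
    signal: np.ndarray  # channels x samples
    windows: list[TrialWindow] = field(default_factory=list)
    channel_labels: Sequence[str] = MUSCLES
    domain: str = "envelope"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels must match signal rows")
        if self.domain not in ("raw", "envelope"):
            raise ValueError("domain must be 'raw' or 'envelope'")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.domain == "envelope" and np.any(self.signal < 0):
            raise ValueError("envelope-domain signal must be non-negative")
        for w in self.windows:
            if w.t_end > self.duration + 1e-9:
                raise ValueError(f"window {w} exceeds recording duration")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def window_slice(self, window: TrialWindow) -> slice:
        """Sample slice covering ``window`` (end-exclusive)."""
        i0 = int(round(window.t_start * self.sample_rate))
        i1 = int(round(window.t_end * self.sample_rate))
        return slice(max(i0, 0), min(i1, self.n_samples))

    def window_signal(self, window: TrialWindow) -> np.ndarray:
        return self.signal[:, self.window_slice(window)]

    def with_signal(self, signal: np.ndarray, domain: Optional[str] = None) -> "Recording":
        return replace(self, signal=signal, domain=domain or self.domain)


def concatenate_windows(rec: Recording, windows: Optional[Sequence[TrialWindow]] = None) -> np.ndarray:
    """Stack the signal of the given windows along time (channels x samples)."""
    windows = list(rec.windows if windows is None else windows)
    if not windows:
        raise ValueError("no windows to concatenate")
    return np.concatenate([rec.window_signal(w) for w in windows], axis=1)
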