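"""Core container for uniformly sampled waveforms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel labels: ECG, or TL for the transmitted-light photoplethysmogram.
VALID_LABELS = ("ECG", "TL")


@dataclass
class RawSignal:
    """A uniformly sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Signal values, arbitrary units.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Channel kind, ``"ECG"`` or ``"TL"`` (transmitted light).
    units : str
        Free-text unit label.
    """

    samples: np.ndarray
    fs: float
    label: str = "ECG"
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n / fs)."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self.samples)) / self.fs
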