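"""Tachogram construction, artifact cleaning and even resampling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from pulsehrv.beats import FiducialSeries

TACHOGRAM_KINDS = ("RRI", "DDI", "SSI", "dP1", "dP2")

_FIDUCIAL_TO_KIND = {
    "R": "RRI",
    "DDI_point": "DDI",
    "SSI_point": "SSI",
    "dP1_point": "dP1",
    "dP2_point": "dP2",
}

#: Hard physiological interval bounds used by the cleaning rule (ms).
CLEAN_MIN_MS = 300.0
CLEAN_MAX_MS = 2000.0
#: Relative deviation from the local-neighbour median that flags an artifact.
CLEAN_REL_DEV = 0.30
CLEAN_N_NEIGHBOURS = 5
#: Removal fraction above which a quality warning is raised (%).
QUALITY_WARN_PCT = 20.0

#: Rate of the evenly resampled series (Hz).
EVEN_FS = 5.0
#: Minimum span (s) for one spectral window.
MIN_SPECTRAL_SPAN_S = 300.0


@dataclass
class Tachogram:
    """Inter-beat intervals (ms) anchored at the later fiducial of each pair.

    ``mu_ibi`` is the mean interval in seconds; ``pct_removed`` the
    percentage of segment duration removed by cleaning.
    """

    intervals: np.ndarray
    anchor_times: np.ndarray
    kind: str
    pct_removed: float = 0.0
    quality_warning: bool = False

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.anchor_times = np.asarray(self.anchor_times, dtype=float)
        if self.kind not in TACHOGRAM_KINDS:
            raise ValueError(f"kind must be one of {TACHOGRAM_KINDS}, got {self.kind!r}")
        if len(self.intervals) != len(self.anchor_times):
            raise ValueError("intervals and anchor_times must have equal length")
        if len(self.anchor_times) > 1 and not (np.diff(self.anchor_times) > 0).all():
            raise ValueError("anchor_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def mu_ibi(self) -> float:
        """Mean inter-beat interval in seconds."""
        return float(np.mean(self.intervals)) / 1000.0


def build_tachogram(fid: FiducialSeries) -> Tachogram:
    """Beat-by-beat intervals from a fiducial series.

    Interval i = (t_{i+1} - t_i) * 1000 ms, anchored at t_{i+1}; n
    fiducials yield n - 1 intervals.
    """
    if len(fid) < 2:
        raise ValueError("at least 2 fiducials are required")
    iv = np.diff(fid.times) * 1000.0
    return Tachogram(intervals=iv, anchor_times=fid.times[1:],
                     kind=_FIDUCIAL_TO_KIND[fid.kind])


def _neighbour_median(iv: np.ndarray, i: int, k: int = CLEAN_N_NEIGHBOURS) -> float:
    """Median of the k nearest neighbours of index i (by index, self excluded)."""
    n = len(iv)
    order = sorted(range(n), key=lambda j: (abs(j - i), j))
    neigh = [j for j in order if j != i][:k]
    return float(np.median(iv[neigh]))


def clean_tachogram(t: Tachogram) -> Tachogram:
    """Automated artifact removal.

    Intervals outside [300, 2000] ms, or deviating by more than 30 % from
    the median of their 5 nearest neighbours, are removed; the rule is
    iterated to a fixed point so cleaning is idempotent.  ``pct_removed``
    is the removed duration as a percentage of the original segment
    duration; above 20 % a quality warning flag is set.
    """
    if len(t) == 0:
        raise ValueError("empty tachogram")
    total_ms = float(np.sum(t.intervals))
    iv = t.intervals.copy()
    at = t.anchor_times.copy()
    removed_ms = 0.0
    while len(iv) > 0:
        bad = (iv < CLEAN_MIN_MS) | (iv > CLEAN_MAX_MS)
        if len(iv) > 1:
            med = np.array([_neighbour_median(iv, i) for i in range(len(iv))])
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(iv - med) / med
            bad |= rel > CLEAN_REL_DEV
        if not bad.any():
            break
        removed_ms += float(np.sum(iv[bad]))
        iv, at = iv[~bad], at[~bad]
    pct = 100.0 * removed_ms / total_ms if total_ms > 0 else 0.0
    warn = pct > QUALITY_WARN_PCT
    if warn:
        warnings.warn(
            f"{pct:.1f}% of the segment removed by cleaning — quality concern",
            RuntimeWarning)
    return Tachogram(intervals=iv, anchor_times=at, kind=t.kind,
                     pct_removed=pct, quality_warning=warn)


@dataclass
class UniformSeries:
    """Evenly resampled interval series (ms) at 5 Hz."""

    values: np.ndarray
    fs: float = EVEN_FS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs != EVEN_FS:
            raise ValueError(f"UniformSeries rate is fixed at {EVEN_FS} Hz")

    def __len__(self) -> int:
        return len(self.values)


def resample_even(t: Tachogram, warn_gap_s: float = 5.0) -> UniformSeries:
    """Linear interpolation of (anchor time, interval) pairs onto a 5 Hz grid.

    The grid spans [first, last] anchor.  Gaps left by cleaning are
    interpolated across; a gap longer than ``warn_gap_s`` raises a
    warning.  A span shorter than 300 s (one spectral window) also warns.
    """
    if len(t) < 2:
        raise ValueError("at least 2 intervals are required")
    span = t.anchor_times[-1] - t.anchor_times[0]
    if span < MIN_SPECTRAL_SPAN_S:
        warnings.warn(
            f"span {span:.0f} s is shorter than one {MIN_SPECTRAL_SPAN_S:.0f} s "
            "spectral window", RuntimeWarning)
    gaps = np.diff(t.anchor_times)
    if (gaps > warn_gap_s).any():
        warnings.warn(
            f"interpolating across a gap longer than {warn_gap_s} s", RuntimeWarning)
    n = int(np.floor(span * EVEN_FS)) + 1
    grid = t.anchor_times[0] + np.arange(n) / EVEN_FS
    vals = np.interp(grid, t.anchor_times, t.intervals)
    return UniformSeries(values=vals, fs=EVEN_FS, start_time=float(t.anchor_times[0]))
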