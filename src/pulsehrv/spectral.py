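"""Welch power spectra with broadband smoothing and HRV band powers.

Spectra are one-sided densities in ms^2/Hz normalised so that the
integral over frequency equals the (windowed) signal variance; band
powers are therefore in ms^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from pulsehrv.tachogram import UniformSeries

#: Welch window length (s) and overlap fraction.
WINDOW_S = 300.0
OVERLAP = 0.9

#: HRV band edges (Hz): lower bound inclusive, upper exclusive.
VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

#: Relative bandwidth of the broadband moving-average smoother.
SMOOTH_REL_BW = 0.1


@dataclass
class Spectrum:
    freqs: np.ndarray
    psd: np.ndarray
    window_s: float = WINDOW_S
    overlap: float = OVERLAP
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if len(self.freqs) != len(self.psd):
            raise ValueError("freqs and psd must have equal length")
        if (self.psd < 0).any():
            raise ValueError("psd must be non-negative")


@dataclass
class BandPowers:
    """Band powers in ms^2 and the LF/HF ratio (NaN when HF = 0)."""

    vlf: float
    lf: float
    hf: float

    @property
    def lf_hf(self) -> float:
        if self.hf == 0:
            return float("nan")
        return self.lf / self.hf


def welch_psd(u: UniformSeries) -> Spectrum:
    """Welch periodogram: 300 s Hann windows, 90 % overlap, linear detrend.

    Frequency grid step is 1 / 300 Hz; the one-sided density integrates to
    the windowed-signal variance.
    """
    nperseg = int(round(WINDOW_S * u.fs))
    if len(u) < nperseg:
        raise ValueError(
            f"series of {len(u)} samples is shorter than one "
            f"{nperseg}-sample window")
    noverlap = int(round(OVERLAP * nperseg))
    freqs, psd = sps.welch(
        u.values, fs=u.fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="linear", scaling="density", return_onesided=True)
    return Spectrum(freqs=freqs, psd=psd, smoothed=False)


def broadband_smooth(s: Spectrum) -> Spectrum:
    """Moving average whose order grows with frequency (~10 % relative
    bandwidth): half-width h(f) = max(1, round(0.1 f / df)) bins, with
    truncated windows at the edges."""
    if s.smoothed:
        raise ValueError("spectrum is already smoothed")
    df = s.freqs[1] - s.freqs[0]
    n = len(s.psd)
    out = np.empty(n)
    half = np.maximum(1, np.round(SMOOTH_REL_BW * s.freqs / df).astype(int))
    for i in range(n):
        h = half[i]
        out[i] = s.psd[max(0, i - h): min(n, i + h + 1)].mean()
    return Spectrum(freqs=s.freqs.copy(), psd=out,
                    window_s=s.window_s, overlap=s.overlap, smoothed=True)


def _band_integral(freqs: np.ndarray, psd: np.ndarray,
                   band: tuple[float, float]) -> float:
    """Trapezoidal integral over [lo, hi] with interpolated exact edges."""
    lo, hi = band
    inside = (freqs > lo) & (freqs < hi)
    f = np.concatenate([[lo], freqs[inside], [hi]])
    p = np.concatenate([[np.interp(lo, freqs, psd)], psd[inside],
                        [np.interp(hi, freqs, psd)]])
    return float(np.trapezoid(p, f))


def band_powers(s: Spectrum) -> BandPowers:
    """Integrate the (smoothed) spectrum over the VLF, LF and HF bands."""
    return BandPowers(
        vlf=_band_integral(s.freqs, s.psd, VLF_BAND),
        lf=_band_integral(s.freqs, s.psd, LF_BAND),
        hf=_band_integral(s.freqs, s.psd, HF_BAND),
    )
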