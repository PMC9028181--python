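"""Resampling, filtering and differentiation of raw signals."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from pulsehrv.signals import RawSignal

#: Cut-off (Hz) of the zero-phase low-pass applied before differentiation.
LOWPASS_CUTOFF = 25.0
LOWPASS_ORDER = 4


def resample_linear(sig: RawSignal, target_fs: float) -> RawSignal:
    """Resample by linear interpolation onto a uniform grid at ``target_fs``.

    Output samples sit at k / target_fs for k = 0 .. floor(T * target_fs),
    where T is the time of the last original sample; duration is preserved
    within one original sample period.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if len(sig.samples) < 2:
        raise ValueError("signal must have at least 2 samples")
    t_last = (len(sig.samples) - 1) / sig.fs
    n_out = int(np.floor(t_last * target_fs)) + 1
    t_new = np.arange(n_out) / target_fs
    new = np.interp(t_new, sig.times, sig.samples)
    return RawSignal(new, fs=target_fs, label=sig.label, units=sig.units)


def lowpass25(sig: RawSignal, cutoff: float = LOWPASS_CUTOFF,
              order: int = LOWPASS_ORDER) -> RawSignal:
    """Zero-phase Butterworth low-pass (forward-backward filtering).

    The effective magnitude response is the squared one-pass Butterworth
    response; phase is exactly zero.  Edges are reflect-padded before
    filtering to suppress transients.
    """
    if sig.fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {sig.fs} Hz too low for a {cutoff} Hz cutoff")
    b, a = sps.butter(order, cutoff, fs=sig.fs)
    out = sps.filtfilt(b, a, sig.samples, padtype="even")
    return RawSignal(out, fs=sig.fs, label=sig.label, units=sig.units)


def derivative(sig: RawSignal, order: int = 1) -> RawSignal:
    """Central-difference derivative (1st or 2nd order), per second.

    Interior points use central differences (exact on polynomials up to
    degree 2); endpoints use one-sided differences.  Intended to run on a
    low-pass-filtered signal — differentiation amplifies high-frequency
    noise.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    dt = 1.0 / sig.fs
    out = np.gradient(sig.samples, dt)
    if order == 2:
        out = np.gradient(out, dt)
    return RawSignal(out, fs=sig.fs, label=sig.label,
                     units=f"{sig.units}/s" + ("" if order == 1 else "2"))
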