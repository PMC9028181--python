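"""Synthetic ECG/PPG generation with known beat-time ground truth.

Beat times come from an integral pulse frequency modulation (IPFM) model:
an instantaneous rate (1 + s(t)) / T0 is integrated and a beat is emitted
each time the integral crosses an integer.  The modulating signal s(t)
carries an LF and an HF sinusoid plus a band-limited 1/f background, the
canonical structure of sleep heart rate variability.

The PPG channel is built as a train of asymmetric pulse templates placed
at the beat times *plus* a pulse arrival time (PAT) that may itself be
modulated sinusoidally — emulating respiratory modulation of pulse wave
velocity, the mechanism that injects variability into pulse-rate
tachograms which is absent from the ECG R-R series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from pulsehrv.signals import RawSignal

#: IPFM integration grid step (s); much finer than any sampling period used.
IPFM_GRID_DT = 1e-3

#: Band limits (Hz) for the 1/f modulation background.
ONE_OVER_F_BAND = (0.003, 0.4)

#: Physiological bounds on an inter-beat interval (s).
IBI_MIN, IBI_MAX = 0.3, 2.5

# Pulse template shape constants: two log-normal bumps.
# (amplitude, median time in units of T0-independent seconds, log-sd)
SYSTOLIC_BUMP = (1.0, 0.17, 0.35)
DICROTIC_BUMP = (0.28, 0.45, 0.28)
#: Template support as a fraction of the base interval T0; kept below the
#: shortest interval the default modulation depths produce.
TEMPLATE_SUPPORT_FRAC = 0.75
#: Fraction of the support over which the template tapers to zero.
TEMPLATE_TAPER_FRAC = 0.15

# ECG template: narrow positive R spike (~20 ms wide) plus a smooth T hump.
R_SIGMA = 0.004      # s; total spike width ~5 sigma ~ 20 ms
T_AMP = 0.15
T_DELAY = 0.26       # s after R
T_SIGMA = 0.05       # s
ECG_TEMPLATE_HALFSPAN = 0.45  # s


@dataclass
class SimConfig:
    """Parameters of one simulated recording.

    Attributes
    ----------
    duration : float
        Recording length in seconds.
    t0 : float
        Base inter-beat interval (s), within [0.3, 2.0].
    amp_lf, amp_hf : float
        Dimensionless amplitudes of the LF and HF rate modulation.
    f_lf, f_hf : float
        Modulation frequencies (Hz); defaults 0.10 (LF) and 0.25 (HF,
        respiratory).
    one_over_f_level : float
        Dimensionless scale of the band-limited 1/f rate background.
    pat0 : float
        Baseline pulse arrival time (s).
    pat_amp : float
        Amplitude of the sinusoidal PAT modulation (s).
    pat_freq : float
        PAT modulation frequency (Hz); respiratory by default.
    ecg_fs, ppg_fs : float
        Sampling rates of the ECG and PPG channels (Hz).
    ppg_bits : int
        ADC resolution of the PPG channel, within [4, 16].
    seed : int
        Mandatory seed; all stochastic output is reproducible.
    """

    duration: float = 900.0
    t0: float = 1.0
    amp_lf: float = 0.05
    amp_hf: float = 0.03
    f_lf: float = 0.10
    f_hf: float = 0.25
    one_over_f_level: float = 0.05
    pat0: float = 0.25
    pat_amp: float = 0.010
    pat_freq: float = 0.25
    ecg_fs: float = 200.0
    ppg_fs: float = 75.0
    ppg_bits: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not 0.3 <= self.t0 <= 2.0:
            raise ValueError(f"t0 must lie in [0.3, 2.0] s, got {self.t0}")
        for name in ("amp_lf", "amp_hf", "one_over_f_level", "pat_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pat0 < 0:
            raise ValueError("pat0 must be non-negative")
        if not 4 <= int(self.ppg_bits) <= 16:
            raise ValueError(f"ppg_bits must lie in [4, 16], got {self.ppg_bits}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class BeatTimes:
    """Strictly increasing beat instants in seconds (ground truth)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        d = np.diff(self.times)
        if len(d) and not (d > 0).all():
            raise ValueError("beat times must be strictly increasing")
        if len(d) and ((d < IBI_MIN) | (d > IBI_MAX)).any():
            raise ValueError(
                f"inter-beat intervals must lie in [{IBI_MIN}, {IBI_MAX}] s"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def intervals(self) -> np.ndarray:
        """True inter-beat intervals in seconds."""
        return np.diff(self.times)


def one_over_f_noise(n: int, dt: float, rng: np.random.Generator,
                     band: tuple[float, float] = ONE_OVER_F_BAND) -> np.ndarray:
    """Band-limited 1/f noise with unit standard deviation.

    White Gaussian noise is shaped in the frequency domain by a 1/sqrt(f)
    amplitude filter restricted to ``band`` and transformed back; the
    result is normalised to SD 1 (zero outside the band).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, dt)
    shape = np.zeros_like(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    shape[in_band] = 1.0 / np.sqrt(freqs[in_band])
    out = np.fft.irfft(spec * shape, n)
    sd = out.std()
    if sd == 0:
        return np.zeros(n)
    return out / sd


def _modulation(cfg: SimConfig, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    s = (cfg.amp_lf * np.sin(2 * np.pi * cfg.f_lf * t)
         + cfg.amp_hf * np.sin(2 * np.pi * cfg.f_hf * t))
    if cfg.one_over_f_level > 0:
        s = s + cfg.one_over_f_level * one_over_f_noise(len(t), IPFM_GRID_DT, rng)
    return s


def simulate_beat_times(cfg: SimConfig) -> BeatTimes:
    """Generate beat instants by integral pulse frequency modulation.

    The instantaneous rate (1 + s(t)) / T0 is integrated on a 1 ms grid
    (trapezoidal rule); beat k occurs when the running integral first
    reaches k, with linear interpolation of the crossing time.

    Raises
    ------
    ValueError
        If the modulation reaches \\|s(t)\\| >= 1 anywhere (the
        instantaneous rate would become non-positive).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration / IPFM_GRID_DT)) + 1
    t = np.arange(n) * IPFM_GRID_DT
    s = _modulation(cfg, t, rng)
    if np.abs(s).max() >= 1:
        raise ValueError(
            "modulation reaches |s(t)| >= 1; instantaneous rate would be non-positive"
        )
    rate = (1.0 + s) / cfg.t0
    integral = np.concatenate(
        [[0.0], np.cumsum((rate[:-1] + rate[1:]) / 2.0) * IPFM_GRID_DT]
    )
    n_beats = int(np.floor(integral[-1]))
    ks = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(integral, ks)  # first grid point with integral >= k
    lo = integral[idx - 1]
    hi = integral[idx]
    frac = (ks - lo) / (hi - lo)
    beat_t = t[idx - 1] + frac * IPFM_GRID_DT
    return BeatTimes(beat_t)


def _ecg_template(u: np.ndarray) -> np.ndarray:
    r = np.exp(-0.5 * (u / R_SIGMA) ** 2)
    tw = T_AMP * np.exp(-0.5 * ((u - T_DELAY) / T_SIGMA) ** 2)
    return r + tw


def simulate_ecg(beats: BeatTimes, fs: float = 200.0,
                 duration: float | None = None) -> RawSignal:
    """Render an ECG-like waveform with unit-amplitude R spikes at the beats.

    Each beat contributes an identical complex: a narrow Gaussian R wave
    (~20 ms wide) and a smooth T hump.  ``duration`` defaults to the last
    beat time plus 1.5 s.
    """
    if fs < 100:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    if duration is None:
        duration = float(beats.times[-1]) + 1.5
    n = int(round(duration * fs))
    sig = np.zeros(n)
    half = int(round(ECG_TEMPLATE_HALFSPAN * fs))
    for tk in beats.times:
        c = int(round(tk * fs))
        i0, i1 = max(0, c - half), min(n, c + half + 1)
        u = np.arange(i0, i1) / fs - tk
        sig[i0:i1] += _ecg_template(u)
    return RawSignal(sig, fs=fs, label="ECG", units="mV")


def _lognormal_bump(u: np.ndarray, amp: float, med: float, sigma: float) -> np.ndarray:
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = amp * np.exp(-0.5 * (np.log(u[pos] / med) / sigma) ** 2)
    return out


def pulse_template(u: np.ndarray, t0: float) -> np.ndarray:
    """Asymmetric pulse waveform: fast systolic rise, slower decay with a
    dicrotic wave; support limited to ``TEMPLATE_SUPPORT_FRAC * t0`` with a
    raised-cosine taper so the tail reaches zero smoothly."""
    support = TEMPLATE_SUPPORT_FRAC * t0
    p = (_lognormal_bump(u, *SYSTOLIC_BUMP) + _lognormal_bump(u, *DICROTIC_BUMP))
    taper_start = support * (1 - TEMPLATE_TAPER_FRAC)
    w = np.ones_like(u)
    tail = (u > taper_start) & (u < support)
    w[tail] = 0.5 * (1 + np.cos(np.pi * (u[tail] - taper_start)
                                / (support - taper_start)))
    w[u >= support] = 0.0
    w[u <= 0] = 0.0
    return p * w


def quantize(x: np.ndarray, bits: int) -> np.ndarray:
    """Uniform quantization of ``x`` to 2**bits levels over its range.

    The maximum absolute error is half a quantization step.
    """
    lo, hi = x.min(), x.max()
    if hi == lo:
        return x.copy()
    levels = 2 ** int(bits) - 1
    step = (hi - lo) / levels
    return lo + np.round((x - lo) / step) * step


def simulate_ppg(beats: BeatTimes, cfg: SimConfig,
                 do_quantize: bool = True) -> RawSignal:
    """Render the transmitted-light (TL) PPG channel.

    The absorbed-light waveform is AL(t) = sum_k P(t - t_k - PAT(t_k))
    with PAT(t) = pat0 + pat_amp * sin(2 pi pat_freq t); the returned
    signal is TL = baseline - AL, sampled at ``cfg.ppg_fs`` and quantized
    to ``cfg.ppg_bits`` levels over its dynamic range (set
    ``do_quantize=False`` for the continuous-amplitude waveform).
    """
    support = TEMPLATE_SUPPORT_FRAC * cfg.t0
    min_ibi = np.diff(beats.times).min() if len(beats) > 1 else np.inf
    if support > min_ibi:
        warnings.warn(
            "pulse template duration exceeds the minimum inter-beat interval; "
            "pulses will overlap", RuntimeWarning)
    duration = float(beats.times[-1]) + cfg.pat0 + cfg.pat_amp + support + 0.5
    fs = cfg.ppg_fs
    n = int(round(duration * fs))
    al = np.zeros(n)
    pat = cfg.pat0 + cfg.pat_amp * np.sin(2 * np.pi * cfg.pat_freq * beats.times)
    arrivals = beats.times + pat
    span = int(np.ceil(support * fs)) + 1
    for ta in arrivals:
        i0 = max(0, int(np.floor(ta * fs)))
        i1 = min(n, i0 + span + 1)
        u = np.arange(i0, i1) / fs - ta
        al[i0:i1] += pulse_template(u, cfg.t0)
    baseline = al.max() + 0.05 * (al.max() - al.min() + 1e-12)
    tl = baseline - al
    if do_quantize:
        tl = quantize(tl, cfg.ppg_bits)
    return RawSignal(tl, fs=fs, label="TL", units="a.u.")
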