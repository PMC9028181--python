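"""Fiducial-point detection on ECG and PPG waveforms.

Five beat-to-beat fiducial series are supported: the ECG R peak and four
PPG landmarks — the diastolic transmitted-light maximum (DDI point), the
systolic absorbed-light maximum (SSI point), and the maxima of the first
(dP1) and second (dP2) derivatives of the absorbed light on the pulse
upstroke.  Both detectors follow a derivative-and-threshold scheme with
parabolic interpolation refining every fiducial to sub-sample precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pulsehrv.preprocess import derivative, lowpass25
from pulsehrv.signals import RawSignal

FIDUCIAL_KINDS = ("R", "DDI_point", "SSI_point", "dP1_point", "dP2_point")

#: Refractory period (s): 200 bpm ceiling, physiological during sleep.
REFRACTORY_S = 0.3
#: Adaptive threshold = THRESHOLD_FRAC x the recent peak envelope of the
#: detection function (windowed maximum of 1 s block maxima over ~5 s).
THRESHOLD_FRAC = 0.4
THRESHOLD_WINDOW_S = 5.0
#: dP1/dP2 search extends this far before the pulse foot (s).
FOOT_BACKTRACK_S = 0.1


@dataclass
class FiducialSeries:
    """Refined event times (s) for one fiducial kind."""

    kind: str
    times: np.ndarray
    source_fs: float

    def __post_init__(self) -> None:
        if self.kind not in FIDUCIAL_KINDS:
            raise ValueError(f"kind must be one of {FIDUCIAL_KINDS}, got {self.kind!r}")
        self.times = np.asarray(self.times, dtype=float)
        d = np.diff(self.times)
        if len(d) and not (d > 0).all():
            raise ValueError("fiducial times must be strictly increasing")
        if len(d) and (d < REFRACTORY_S - 1e-9).any():
            raise ValueError(
                f"consecutive fiducials closer than the {REFRACTORY_S} s refractory period")

    def __len__(self) -> int:
        return len(self.times)


def refine_parabolic(samples3: np.ndarray, fs: float) -> float:
    """Sub-sample refinement of a discrete extremum.

    Given three consecutive samples with the middle one largest, returns
    the vertex abscissa of the interpolating parabola as a time offset in
    seconds relative to the middle sample, clipped to +-half a sample.  A
    flat triple yields offset 0.
    """
    y0, y1, y2 = (float(v) for v in samples3)
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return delta / fs


def _running_threshold(e: np.ndarray, fs: float,
                       frac: float = THRESHOLD_FRAC,
                       window_s: float = THRESHOLD_WINDOW_S) -> np.ndarray:
    """Adaptive threshold: frac x the recent peak envelope.

    The envelope is the windowed maximum of 1 s block maxima over a
    +-window/2 neighbourhood: it tracks amplitude drift on the time scale
    of a few beats while staying anchored to the event peaks themselves —
    a quantile of all samples would sit far below narrow spikes that
    occupy only a small fraction of each window."""
    block = max(1, int(round(fs)))
    n_blocks = max(1, int(np.ceil(len(e) / block)))
    half = max(1, int(round(window_s / 2)))
    block_max = np.array([e[i * block:(i + 1) * block].max()
                          for i in range(n_blocks)])
    thr_blocks = np.array([block_max[max(0, i - half): i + half + 1].max()
                           for i in range(n_blocks)])
    thr = np.repeat(thr_blocks, block)[: len(e)]
    return frac * thr


def _suprathreshold_regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as half-open (start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def _apply_refractory(times: np.ndarray) -> np.ndarray:
    """Keep-first suppression of events closer than the refractory period."""
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= REFRACTORY_S:
            kept.append(t)
    return np.asarray(kept)


def _refine_at(x: np.ndarray, idx: int, fs: float) -> float:
    """Parabolic-refined time (s) of a discrete extremum at ``idx``."""
    if 0 < idx < len(x) - 1:
        return idx / fs + refine_parabolic(x[idx - 1: idx + 2], fs)
    return idx / fs


def detect_r_peaks(ecg: RawSignal) -> FiducialSeries:
    """Locate ECG R peaks by a derivative-and-threshold algorithm.

    The squared first derivative is compared against an adaptive running
    threshold; within each suprathreshold region the sample of maximal
    absolute deviation from the local baseline is taken (making the
    detector invariant to polarity inversion), a 0.3 s refractory period
    suppresses double detections, and parabolic interpolation refines each
    peak to a continuous time.
    """
    if ecg.fs < 100:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    x = ecg.samples
    fs = ecg.fs
    d = np.gradient(x, 1.0 / fs)
    e = d * d
    thr = _running_threshold(e, fs)
    regions = _suprathreshold_regions(e > thr)
    margin = int(round(0.025 * fs))
    cand = []
    for start, stop in regions:
        i0, i1 = max(0, start - margin), min(len(x), stop + margin)
        seg = x[i0:i1]
        dev = np.abs(seg - np.median(seg))
        pk = i0 + int(np.argmax(dev))
        cand.append(_refine_at(dev, pk - i0, fs) + i0 / fs)
    cand = np.unique(np.asarray(cand))
    if len(cand) == 0:
        if ecg.duration >= 10:
            raise ValueError("no beats detected")
        cand = np.asarray([])
    times = _apply_refractory(cand)
    return FiducialSeries(kind="R", times=times, source_fs=fs)


def _ppg_landmarks(tl: RawSignal) -> dict[str, np.ndarray]:
    """Detect all four PPG fiducial series on a 200 Hz TL signal.

    Absorbed light AL = -TL is low-pass filtered; beats are localised on
    the squared positive AL upstroke velocity.  Per beat: dP1 = maximum of
    the first AL derivative on the upstroke; the systolic AL maximum
    follows it; the pulse foot (AL minimum) precedes it; dP2 = maximum of
    the second AL derivative in [foot - 100 ms, AL peak].  The diastolic
    TL maximum (DDI point) is searched in the open interval between
    consecutive pulse feet.
    """
    fs = tl.fs
    al = RawSignal(-tl.samples, fs=fs, label="TL", units=tl.units)
    alf = lowpass25(al)
    d1 = derivative(alf, 1).samples
    d2 = derivative(alf, 2).samples
    a = alf.samples
    up = np.clip(d1, 0, None) ** 2
    thr = _running_threshold(up, fs)
    regions = _suprathreshold_regions(up > thr)

    w_peak = int(round(0.40 * fs))   # forward window for the systolic peak
    w_foot = int(round(0.30 * fs))   # backward window for the foot
    w_back = int(round(FOOT_BACKTRACK_S * fs))

    dp1_idx, dp2_idx, ssi_idx, foot_idx = [], [], [], []
    for start, stop in regions:
        i_dp1 = start + int(np.argmax(d1[start:stop]))
        j1 = min(len(a), i_dp1 + w_peak)
        i_peak = i_dp1 + int(np.argmax(a[i_dp1:j1]))
        j0 = max(0, i_dp1 - w_foot)
        vals = a[j0:i_dp1 + 1]
        # last sample within 1% of the pulse amplitude of the minimum: the
        # pulse onset, stable against dither along the flat baseline
        amp = a[j0:j1].max() - vals.min()
        near_min = np.flatnonzero(vals <= vals.min() + 0.01 * amp)
        i_foot = j0 + int(near_min[-1])
        k0 = max(0, i_foot - w_back)
        i_dp2 = k0 + int(np.argmax(d2[k0:i_peak + 1]))
        dp1_idx.append(i_dp1)
        dp2_idx.append(i_dp2)
        ssi_idx.append(i_peak)
        foot_idx.append(i_foot)

    # Refractory on the upstroke anchor; drop whole beats.
    dp1_t = np.asarray(dp1_idx) / fs
    keep = np.zeros(len(dp1_t), dtype=bool)
    last = -np.inf
    for i, t in enumerate(dp1_t):
        if t - last >= REFRACTORY_S:
            keep[i] = True
            last = t
    dp1_idx = [v for v, k in zip(dp1_idx, keep) if k]
    dp2_idx = [v for v, k in zip(dp2_idx, keep) if k]
    ssi_idx = [v for v, k in zip(ssi_idx, keep) if k]
    foot_idx = [v for v, k in zip(foot_idx, keep) if k]

    # The diastolic maximum is searched on the unfiltered TL: the raw signal
    # keeps a flat diastolic stretch flat, so the first sample attaining the
    # window maximum is a stable landmark; zero-phase filtering would bend
    # the stretch into a noise-sensitive dome.
    tl_raw = tl.samples
    ddi_t = []
    for f0, f1 in zip(foot_idx[:-1], foot_idx[1:]):
        if f1 - f0 < 3:
            continue
        win = tl_raw[f0 + 1: f1]
        # last sample within 1% of the window amplitude of the maximum: the
        # late-diastolic maximum is pinned against the steep onset of the
        # next pulse, stable against quantization dither along the slowly
        # decaying diastolic stretch
        tol = 0.01 * (win.max() - win.min())
        near_max = np.flatnonzero(win >= win.max() - tol)
        i_max = f0 + 1 + int(near_max[-1])
        ddi_t.append(_refine_at(tl_raw, i_max, fs))

    out = {
        "dP1_point": np.asarray([_refine_at(d1, i, fs) for i in dp1_idx]),
        "dP2_point": np.asarray([_refine_at(d2, i, fs) for i in dp2_idx]),
        "SSI_point": np.asarray([_refine_at(a, i, fs) for i in ssi_idx]),
        "DDI_point": np.asarray(ddi_t),
    }
    return out


def detect_ppg_fiducials(tl: RawSignal, kind: str) -> FiducialSeries:
    """Detect one PPG fiducial series on a transmitted-light signal.

    ``tl`` must already be resampled to ~200 Hz.  ``kind`` is one of
    ``DDI_point``, ``SSI_point``, ``dP1_point``, ``dP2_point``.
    """
    if kind not in ("DDI_point", "SSI_point", "dP1_point", "dP2_point"):
        raise ValueError(f"invalid PPG fiducial kind {kind!r}")
    marks = _ppg_landmarks(tl)
    times = marks[kind]
    if len(times) < 2:
        raise ValueError(f"fewer than 2 {kind} fiducials detected")
    return FiducialSeries(kind=kind, times=times, source_fs=tl.fs)
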