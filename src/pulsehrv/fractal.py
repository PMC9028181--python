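"""Multiscale detrended fluctuation analysis (DFA-1) with beat-to-time
scale mapping.

The fluctuation function F(n) is computed on the beat domain; local
slopes alpha_B(n) of log F vs log n are mapped to temporal scales via
tau = n * mu_IBI, and the short- and long-term self-similarity
coefficients alpha1 and alpha2 are averages of alpha(tau) over
5 <= tau <= 12 s and 12 < tau <= 360 s respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Box sizes per decade (log-spaced).
BOXES_PER_DECADE = 16
#: Smallest box size (beats).
MIN_BOX = 4
#: Half-width (decades) of the local-slope regression window.
SLOPE_HALFWIDTH_DECADES = 0.3
#: Minimum series length (beats): alpha2 needs tau up to 360 s.
MIN_BEATS = 500

#: Temporal-scale bands (s) for alpha1 / alpha2.
ALPHA1_BAND = (5.0, 12.0)    # closed: 5 <= tau <= 12
ALPHA2_BAND = (12.0, 360.0)  # half-open: 12 < tau <= 360


@dataclass
class DFACurve:
    n_beats: np.ndarray
    F: np.ndarray
    tau: np.ndarray
    alpha_tau: np.ndarray
    alpha1: float
    alpha2: float
    mu_ibi: float


def _box_sizes(n_samples: int) -> np.ndarray:
    n_max = n_samples // 4
    if n_max < MIN_BOX:
        raise ValueError("series too short for DFA")
    exps = np.arange(np.log10(MIN_BOX), np.log10(n_max) + 1e-12,
                     1.0 / BOXES_PER_DECADE)
    sizes = np.unique(np.round(10.0 ** exps).astype(int))
    return sizes[(sizes >= MIN_BOX) & (sizes <= n_max)]


def dfa_fluctuation(intervals: np.ndarray,
                    min_beats: int = MIN_BEATS) -> tuple[np.ndarray, np.ndarray]:
    """DFA-1 fluctuation function of an interval series (ms).

    The mean-centred series is integrated; for each log-spaced box size n
    (16 per decade, 4 <= n <= N/4) the profile is detrended by a linear
    fit in non-overlapping boxes and F(n) is the RMS residual.
    """
    x = np.asarray(intervals, dtype=float)
    if len(x) < min_beats:
        raise ValueError(
            f"at least {min_beats} beats are required, got {len(x)}")
    y = np.cumsum(x - x.mean())
    sizes = _box_sizes(len(x))
    F = np.empty(len(sizes))
    for k, n in enumerate(sizes):
        nb = len(y) // n
        seg = y[: nb * n].reshape(nb, n)
        t = np.arange(n, dtype=float)
        tm = t.mean()
        tc = t - tm
        denom = (tc * tc).sum()
        slope = seg @ tc / denom
        inter = seg.mean(axis=1)
        resid = seg - (inter[:, None] + slope[:, None] * tc[None, :])
        F[k] = np.sqrt(np.mean(resid ** 2))
    return sizes, F


def alpha_of_tau(n_beats: np.ndarray, F: np.ndarray, mu_ibi: float,
                 halfwidth: float = SLOPE_HALFWIDTH_DECADES
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Local slope of log10 F vs log10 n and the tau = n * mu_IBI mapping.

    The slope at each box size is a least-squares fit over the box sizes
    within +-``halfwidth`` decades.
    """
    ln = np.log10(np.asarray(n_beats, dtype=float))
    lf = np.log10(np.asarray(F, dtype=float))
    alpha = np.empty(len(ln))
    for i in range(len(ln)):
        sel = np.abs(ln - ln[i]) <= halfwidth + 1e-12
        xs, ys = ln[sel], lf[sel]
        if len(xs) < 2:
            alpha[i] = np.nan
            continue
        xc = xs - xs.mean()
        alpha[i] = float((xc @ ys) / (xc @ xc))
    tau = np.asarray(n_beats, dtype=float) * mu_ibi
    return tau, alpha


def alpha_bands(tau: np.ndarray, alpha_tau: np.ndarray) -> tuple[float, float]:
    """Averages of alpha(tau) over 5 <= tau <= 12 s and 12 < tau <= 360 s.

    A band containing no scales yields NaN.
    """
    tau = np.asarray(tau, dtype=float)
    a = np.asarray(alpha_tau, dtype=float)
    m1 = (tau >= ALPHA1_BAND[0]) & (tau <= ALPHA1_BAND[1])
    m2 = (tau > ALPHA2_BAND[0]) & (tau <= ALPHA2_BAND[1])
    a1 = float(np.nanmean(a[m1])) if m1.any() else float("nan")
    a2 = float(np.nanmean(a[m2])) if m2.any() else float("nan")
    return a1, a2


def dfa_curve(intervals: np.ndarray, mu_ibi: float | None = None,
              min_beats: int = MIN_BEATS) -> DFACurve:
    """Full multiscale DFA of an interval series in ms."""
    x = np.asarray(intervals, dtype=float)
    if mu_ibi is None:
        mu_ibi = float(x.mean()) / 1000.0
    n, F = dfa_fluctuation(x, min_beats=min_beats)
    tau, a = alpha_of_tau(n, F, mu_ibi)
    a1, a2 = alpha_bands(tau, a)
    return DFACurve(n_beats=n, F=F, tau=tau, alpha_tau=a,
                    alpha1=a1, alpha2=a2, mu_ibi=mu_ibi)


def global_slope(n_beats: np.ndarray, F: np.ndarray) -> float:
    """Single log-log slope of F(n) over all box sizes (least squares)."""
    ln = np.log10(np.asarray(n_beats, dtype=float))
    lf = np.log10(np.asarray(F, dtype=float))
    xc = ln - ln.mean()
    return float((xc @ lf) / (xc @ xc))
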