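"""Sample entropy and multiscale entropy (MSE) of interval series.

SampEn(m, r) = -ln(A/B) where B counts pairs of m-length templates within
Chebyshev distance r and A counts the same for length m + 1, self-matches
excluded.  MSE evaluates SampEn on coarse-grained (block-averaged) series
at increasing scale, holding r fixed at 15 % of the SD of the original
scale-1 series; scales are mapped to time via tau = scale * mu_IBI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pulsehrv.tachogram import Tachogram

#: Tolerance as a fraction of the scale-1 SD, fixed across scales.
R_FRACTION = 0.15
#: Minimum coarse-grained length for a scale to be usable.
MIN_COARSE_LEN = 100
#: Minimum number of beats for an MSE curve.
MIN_BEATS = 500
#: Longest temporal scale considered (s).
MAX_TAU_S = 333.0

#: Temporal-scale bands (s) mirroring the reciprocal HRV frequency bands:
#: HF 2.5 <= tau < 6.7 (1/0.4 .. ~1/0.15), LF 6.7 <= tau < 25, VLF 25 <= tau < 333.
MSE_HF_BAND = (2.5, 6.7)
MSE_LF_BAND = (6.7, 25.0)
MSE_VLF_BAND = (25.0, 333.0)

_CHUNK = 512


@dataclass
class MSECurve:
    m: int
    r: float
    scales: np.ndarray
    tau: np.ndarray
    mse: np.ndarray
    mu_ibi: float
    sampen1: float
    mse_hf: float
    mse_lf: float
    mse_vlf: float
    band_counts: dict = field(default_factory=dict)


def _pair_counts(emb: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Counts of template pairs within Chebyshev distance r.

    ``emb`` has shape (T, m+1); returns (A, B) for lengths m+1 and m,
    counting unordered pairs i < j.
    """
    T = emb.shape[0]
    A = 0
    B = 0
    for i0 in range(0, T - 1, _CHUNK):
        i1 = min(T - 1, i0 + _CHUNK)
        block = emb[i0:i1]          # (c, m+1)
        rest = emb[i0 + 1:]         # absolute j from i0 + 1
        within_m = np.ones((block.shape[0], rest.shape[0]), dtype=bool)
        for d in range(m):
            within_m &= np.abs(block[:, d, None] - rest[None, :, d]) <= r
        within_m1 = within_m & (np.abs(block[:, m, None] - rest[None, :, m]) <= r)
        rows = np.arange(i1 - i0)
        cols = np.arange(rest.shape[0])
        # pair (i, j) = (i0 + row, i0 + 1 + col); j > i requires col >= row
        upper = cols[None, :] >= rows[:, None]
        B += int((within_m & upper).sum())
        A += int((within_m1 & upper).sum())
    return A, B


def sample_entropy(x: np.ndarray, m: int = 1, r: float | None = None) -> float:
    """Sample entropy -ln(A/B) with Chebyshev template distance.

    ``r`` defaults to 15 % of the series SD.  Returns NaN (undefined) when
    either count is zero.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m + 2:
        raise ValueError("series too short for the requested embedding")
    if r is None:
        r = R_FRACTION * float(np.std(x, ddof=1))
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    T = len(x) - m
    emb = np.column_stack([x[i: i + T] for i in range(m + 1)])
    A, B = _pair_counts(emb, m, r)
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping block means of length ``scale``."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    x = np.asarray(x, dtype=float)
    nb = len(x) // scale
    return x[: nb * scale].reshape(nb, scale).mean(axis=1)


def mse_curve(t: Tachogram, m: int = 1) -> MSECurve:
    """Multiscale entropy of a cleaned tachogram.

    The tolerance r is fixed from the scale-1 SD; a scale is usable when
    the coarse-grained series keeps at least 100 points and its temporal
    scale tau = scale * mu_IBI does not exceed 333 s.  Band summaries
    average the usable scales inside each tau band (NaN when a band has
    none) and record how many scales contributed.
    """
    x = np.asarray(t.intervals, dtype=float)
    if len(x) < MIN_BEATS:
        raise ValueError(f"at least {MIN_BEATS} beats are required, got {len(x)}")
    mu = t.mu_ibi
    r = R_FRACTION * float(np.std(x, ddof=1))
    max_scale = min(len(x) // MIN_COARSE_LEN, int(np.floor(MAX_TAU_S / mu)))
    scales = np.arange(1, max(1, max_scale) + 1)
    mse = np.array([sample_entropy(coarse_grain(x, int(s)), m=m, r=r)
                    for s in scales])
    tau = scales * mu
    sampen1 = mse[0]

    def band_mean(band):
        sel = (tau >= band[0]) & (tau < band[1]) & np.isfinite(mse)
        return (float(np.mean(mse[sel])) if sel.any() else float("nan"),
                int(sel.sum()))

    hf, n_hf = band_mean(MSE_HF_BAND)
    lf, n_lf = band_mean(MSE_LF_BAND)
    vlf, n_vlf = band_mean(MSE_VLF_BAND)
    return MSECurve(m=m, r=r, scales=scales, tau=tau, mse=mse, mu_ibi=mu,
                    sampen1=float(sampen1), mse_hf=hf, mse_lf=lf, mse_vlf=vlf,
                    band_counts={"hf": n_hf, "lf": n_lf, "vlf": n_vlf})
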