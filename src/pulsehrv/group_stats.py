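"""Paired PPG-vs-ECG comparison statistics.

The Wilcoxon matched-pairs signed-rank test is used throughout: zero
differences are dropped (Wilcoxon's convention), ties receive midranks,
the two-sided p-value is exact (conditional on the observed ranks) for
n <= 25 and uses a tie-corrected normal approximation with continuity
correction above.  Ratio curves summarise per-subject PPG/RRI ratios on a
common grid with pointwise V statistics and exact significance
thresholds, mirroring the pointwise-comparison figures of paired HRV
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

EXACT_MAX_N = 25
BOOTSTRAP_B = 1000


def _exact_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the positive-rank sum given the rank values.

    Ranks may be half-integers (midranks); they are doubled to integers
    and the distribution of the doubled statistic is built by dynamic
    programming over all 2^n sign assignments.  Returns (support of the
    doubled statistic, probabilities).
    """
    w = np.round(2 * np.asarray(ranks, dtype=float)).astype(int)
    total = int(w.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for wi in w:
        nxt = dist.copy()
        nxt[wi:] += dist[: total + 1 - wi]
        dist = nxt
    dist /= dist.sum()
    return np.arange(total + 1), dist


def wilcoxon_paired(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test.

    Returns (V, p): V is the sum of ranks of positive differences x - y
    (midranks for ties, zero differences dropped); p is two-sided, exact
    for n <= 25.  When every difference is zero the test is undefined and
    (NaN, NaN) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return float("nan"), float("nan")
    ranks = sst.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        support, dist = _exact_distribution(ranks)
        v2 = int(round(2 * v))
        p_le = dist[: v2 + 1].sum()
        p_ge = dist[v2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts ** 3 - counts) / 48.0).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        # continuity correction toward the mean
        z = (v - mean - 0.5 * np.sign(v - mean)) / np.sqrt(var)
        p = float(2 * sst.norm.sf(abs(z)))
        p = min(1.0, p)
    return v, p


def pointwise_thresholds(n: int, levels: tuple[float, ...] = (0.05, 0.01)
                         ) -> dict[float, float]:
    """Smallest V whose exact two-sided tail probability is <= each level.

    Computed from the exact null distribution with untied ranks 1..n.
    When even the maximal statistic n(n+1)/2 is not significant (e.g.
    n = 5 at the 5 % level, where the smallest two-sided p is 1/16) the
    threshold is unattainable and reported as NaN.
    """
    if n < 5:
        raise ValueError("at least 5 subjects are required")
    for level in levels:
        if not 0 < level < 1:
            raise ValueError(f"level must lie in (0, 1), got {level}")
    support, dist = _exact_distribution(np.arange(1, n + 1))
    sf = np.cumsum(dist[::-1])[::-1]  # P(W2 >= k)
    reachable = dist > 0
    out: dict[float, float] = {}
    for level in levels:
        ok = (2.0 * sf <= level) & reachable
        if ok.any():
            out[level] = float(support[ok.argmax()]) / 2.0
        else:
            out[level] = float("nan")
    return out


@dataclass
class RatioCurve:
    """Pointwise paired ratio of a PPG-derived curve to the RRI curve."""

    grid: np.ndarray
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    V: np.ndarray
    thresholds: dict = field(default_factory=dict)
    n_subjects: int = 0


def ratio_curve(ppg: np.ndarray, rri: np.ndarray, grid: np.ndarray,
                levels: tuple[float, ...] = (0.05, 0.01)) -> RatioCurve:
    """Per-point PPG/RRI ratios across subjects with Wilcoxon V statistics.

    ``ppg`` and ``rri`` are (n_subjects, n_grid) arrays of paired curves
    on a common grid.  Points with a zero denominator in any subject are
    flagged missing (NaN).  V at each point tests PPG against RRI.
    """
    ppg = np.atleast_2d(np.asarray(ppg, dtype=float))
    rri = np.atleast_2d(np.asarray(rri, dtype=float))
    if ppg.shape != rri.shape:
        raise ValueError("paired curve arrays must have the same shape")
    n_subj, n_grid = ppg.shape
    if n_subj < 5:
        raise ValueError("at least 5 subjects are required")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rri != 0, ppg / rri, np.nan)
    med = np.nanmedian(ratio, axis=0)
    q1 = np.nanpercentile(ratio, 25, axis=0)
    q3 = np.nanpercentile(ratio, 75, axis=0)
    V = np.array([wilcoxon_paired(ppg[:, j], rri[:, j])[0] for j in range(n_grid)])
    thr = pointwise_thresholds(n_subj, levels)
    return RatioCurve(grid=np.asarray(grid, dtype=float), median=med,
                      q1=q1, q3=q3, V=V, thresholds=thr, n_subjects=n_subj)


def median_se(values: np.ndarray, seed: int = 0, B: int = BOOTSTRAP_B
              ) -> tuple[float, float]:
    """Median and its bootstrap standard error (B resamples, seeded)."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(B, len(v)))
    meds = np.median(v[idx], axis=1)
    return float(np.median(v)), float(meds.std(ddof=1))


def geometric_mean_se(values: np.ndarray) -> tuple[float, float]:
    """Geometric mean and geometric SE: exp of mean and SEM of the logs."""
    lv = np.log(np.asarray(values, dtype=float))
    return float(np.exp(lv.mean())), float(np.exp(lv.std(ddof=1) / np.sqrt(len(lv))))


def summarize_indexes(cohort: dict[str, dict[str, np.ndarray]],
                      reference: str = "RRI",
                      geometric: tuple[str, ...] = (),
                      seed: int = 0) -> pd.DataFrame:
    """Cohort summary table: median (SE median) per index and tachogram kind
    with paired Wilcoxon p-values against the reference column.

    ``cohort`` maps index name -> {tachogram kind -> per-subject values}.
    Indexes listed in ``geometric`` (typically band powers) additionally
    get geometric mean / geometric SE columns.
    """
    rows = []
    for index_name, by_kind in cohort.items():
        if reference not in by_kind:
            raise ValueError(f"reference kind {reference!r} missing for {index_name}")
        ref_vals = np.asarray(by_kind[reference], dtype=float)
        if len(ref_vals) < 3:
            raise ValueError("at least 3 subjects are required")
        for kind, vals in by_kind.items():
            vals = np.asarray(vals, dtype=float)
            med, se = median_se(vals, seed=seed)
            row = {"index": index_name, "kind": kind,
                   "median": med, "se_median": se}
            if index_name in geometric:
                gm, gse = geometric_mean_se(vals)
                row["geo_mean"] = gm
                row["geo_se"] = gse
            if kind != reference:
                _, p = wilcoxon_paired(vals, ref_vals)
                row["p_vs_ref"] = p
                row["stars"] = ("**" if p < 0.01 else "*" if p < 0.05 else "")
            else:
                row["p_vs_ref"] = np.nan
                row["stars"] = ""
            rows.append(row)
    return pd.DataFrame(rows)
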