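"""Readers and writers for the package's native text formats.

Raw signals are stored as two-column headerless CSV (time_s, value) with
a JSON sidecar holding the sampling rate, label and bit depth; all
derived products (fiducials, tachograms, spectra, DFA and MSE curves,
ratio curves, summary tables) are TSV with JSON sidecars for scalars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pulsehrv.beats import FiducialSeries
from pulsehrv.entropy import MSECurve
from pulsehrv.fractal import DFACurve
from pulsehrv.group_stats import RatioCurve
from pulsehrv.signals import RawSignal
from pulsehrv.spectral import BandPowers, Spectrum
from pulsehrv.tachogram import Tachogram


def write_raw_signal(sig: RawSignal, prefix: str | Path, bits: int | None = None) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    arr = np.column_stack([sig.times, sig.samples])
    np.savetxt(f"{prefix}.csv", arr, delimiter=",", fmt=["%.6f", "%.8g"])
    meta = {"fs": sig.fs, "label": sig.label, "units": sig.units}
    if bits is not None:
        meta["bits"] = bits
    Path(f"{prefix}.json").write_text(json.dumps(meta, indent=1))


def read_raw_signal(prefix: str | Path) -> RawSignal:
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.json").read_text())
    arr = np.loadtxt(f"{prefix}.csv", delimiter=",")
    return RawSignal(arr[:, 1], fs=meta["fs"], label=meta["label"],
                     units=meta.get("units", "a.u."))


def write_fiducials(fid: FiducialSeries, path: str | Path) -> None:
    df = pd.DataFrame({"index": np.arange(len(fid)), "time_s": fid.times,
                       "kind": fid.kind})
    df.to_csv(path, sep="\t", index=False)


def read_fiducials(path: str | Path, source_fs: float = 200.0) -> FiducialSeries:
    df = pd.read_csv(path, sep="\t")
    return FiducialSeries(kind=str(df["kind"].iloc[0]),
                          times=df["time_s"].to_numpy(), source_fs=source_fs)


def write_tachogram(t: Tachogram, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"anchor_time_s": t.anchor_times, "interval_ms": t.intervals,
                  "kind": t.kind}).to_csv(path, sep="\t", index=False)
    side = {"kind": t.kind, "mu_ibi_s": t.mu_ibi, "pct_removed": t.pct_removed,
            "quality_warning": t.quality_warning}
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def read_tachogram(path: str | Path) -> Tachogram:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    side = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
    return Tachogram(intervals=df["interval_ms"].to_numpy(),
                     anchor_times=df["anchor_time_s"].to_numpy(),
                     kind=str(df["kind"].iloc[0]),
                     pct_removed=side.get("pct_removed", 0.0),
                     quality_warning=side.get("quality_warning", False))


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"freq_hz": s.freqs, "psd_ms2_hz": s.psd}).to_csv(
        path, sep="\t", index=False)


def write_band_powers(bp: BandPowers, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"vlf_ms2": bp.vlf, "lf_ms2": bp.lf, "hf_ms2": bp.hf,
         "lf_hf": None if np.isnan(bp.lf_hf) else bp.lf_hf}, indent=1))


def write_dfa(curve: DFACurve, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"n": curve.n_beats, "F_ms": curve.F, "tau_s": curve.tau,
                  "alpha_tau": curve.alpha_tau}).to_csv(path, sep="\t", index=False)
    path.with_suffix(".json").write_text(json.dumps(
        {"alpha1": curve.alpha1, "alpha2": curve.alpha2,
         "mu_ibi_s": curve.mu_ibi}, indent=1))


def write_mse(curve: MSECurve, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"scale": curve.scales, "tau_s": curve.tau,
                  "sampen": curve.mse}).to_csv(path, sep="\t", index=False)

    def _clean(v):
        return None if (isinstance(v, float) and np.isnan(v)) else v

    path.with_suffix(".json").write_text(json.dumps(
        {"m": curve.m, "r_ms": curve.r, "sampen1": _clean(curve.sampen1),
         "mse_hf": _clean(curve.mse_hf), "mse_lf": _clean(curve.mse_lf),
         "mse_vlf": _clean(curve.mse_vlf),
         "band_counts": curve.band_counts}, indent=1))


def write_ratio_curve(rc: RatioCurve, path: str | Path) -> None:
    thr5 = rc.thresholds.get(0.05, float("nan"))
    thr1 = rc.thresholds.get(0.01, float("nan"))
    pd.DataFrame({"grid": rc.grid, "median": rc.median, "q1": rc.q1,
                  "q3": rc.q3, "V": rc.V,
                  "thr5": np.full(len(rc.grid), thr5),
                  "thr1": np.full(len(rc.grid), thr1)}).to_csv(
        path, sep="\t", index=False)
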