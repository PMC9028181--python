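"""End-to-end analysis pipeline: simulate or load recordings, extract the
five tachograms, run spectral / DFA / MSE analysis, and aggregate cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pulsehrv import __version__
from pulsehrv.beats import detect_ppg_fiducials, detect_r_peaks
from pulsehrv.entropy import MSECurve, mse_curve
from pulsehrv.fractal import DFACurve, dfa_curve
from pulsehrv.group_stats import summarize_indexes, wilcoxon_paired
from pulsehrv.preprocess import resample_linear
from pulsehrv.signals import RawSignal
from pulsehrv.spectral import BandPowers, band_powers, broadband_smooth, welch_psd
from pulsehrv.synth import BeatTimes, SimConfig, simulate_beat_times, simulate_ecg, simulate_ppg
from pulsehrv.tachogram import Tachogram, build_tachogram, clean_tachogram, resample_even

logger = logging.getLogger("pulsehrv")

PPG_KIND_TO_FIDUCIAL = {
    "DDI": "DDI_point",
    "SSI": "SSI_point",
    "dP1": "dP1_point",
    "dP2": "dP2_point",
}

#: Detection runs at the ECG rate; PPG is resampled up to match.
ANALYSIS_FS = 200.0


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    kinds: tuple[str, ...] = ("RRI", "DDI", "SSI", "dP1", "dP2")
    do_spectral: bool = True
    do_dfa: bool = True
    do_mse: bool = True
    m_values: tuple[int, ...] = (1,)
    out_dir: str | None = None
    seed: int = 0


@dataclass
class SubjectResult:
    """All per-subject analysis products, keyed by tachogram kind."""

    tachograms: dict[str, Tachogram]
    spectra: dict[str, object] = field(default_factory=dict)
    bands: dict[str, BandPowers] = field(default_factory=dict)
    dfa: dict[str, DFACurve] = field(default_factory=dict)
    mse: dict[str, MSECurve] = field(default_factory=dict)

    def index_value(self, index: str, kind: str) -> float:
        """Scalar HRV index by name: vlf/lf/hf/lf_hf, alpha1/alpha2,
        sampen/mse_hf/mse_lf/mse_vlf."""
        if index in ("vlf", "lf", "hf", "lf_hf"):
            return getattr(self.bands[kind], index)
        if index in ("alpha1", "alpha2"):
            return getattr(self.dfa[kind], index)
        if index in ("sampen", "mse_hf", "mse_lf", "mse_vlf"):
            attr = "sampen1" if index == "sampen" else index
            return getattr(self.mse[kind], attr)
        raise KeyError(index)


def extract_tachograms(ecg: RawSignal, tl: RawSignal,
                       kinds: tuple[str, ...] = ("RRI", "DDI", "SSI", "dP1", "dP2"),
                       ) -> dict[str, Tachogram]:
    """Detect fiducials and build cleaned tachograms from a two-channel
    recording.  The PPG (TL) channel is resampled to 200 Hz first."""
    out: dict[str, Tachogram] = {}
    tl200 = resample_linear(tl, ANALYSIS_FS) if tl.fs != ANALYSIS_FS else tl
    for kind in kinds:
        t0 = time.perf_counter()
        if kind == "RRI":
            fid = detect_r_peaks(ecg)
        else:
            fid = detect_ppg_fiducials(tl200, PPG_KIND_TO_FIDUCIAL[kind])
        tach = clean_tachogram(build_tachogram(fid))
        logger.info("%s: %d beats, %.1f%% removed (%.2f s)", kind, len(tach),
                    tach.pct_removed, time.perf_counter() - t0)
        out[kind] = tach
    return out


def analyze_tachogram(tach: Tachogram, cfg: PipelineConfig) -> dict:
    """Spectral, self-similarity and entropy analysis of one tachogram."""
    res: dict = {}
    if cfg.do_spectral:
        u = resample_even(tach)
        spec = broadband_smooth(welch_psd(u))
        res["spectrum"] = spec
        res["bands"] = band_powers(spec)
    if cfg.do_dfa:
        res["dfa"] = dfa_curve(tach.intervals, mu_ibi=tach.mu_ibi)
    if cfg.do_mse:
        res["mse"] = {m: mse_curve(tach, m=m) for m in cfg.m_values}
    return res


def run_subject(cfg: PipelineConfig) -> SubjectResult:
    """Simulate one subject and run the full analysis chain."""
    beats = simulate_beat_times(cfg.sim)
    ecg = simulate_ecg(beats, fs=cfg.sim.ecg_fs)
    tl = simulate_ppg(beats, cfg.sim)
    tachs = extract_tachograms(ecg, tl, cfg.kinds)
    result = SubjectResult(tachograms=tachs)
    for kind, tach in tachs.items():
        res = analyze_tachogram(tach, cfg)
        if "spectrum" in res:
            result.spectra[kind] = res["spectrum"]
            result.bands[kind] = res["bands"]
        if "dfa" in res:
            result.dfa[kind] = res["dfa"]
        if "mse" in res:
            result.mse[kind] = res["mse"][cfg.m_values[0]]
    return result


def make_cohort_configs(n_subjects: int, seed: int,
                        base: SimConfig | None = None,
                        pat_amp_range: tuple[float, float] = (0.005, 0.015),
                        ) -> list[PipelineConfig]:
    """Seeded per-subject configurations for a simulated cohort.

    PAT modulation amplitudes are spread evenly over ``pat_amp_range``
    (5-15 ms by default, respiratory frequency), one amplitude per
    subject; each subject gets an independent sub-seed.
    """
    base = base or SimConfig()
    amps = np.linspace(*pat_amp_range, n_subjects)
    cfgs = []
    for i in range(n_subjects):
        sim = dataclasses.replace(base, seed=(seed * 10007 + i) % (2 ** 31),
                                  pat_amp=float(amps[i]))
        cfgs.append(PipelineConfig(sim=sim, seed=seed))
    return cfgs


COHORT_INDEXES = ("vlf", "lf", "hf", "lf_hf", "alpha1", "alpha2",
                  "sampen", "mse_hf", "mse_lf", "mse_vlf")


def run_cohort(configs: list[PipelineConfig],
               indexes: tuple[str, ...] = COHORT_INDEXES) -> dict:
    """Run every subject and aggregate the paired cohort comparison.

    Returns a dict with per-subject results, the cohort index table
    (index -> kind -> per-subject values), the summary DataFrame, and the
    median SSI/RRI ratios of each index.
    """
    subjects = []
    for i, cfg in enumerate(configs):
        t0 = time.perf_counter()
        subjects.append(run_subject(cfg))
        logger.info("subject %d/%d analysed in %.1f s", i + 1, len(configs),
                    time.perf_counter() - t0)
    kinds = configs[0].kinds
    cohort: dict[str, dict[str, np.ndarray]] = {}
    for index in indexes:
        cohort[index] = {
            kind: np.array([s.index_value(index, kind) for s in subjects])
            for kind in kinds
        }
    summary = summarize_indexes(
        cohort, reference="RRI", geometric=("vlf", "lf", "hf"),
        seed=configs[0].seed)
    ratios = {}
    for index in indexes:
        for kind in kinds:
            if kind == "RRI":
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                r = cohort[index][kind] / cohort[index]["RRI"]
            ratios[(index, kind)] = float(np.nanmedian(r))
    return {"subjects": subjects, "cohort": cohort, "summary": summary,
            "median_ratios": ratios}


def write_manifest(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Record package version, seed and all parameters needed to reproduce
    every output file of a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "pulsehrv",
        "version": __version__,
        "seed": cfg.seed,
        "sim": dataclasses.asdict(cfg.sim),
        "kinds": list(cfg.kinds),
        "analyses": {"spectral": cfg.do_spectral, "dfa": cfg.do_dfa,
                     "mse": cfg.do_mse, "m_values": list(cfg.m_values)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
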