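import warnings

import numpy as np
import pytest

from pulsehrv.preprocess import resample_linear
from pulsehrv.synth import SimConfig, simulate_beat_times, simulate_ecg, simulate_ppg


@pytest.fixture(scope="session")
def sim_recording():
    """One ~310 s simulated recording with default modulation and no PAT
    modulation: beats, ECG at 200 Hz, and the PPG TL channel resampled to
    200 Hz.  Shared across detection and round-trip tests."""
    cfg = SimConfig(duration=310.0, pat_amp=0.0, seed=4)
    beats = simulate_beat_times(cfg)
    ecg = simulate_ecg(beats, fs=cfg.ecg_fs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tl = simulate_ppg(beats, cfg)
    tl200 = resample_linear(tl, 200.0)
    return {"cfg": cfg, "beats": beats, "ecg": ecg, "tl": tl, "tl200": tl200}


@pytest.fixture(scope="session")
def sim_recording_pat():
    """Same conditions but with 10 ms respiratory PAT modulation."""
    cfg = SimConfig(duration=900.0, pat_amp=0.010, seed=11)
    beats = simulate_beat_times(cfg)
    ecg = simulate_ecg(beats, fs=cfg.ecg_fs)
    tl = simulate_ppg(beats, cfg)
    tl200 = resample_linear(tl, 200.0)
    return {"cfg": cfg, "beats": beats, "ecg": ecg, "tl": tl, "tl200": tl200}


def match_intervals(detected_ms: np.ndarray, true_ms: np.ndarray) -> np.ndarray:
    """Errors between a detected interval series and the ground-truth one,
    allowing the detected series to start up to two beats later (edge
    effects may drop the first/last event of a series)."""
    best = None
    for off in range(3):
        if off + len(detected_ms) > len(true_ms):
            continue
        err = detected_ms - true_ms[off: off + len(detected_ms)]
        if best is None or np.abs(err).max() < np.abs(best).max():
            best = err
    assert best is not None, "detected series longer than truth"
    return best
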