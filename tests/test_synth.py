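"""Ground-truth properties of the IPFM beat generator and waveform synthesis."""

import numpy as np
import pytest
from scipy.signal import periodogram

from pulsehrv.signals import RawSignal
from pulsehrv.synth import (
    BeatTimes,
    SimConfig,
    one_over_f_noise,
    pulse_template,
    quantize,
    simulate_beat_times,
    simulate_ecg,
    simulate_ppg,
)


def _plain_cfg(**kw):
    base = dict(duration=10.0, t0=1.0, amp_lf=0.0, amp_hf=0.0,
                one_over_f_level=0.0, pat_amp=0.0, seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestIPFM:
    def test_constant_rate_beats_at_integer_multiples(self):
        beats = simulate_beat_times(_plain_cfg())
        np.testing.assert_allclose(beats.times, np.arange(1, 11), atol=1e-6)

    def test_beat_count_equals_floor_of_integral(self):
        # with rate 1/T0 and duration D the integral is exactly D/T0
        beats = simulate_beat_times(_plain_cfg(duration=12.7, t0=0.8))
        assert len(beats) == int(np.floor(12.7 / 0.8))

    def test_hf_modulation_appears_at_its_frequency(self):
        cfg = _plain_cfg(duration=600.0, amp_hf=0.05, f_hf=0.25)
        beats = simulate_beat_times(cfg)
        iv = np.diff(beats.times)
        f, p = periodogram(iv - iv.mean(), fs=1.0 / iv.mean())
        assert abs(f[np.argmax(p)] - 0.25) <= 0.01

    def test_long_run_mean_interval_matches_t0(self):
        cfg = SimConfig(duration=3600.0, t0=1.0, seed=2)
        beats = simulate_beat_times(cfg)
        assert abs(np.diff(beats.times).mean() - 1.0) < 0.01

    def test_excessive_modulation_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            simulate_beat_times(_plain_cfg(amp_lf=0.6, amp_hf=0.5))

    def test_seed_reproducibility(self):
        cfg = SimConfig(duration=120.0, seed=7)
        a = simulate_beat_times(cfg).times
        b = simulate_beat_times(SimConfig(duration=120.0, seed=7)).times
        np.testing.assert_array_equal(a, b)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"duration": 0.0}, {"t0": 0.2}, {"t0": 2.5}, {"amp_lf": -0.1},
        {"pat0": -0.1}, {"ppg_bits": 3}, {"ppg_bits": 17},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_beat_times_must_be_physiological(self):
        with pytest.raises(ValueError):
            BeatTimes(np.array([0.0, 0.1]))   # 100 ms interval
        with pytest.raises(ValueError):
            BeatTimes(np.array([0.0, 3.0]))   # 3 s interval


class TestECG:
    def test_single_beat_peak_at_beat_time(self):
        beats = BeatTimes(np.array([4.0, 5.0]))
        ecg = simulate_ecg(beats, fs=200.0, duration=7.0)
        t_max = np.argmax(ecg.samples) / 200.0
        assert abs(t_max - 4.0) <= 0.5 / 200.0 or abs(t_max - 5.0) <= 0.5 / 200.0

    def test_unit_r_amplitude(self):
        beats = BeatTimes(np.array([2.0, 3.0, 4.0]))
        ecg = simulate_ecg(beats, fs=200.0)
        assert ecg.samples.max() == pytest.approx(1.0, abs=0.02)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_ecg(BeatTimes(np.array([1.0, 2.0])), fs=50.0)


class TestPPG:
    def test_quantization_error_at_most_half_step(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        for bits in (4, 8, 12):
            q = quantize(x, bits)
            step = (x.max() - x.min()) / (2 ** bits - 1)
            assert np.abs(q - x).max() <= step / 2 + 1e-12

    def test_template_is_causal_and_bounded_support(self):
        u = np.linspace(-0.5, 2.0, 2000)
        p = pulse_template(u, t0=1.0)
        assert (p[u <= 0] == 0).all()
        assert (p[u >= 0.75] == 0).all()
        assert p.max() > 0

    def test_pat_sine_injects_predicted_interval_variance(self):
        # constant IBI 1 s; first-differencing a sinusoid sampled at beat
        # times gives variance 2 * (pat_amp * sin(pi * f * IBI))^2
        from pulsehrv.beats import detect_ppg_fiducials
        from pulsehrv.preprocess import resample_linear
        cfg = _plain_cfg(duration=600.0, pat_amp=0.010, pat_freq=0.25, seed=5)
        beats = simulate_beat_times(cfg)
        tl = simulate_ppg(beats, cfg)
        fid = detect_ppg_fiducials(resample_linear(tl, 200.0), "SSI_point")
        iv = np.diff(fid.times) * 1000.0
        predicted = 2.0 * (10.0 * np.sin(np.pi * 0.25 * 1.0)) ** 2
        assert np.var(iv) == pytest.approx(predicted, rel=0.15)

    def test_overlap_warning_when_template_exceeds_min_ibi(self):
        beats = BeatTimes(np.array([1.0, 1.5, 2.0, 2.5]))
        with pytest.warns(RuntimeWarning, match="overlap"):
            simulate_ppg(beats, _plain_cfg(t0=1.0))

    def test_one_diastolic_maximum_per_gap(self):
        # continuous (unquantized) TL: between consecutive systolic peaks the
        # signal has a single maximal stretch (the diastolic maximum)
        cfg = _plain_cfg(duration=30.0)
        beats = simulate_beat_times(cfg)
        tl = simulate_ppg(beats, cfg, do_quantize=False).samples
        peaks = [np.argmin(tl[int((t + 0.1) * 75):int((t + 0.5) * 75)])
                 + int((t + 0.1) * 75) for t in beats.times[:-1]]
        for a, b in zip(peaks[:-1], peaks[1:]):
            seg = tl[a:b]
            runs = np.flatnonzero(np.diff((seg == seg.max()).astype(int)) == 1)
            assert len(runs) <= 1  # a single maximal run strictly inside


class TestOneOverF:
    def test_unit_sd_and_band_limits(self):
        rng = np.random.default_rng(1)
        x = one_over_f_noise(600_000, 1e-3, rng)
        assert x.std() == pytest.approx(1.0, rel=1e-6)
        f, p = periodogram(x, fs=1000.0)
        assert p[f > 0.5].sum() < 1e-6 * p.sum()

    def test_spectral_slope_near_one_over_f(self):
        rng = np.random.default_rng(2)
        x = one_over_f_noise(2_000_000, 1e-3, rng)
        f, p = periodogram(x, fs=1000.0)
        sel = (f >= 0.005) & (f <= 0.3)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.35)
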