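# pulsehrv

Pulse-rate variability vs heart-rate variability during sleep: a complete
analysis chain for comparing beat-to-beat interval series derived from a
finger photoplethysmogram (PPG) against the ECG R–R reference, together
with a synthetic signal generator that reproduces the pulse-arrival-time
mechanism behind their discrepancies.

Wearable PPG devices are increasingly used to estimate heart rate
variability (HRV) during sleep, where autonomic indexes matter most for
breathing disorders.  But a PPG tachogram is not an R–R tachogram: the
pulse arrives at the finger after a pulse arrival time (PAT) that is
itself modulated — notably by respiration, through pulse wave velocity —
so PPG-derived series carry extra variability concentrated at respiratory
frequencies.  `pulsehrv` implements the full comparison pipeline and a
generative model to study that mechanism quantitatively:

- **Synthesis** (`pulsehrv.synth`): integral pulse frequency modulation
  (IPFM) beat generator with LF/HF sinusoidal and 1/f rate modulation;
  ECG waveform with sharp R waves; PPG transmitted-light waveform whose
  pulse arrivals are the beat times plus a configurable, sinusoidally
  modulated PAT; 75 Hz sampling, 8-bit quantization.
- **Detection** (`pulsehrv.beats`, `pulsehrv.preprocess`): derivative-and-
  threshold detectors with parabolic sub-sample refinement for the five
  fiducial series — R peaks and the four PPG landmarks (DDI: diastolic
  transmitted-light maxima; SSI: systolic absorbed-light maxima; dP1/dP2:
  maxima of the first/second absorbed-light derivative).
- **Tachograms** (`pulsehrv.tachogram`): interval series in ms, automated
  artifact cleaning with removal accounting, uniform 5 Hz resampling.
- **Analysis** (`pulsehrv.spectral`, `pulsehrv.fractal`,
  `pulsehrv.entropy`): Welch spectra (300 s Hann, 90 % overlap) with
  constant-relative-bandwidth smoothing and VLF/LF/HF band powers;
  multiscale DFA with the τ = n·μ_IBI mapping and α₁/α₂ over temporal
  scale bands; sample entropy (m = 1 or 2, r = 0.15·SD fixed across
  scales) and multiscale entropy with MSE_HF/LF/VLF summaries.
- **Statistics** (`pulsehrv.group_stats`): exact paired Wilcoxon
  signed-rank tests (midranks, zeros dropped), pointwise V statistics
  with exact significance thresholds, ratio curves, cohort summary
  tables (median, bootstrap SE of the median, geometric mean/SE).

## Worked example

Simulate one 15-minute subject with 10 ms respiratory PAT modulation at
0.25 Hz and compare the SSI tachogram with the R–R reference:

```python
from pulsehrv.pipeline import PipelineConfig, run_subject
from pulsehrv.synth import SimConfig

cfg = PipelineConfig(sim=SimConfig(duration=900.0, pat_amp=0.010, seed=42),
                     kinds=("RRI", "SSI"))
res = run_subject(cfg)
for kind in ("RRI", "SSI"):
    bp, d, ms = res.bands[kind], res.dfa[kind], res.mse[kind]
    print(f"{kind}:  HF {bp.hf:7.1f} ms^2   LF/HF {bp.lf_hf:5.2f}   "
          f"alpha1 {d.alpha1:5.3f}   SampEn {ms.sampen1:5.3f}")
```

prints

```
RRI:  HF   527.4 ms^2   LF/HF  3.55   alpha1 1.026   SampEn 2.102
SSI:  HF   587.6 ms^2   LF/HF  3.19   alpha1 1.000   SampEn 2.123
```

The four signed discrepancies are the mechanism's fingerprint: PAT
modulation at the respiratory frequency inflates the HF power of the
PPG tachogram (527 → 588 ms²), which lowers LF/HF (3.55 → 3.19), drags
the short-term self-similarity coefficient α₁ toward less correlated
behaviour (1.026 → 1.000), and raises sample entropy (2.102 → 2.123) —
while the ECG reference is untouched.  On a seeded 12-subject cohort the
same four signs hold for the median SSI/RRI ratios (see
`tests/test_acceptance.py`).

The same pipeline runs from the shell:

```sh
pulsehrv simulate --config cfg.json --out rec/      # two-channel recording
pulsehrv detect   --rec rec/ --out tachs/           # five tachograms
pulsehrv analyze  --tachograms tachs/ --out idx/    # spectra, DFA, MSE
pulsehrv cohort   --subjects 12 --seed 1 --out coh/ # paired cohort tables
pulsehrv report   --cohort-dir coh/
```

All outputs are TSV/JSON; every run writes a manifest with the seed and
all parameters needed to reproduce it.

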