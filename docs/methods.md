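# Methods

`pulsehrv` studies a methodological question of sleep heart-rate-variability
(HRV) monitoring: when the beat-to-beat interval series is derived from a
finger photoplethysmogram (PPG) instead of the ECG, how do the standard HRV
indexes — band powers, multiscale self-similarity, multiscale entropy —
deviate from the R-R reference, and can the deviations be explained by
modulation of the pulse arrival time (PAT)?  Since suitable clinical
recordings are access-restricted in general, the package pairs the full
analysis chain with a generative model that reproduces the mechanism with
known ground truth.

## Signal model

**Beat times.**  An integral pulse frequency modulation (IPFM) model emits
beat k when the running integral of the instantaneous rate
(1 + s(t)) / T0 first reaches k.  The modulation

s(t) = a_LF sin(2π f_LF t) + a_HF sin(2π f_HF t) + c · b(t)

combines a low-frequency (default a_LF = 0.05 at 0.10 Hz) and a
respiratory high-frequency sinusoid (a_HF = 0.03 at 0.25 Hz) with a
band-limited 1/f background b(t) (unit SD, shaped over 0.003–0.4 Hz,
c = 0.05).  With T0 = 1 s these defaults give an interval SD of roughly
40–60 ms and LF/HF near 3–4 — representative of adult non-REM sleep.  The
integral is evaluated by the trapezoidal rule on a 1 ms grid with linear
interpolation of the threshold crossing; the resulting timing error is far
below one ECG sample period (5 ms).  Modulations with |s| ≥ 1 are rejected
since the rate would become non-positive.

**ECG.**  Each beat contributes an identical template: a unit-amplitude
Gaussian R spike (σ = 4 ms, total width ≈ 20 ms) and a smooth T hump
(amplitude 0.15, 260 ms later).  This is deliberately minimal: the R-peak
detector only needs a sharp dominant deflection.

**PPG.**  The absorbed-light waveform is AL(t) = Σ_k P(t − t_k − PAT(t_k))
with PAT(t) = pat0 + pat_amp · sin(2π f_pat t) (defaults pat0 = 250 ms,
pat_amp = 10 ms, f_pat = 0.25 Hz).  The pulse template P is the sum of two
log-normal bumps — systolic peak and dicrotic wave — with a raised-cosine
taper ending at 0.75 · T0 so pulses normally do not overlap (an overlap
produces a warning, not an error).  The shape parameters are fixed named
constants and are a synthetic stand-in: real pulse morphology (and its
dependence on vascular tone or altitude) is not modelled.  The recorded
channel is transmitted light TL = baseline − AL, sampled at 75 Hz and
uniformly quantized to 8 bits (4–16 supported), emulating a wearable
acquisition front end.

Because the PAT term enters every PPG tachogram as a first difference
PAT(t_{k+1}) − PAT(t_k) ≈ IBI · dPAT/dt, it is in phase quadrature with
the intrinsic respiratory interval modulation at the same frequency, so
the injected HF power *adds* to the intrinsic HF power regardless of
phase.  A sinusoid of amplitude pat_amp sampled at beats of constant
interval I produces interval variance 2·(pat_amp · sin(π f_pat I))², which
the tests verify end-to-end through waveform synthesis and detection.

What the generator does **not** emulate: motion artifacts, ectopic beats,
baseline wander, sensor noise beyond quantization, pulse-shape variability
and amplitude modulation.  Passing tests therefore demonstrate
correctness of the analysis chain and of the PAT mechanism's direction,
not detector robustness on ambulatory recordings.

## Fiducial detection

Both detectors are derivative-and-threshold schemes.  The detection
function (squared first derivative for the ECG; squared positive upstroke
velocity of the filtered absorbed light for the PPG) is compared with an
adaptive threshold equal to 0.4 × the recent peak envelope, computed as
the windowed maximum of 1 s block maxima over ±2 s.  An envelope tracker
is used rather than a running quantile because an R spike occupies well
under 2 % of any window, putting even a 98th percentile far below the
event peaks and making it collapse wherever beats are sparse.  A 0.3 s
refractory period (200 bpm ceiling, physiological during sleep)
suppresses double detections, keep-first.  Within each suprathreshold
region the ECG landmark is the sample of maximal absolute deviation from
the local median — invariant to polarity inversion and amplitude scaling.

Per PPG beat, four landmarks are located: maximum of the first AL
derivative on the upstroke (dP1), systolic AL maximum (SSI), maximum of
the second derivative in [foot − 100 ms, AL peak] (dP2, restricted to the
upstroke to avoid dicrotic derivative maxima), and the late-diastolic TL
maximum between consecutive pulse feet (DDI).  The foot and the DDI point
are located with a 1 % amplitude tolerance (last near-minimum sample
before the upstroke, last near-maximum sample before the next onset):
along the slowly-varying diastolic stretch the strict extremum is decided
by quantization dither, whereas the tolerance-based landmark is pinned
against the steep pulse onset and stable to within a couple of samples.
All fiducials are refined to sub-sample precision by parabolic
interpolation through the three samples around the discrete extremum
(offset clipped to ±half a sample; flat triples yield zero offset).

PPG signals are resampled to 200 Hz by linear interpolation before
detection, and derivatives are taken only after a fourth-order zero-phase
Butterworth low-pass at 25 Hz (forward–backward `filtfilt` with
reflect padding; the effective magnitude response is the squared one-pass
response).  Derivatives use central differences (exact for quadratics),
one-sided at the ends.

## Tachograms

Intervals are in ms, anchored at the later fiducial.  Cleaning removes
intervals outside [300, 2000] ms or deviating more than 30 % from the
median of their five nearest neighbours — conventional automated HRV
artifact criteria standing in for visual editing; the rule is iterated to
a fixed point so cleaning is exactly idempotent.  The removed duration is
tracked as a percentage of the original segment; above 20 % a quality
warning is raised.  Gaps left by removal are interpolated across (with a
warning for gaps > 5 s) rather than concatenated, keeping the time axis
physical.  For spectral analysis the (anchor, interval) pairs are
linearly interpolated onto a uniform 5 Hz grid.  Linear interpolation of
a beat-anchored series acts as a triangular smoothing kernel, so
components near the respiratory frequency are attenuated more than LF
components; this affects RRI and PPG tachograms identically and cancels
in paired comparisons.

## Spectra, self-similarity, entropy

**Welch spectra** use 300 s Hann windows with 90 % overlap and per-window
linear detrending; the one-sided density (ms²/Hz, grid step 1/300 Hz) is
normalised so its integral equals the windowed-signal variance.  Spectra
are broadband-smoothed with a centred moving average whose half-width
grows with frequency, h(f) = max(1, round(0.1 f/Δf)) bins (≈10 % constant
relative bandwidth, truncated at the edges).  Band powers integrate the
smoothed density by the trapezoidal rule with interpolated band edges:
VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz; LF/HF is reported as
missing when HF = 0.

**DFA.**  Classic DFA-1 (integrate the mean-centred series, linear
detrend in non-overlapping boxes, RMS residual) over log-spaced box
sizes, 16 per decade, 4 ≤ n ≤ N/4.  Local slopes of log F vs log n are
fitted by least squares in sliding windows of ±0.3 decades, then mapped
to temporal scales via τ = n · μ_IBI.  The short- and long-term
coefficients α₁ and α₂ average α(τ) over 5 ≤ τ ≤ 12 s and
12 < τ ≤ 360 s (endpoints exactly as defined).  At least 500 beats are
required.  The vectorised implementation is tested for exact agreement
with a per-box `polyfit` oracle, and against analytic anchors: slope 0.5
for white noise, 1.5 for Brownian motion, ≈1 for 1/f noise.

**Entropy.**  SampEn(m, r) = −ln(A/B) with Chebyshev template distance,
self-matches excluded, undefined (NaN) when either count is zero;
computed by chunked vectorised pair counting and verified against both a
brute-force O(N²) loop and the closed form for iid Gaussian data,
−ln(2Φ(r/σ√2) − 1).  The multiscale curve coarse-grains by
non-overlapping block means with the tolerance fixed at 15 % of the
scale-1 SD (never recomputed per scale).  A scale is usable when the
coarse-grained series keeps ≥ 100 points and τ = scale · μ_IBI ≤ 333 s;
band summaries MSE_HF/LF/VLF average usable scales over τ ∈ [2.5, 6.7),
[6.7, 25) and [25, 333) s — the reciprocals of the spectral bands — and
record how many scales contributed, since on recordings shorter than a
few hours the VLF band is often empty.  m = 1 is the default; m = 2 is
supported.

## Paired statistics

The Wilcoxon matched-pairs signed-rank test drops zero differences
(Wilcoxon's convention) and assigns midranks to ties; V is the
positive-rank sum.  The two-sided p-value is exact for n ≤ 25, computed
by dynamic programming over the rank values (midranks are doubled to
integers first), and uses a tie-corrected normal approximation with
continuity correction above.  Pointwise significance thresholds are the
smallest V whose exact two-sided tail probability reaches the level,
restricted to attainable values of the statistic; at n = 5 the 5 % level
is unattainable (minimum two-sided p = 1/16) and reported as NaN.  Ratio
curves summarise per-subject PPG/RRI ratios on a shared grid (identical
by construction) with median, quartiles and pointwise V; no
multiple-comparison control is applied across grid points — a documented
limitation of pointwise testing.  Cohort tables report median and a
seeded-bootstrap (B = 1000) standard error of the median, plus geometric
mean and geometric SE for band powers.

## Problem sizes and numerical choices

Simulated subjects default to 900 s (≈900 beats): enough for three Welch
windows, for α₁ (τ ≤ 12 s) and for stable SampEn, while keeping a
12-subject cohort analysis under a minute.  α₂ and MSE_VLF need longer
series (360 s box scales need ≥ 1440 beats at 4 boxes minimum); the
analysis computes them when reachable and reports NaN otherwise.  All
randomness flows from a mandatory integer seed through
`numpy.random.default_rng`; reruns are bit-identical.  Degenerate inputs
(flat signals, empty tachograms, all-zero differences) raise or return
NaN as documented per function rather than propagating garbage.

## Known limitations

- The pulse template is a stand-in; detector parameters are declared, not
  fitted to any device.
- The automated cleaning rule replaces human editing; both thresholds are
  exposed as module constants.
- PAT modulation is a single sinusoid; real respiratory modulation has
  bandwidth and amplitude variability.
- The 1 % tolerance landmarks for foot/DDI assume a monotone diastolic
  decay, true for the template and for artifact-free PPG, not for signals
  with strong baseline wander.
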