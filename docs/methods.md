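# Methods

## Problem and scope

During atrial fibrillation (AF), the surface ECG shows fibrillatory
(f-) waves in place of P-waves. Their organization carries prognostic
information: patients whose f-waves are faster and more disorganized
before electrical cardioversion are more likely to relapse to AF within
weeks of a successful shock. `afmse` implements the full single-lead
analysis chain that turns a 90 s pre-shock ECG segment into a set of
scalar predictors of that early relapse — classic indices (f-wave
amplitude FWA, normalized amplitude nFWA, dominant frequency DF, Sample
Entropy SE of the f-wave fundamental) and multiscale entropy profiles
(MSE, CMSE, RMSE) summarized by scale-region areas and slopes — plus the
cohort-level statistics (normality-routed group tests, ROC/AROC, Youden
operating point) used to rank them. Because no public recording set
accompanies this analysis, the package includes a first-class synthetic
cohort generator that reproduces the statistical structure the chain
assumes.

## Preprocessing

The denoising chain is linear and zero-phase throughout (each IIR filter
is applied forward and backward, so magnitude responses act squared and
phase is untouched):

1. baseline wander estimated by a 3rd-order Butterworth low-pass at
   0.8 Hz and subtracted;
2. powerline interference removed by a notch at 50 Hz (configurable to
   60 Hz) with a 4 Hz bandwidth, realized as a 2nd-order IIR notch
   (Q = 12.5) — the minimal design meeting the center/bandwidth spec;
3. high-frequency noise removed by a low-pass at 70 Hz, realized as a
   4th-order Butterworth (the order is an implementation choice,
   consistent with the other Butterworth stages).

All filters run as second-order sections for numerical stability, with
reflect padding of roughly three times the slowest filter time constant
to suppress startup transients. Poles are checked against the unit
circle at design time. The chain is linear, length-preserving and
idempotent to within 2% RMS for signals band-limited to 3–25 Hz.

## f-wave extraction

R-peaks are detected by band-passing to 5–30 Hz, squaring, integrating
over 120 ms and peak-picking with a 200 ms refractory period; each
candidate is refined to the local absolute-amplitude maximum of the
ECG. The 5 Hz lower edge (rather than the more common 8–10 Hz) keeps
widened ectopic complexes detectable; the squared envelope still dwarfs
the much smaller f-waves. Any detector meeting the accuracy contracts
(±10 ms on clean records, ≥ 99% sensitivity at 0.05 mV broadband noise)
would be acceptable here.

Beats are labeled ectopic when the zero-lag normalized correlation of
their windowed complex with a pointwise-median beat template falls below
0.9 (configurable). The median template is robust to the ectopics it is
meant to find; a running-template variant would behave equivalently at
these ectopic rates.

QRST cancellation uses a window of min(470 ms, 90% of the median RR
interval) centered on each R-peak (odd windows take the extra sample
after the peak). One average template per beat kind is built from the
full-window beats of that kind and subtracted at every beat after a
per-beat least-squares amplitude fit — the scaling strictly reduces the
residual and is a no-op when beats are identical; it can be switched
off. Edge windows are truncated. The residual is finally high-pass
filtered at 3 Hz (4th-order Butterworth, zero-phase) to remove QRST
residua and any remaining drift, yielding the f-wave signal f(n).

## Classic predictors

- **FWA** — the RMS of f(n) in mV. An alternative mean-of-squares
  reading is exposed via `mode="mean_square"`; the RMS reading is the
  default because the index is reported in amplitude units (mV) and
  published nFWA medians near 0.06–0.10 are consistent with an RMS
  ratio.
- **nFWA** — RMS(f) divided by the RMS of the preprocessed ECG sampled
  at the R-peaks; dimensionless, robust to inter-patient attenuation.
- **DF** — Welch periodogram with a Hamming window of round(6 s · fs)
  samples (6144 at 1024 Hz), 66% overlap (hop = window −
  round(0.66·window)) and FFT length equal to the window. Windows whose
  PSD (restricted to 3–25 Hz) has Pearson correlation below 0.7 with the
  mean PSD of the remaining windows are discarded before averaging —
  this suppresses windows corrupted by noise bursts or cancellation
  residua. The DF is the argmax of the surviving average within
  3–12 Hz. The screening correlation type and band are implementation
  choices (zero-lag Pearson on the band-restricted PSD); if screening
  discards everything, the unscreened average is used with a warning.
- **Fundamental ff(n)** — f(n) band-passed by a zero-phase 9th-order
  Chebyshev type II filter with band edges DF ± 2.5 Hz and 20 dB
  stopband attenuation; a non-positive lower edge is clipped to 0.5 Hz.
- **SE** — Sample Entropy of ff(n) with m = 2 and r = 0.2 standard
  deviations of ff(n) (population SD). The implementation follows the
  template convention in which both match probabilities are averaged
  over the same N − m templates (the epoch at j spans x[j..j+m]), with
  strict inequality d < r and self-matches excluded. This makes
  A ≤ B an exact identity and SE ≥ 0 always. Zero matches at either
  length yield a flagged NaN (`TemplateMatchCounts.undefined`), never a
  silent exception; a constant series takes the same path. The O(N²)
  pair scan is numba-compiled with a blocked numpy fallback.

## Multiscale entropy

Coarse graining at scale τ replaces the series by means of consecutive
non-overlapping blocks of exactly τ samples (length floor(N/τ)); the
printed summation bound that would imply τ+1 terms per block is treated
as a typo, since only τ-sample blocks reproduce the documented
768-sample length of the scale-40 series of a 30 s segment at 1024 Hz.

- **MSE**: SE of the offset-0 coarse-grained series at each τ = 1..40,
  tolerance frozen at 0.2·SD of the original ff(n).
- **CMSE**: the mean of SE over all τ coarse-graining offsets; offsets
  with undefined entropy are excluded from the mean and a scale is
  flagged only when every offset is undefined.
- **RMSE**: a zero-phase 6th-order Butterworth low-pass at normalized
  cutoff 0.5/τ is applied before keeping every τ-th sample, and the
  tolerance is recomputed per scale as 0.2·SD of the filtered
  (pre-decimation) series. Scale 1 skips the filter (the cutoff would
  sit at Nyquist), making RMSE(τ=1) coincide with SE.

The r for MSE/CMSE is frozen per segment (all metrics are per-segment
quantities); only RMSE rescales it. Undefined entropies at large scales
are flagged and excluded from derived features, with flag counts
surfaced in the run manifest.

Profiles are summarized per region — low τ = 1–10, middle 11–20, high
21–40 — by the **area** (plain sum of entropy values over the region's
integer scales, so a constant profile of 1.0 over 20 scales gives area
20; a trapezoidal alternative is available via `area_rule`) and the
**slope** of a first-degree least-squares fit against the raw integer
scales. The entropy at a "best" scale (29 for MSE/CMSE, 39 for RMSE) is
carried along. A 90 s record is analyzed as three non-overlapping 30 s
segments, each with its own DF, band-pass and tolerance, and segment
metrics are averaged (flagged segments excluded, contributing counts
recorded).

### What the three variants do on reference signals

On white noise the MSE profile decreases monotonically in τ: the frozen
tolerance grows relative to the coarse-grained SD (r/σ_τ ≈ 0.2√τ), so
matches become more likely and entropy drops — the "artificial
regularity" the refined variant is designed to remove. CMSE averages τ
correlated estimates per scale and therefore always has across-seed
variance at most that of MSE. RMSE, by rescaling r, keeps white-noise
entropy near its scale-1 value (≈ 2.2) across scales; because its
per-scale estimates retain full entropy on a τ-fold shorter series, its
across-seed variance on white noise is *larger* than fixed-r MSE's at
large scales, not smaller — the variance advantage of RMSE manifests on
band-limited, f-wave-like signals where fixed-r MSE suffers aliasing
and tolerance-inflation artifacts, and in within-cohort spread rather
than in the white-noise estimator variance.

## Evaluation

The positive class is "relapsing to AF". Normality is tested per group
with a Kolmogorov–Smirnov test of the standardized data against the
standard normal at α = 0.05 (the Lilliefors caveat — critical values are
approximate when parameters are estimated — is accepted: only the test
routing matters downstream). Both groups normal → two-sample t-test;
otherwise Wilcoxon rank-sum. AROC is the probability that a positive
outranks a negative with ties counting ½, computed from ranks and
identical to exhaustive pair counting. Thresholds are midpoints between
consecutive sorted unique scores plus ±∞; the Youden point maximizes
Se + Sp, ties resolved toward higher specificity. Orientation follows
each predictor's direction (nFWA is lower in relapsing patients; the
AROC ≥ 0.5 convention is not forced).

## Synthetic cohort generator

The atrial component is a sum of sawtooth-like harmonics (amplitudes
halving per harmonic) of a fundamental with sinusoidal amplitude
modulation (depth 0.10 at 0.5 Hz), sinusoidal frequency modulation
(±0.2 Hz at 0.1 Hz) and a per-sample Gaussian random-walk phase jitter —
the standard surface-AF signal model, giving independent knobs for the
dominant frequency and for disorganization. The ventricular component
places a fixed Gaussian-lobe QRST morphology (R amplitude 1 mV, compact
T-wave peaking 150 ms after R, consistent with the shortened QT at AF
heart rates and fully contained in the 470 ms cancellation window) at
i.i.d. log-normal RR intervals (mean 0.7 s, CV 0.18 — AF rhythm carries
no sinus correlation structure); ectopic beats are widened, attenuated,
T-inverted versions. Noise adds baseline wander (0.10 mV at 0.33 Hz),
50 Hz powerline interference (0.02 mV) and white noise (0.015 mV) —
exactly the targets of the preprocessing chain.

Group archetypes: patients maintaining sinus rhythm draw their DF from
Normal(4.9, 0.4) Hz with phase jitter 0.02 rad/sample and base atrial
amplitude 0.09 mV; relapsing patients from Normal(5.6, 0.4) Hz with
jitter 0.06 rad/sample and 0.06 mV. The DF centers sit at the published
cohort medians, the spreads make the groups overlap (AROC well below
1), the jitter difference drives the entropy separation, and the
amplitude difference reproduces the nFWA direction (lower in relapse)
at near-equal FWA. The default cohort is 31 SR / 39 relapse records of
90 s at 1024 Hz. Per-record seeds derive from the master seed through
counter-based spawn keys (group, index), so cohorts are reproducible
and order-independent.

What the generator does **not** emulate: genuine atrial
electrophysiology (no tissue model), QRS morphology variability within
a kind, respiratory modulation of RR or amplitude, muscle artifact,
electrode motion, or lead-dependent projection. Passing tests on this
cohort therefore demonstrate that the chain recovers planted spectral
and complexity structure through realistic interference — not clinical
performance on real patients.

## Problem sizes used in the test suite and acceptance script

Unit tests run on short records (8–20 s at 128–512 Hz). The
cohort-level statistical checks synthesize 31/39 cohorts of 10 s records
at 1024 Hz analyzed as a single segment with the RMSE profile — chosen
so the per-record scale-40 series still has 256 samples (above the 10^m
guideline for m = 2) while a ten-cohort direction study completes on one
CPU in minutes. Variance and monotonicity properties use white-noise
records of N = 30720, the exact per-segment length of the reference
configuration. The acceptance script mirrors these sizes with 4 cohort
seeds. Entropy magnitudes at 10 s differ slightly from 30 s values
(shorter series bias SE upward when matches are scarce), which is
immaterial for the direction and discrimination checks performed.

## Known limitations

- The R-peak detector and ectopic classifier are simple energy/template
  methods adequate for the synthetic morphology; real recordings with
  severe artifact would need a clinical-grade detector behind the same
  interfaces.
- Average-template cancellation leaves residua when QRST morphology
  drifts within a kind; spatiotemporal or PCA-based cancellation is out
  of scope.
- AROC confidence intervals, cross-validation and multivariable models
  are out of scope; reported AROCs on small cohorts carry the usual
  binomial uncertainty (SD ≈ 0.07 at n = 70 under the null).
- WFDB-format I/O is not provided; records travel as CSV + JSON
  sidecars.
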