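# Methods

## Scope and model

`scdhrv` classifies one-minute ECG windows as *normal* or *SCD-prone* from a
13-feature HRV vector, and evaluates that classifier with leave-one-out
cross-validation repeated 16 times. The pipeline's stages and their contracts
are described below, with the numerical choices that the underlying method
descriptions leave open and the reasoning behind them.

## Preprocessing

Baseline wander is estimated by two cascaded centred moving averages with
window lengths `round(N/3)` and `round(2N/3)` samples (N = record length),
each forced odd, with reflection padding at the edges, and subtracted.
For a one-minute record these are 20 s and 40 s windows: the estimator
passes only drift far below ~1/40 Hz and has exact nulls at multiples of
1/20 Hz. Consequences worth knowing:

* respiration-band wander (0.15–0.4 Hz) is *not* attenuated by this filter —
  it lies well above the averaging passband; what the filter provides is
  isoelectric-line placement (DC and ultra-slow drift removal);
* edge behaviour depends on the reflection assumption (even symmetry); drift
  components with strong odd symmetry at the record edges leave a residual of
  order 10 % concentrated in the outer thirds.

A median-filter variant of the same cascade is available behind
`FilterConfig(use_median=True)`, since prose descriptions of this step
sometimes say "median filtered"; the moving-average form is the default
because the window-length prescription (1/3, 2/3) is stated for it.

Powerline interference is removed with a second-order IIR notch
(`scipy.signal.iirnotch`, default bandwidth 2 Hz) applied forward–backward.
Zero-phase application is non-negotiable here: every downstream feature is a
function of R-peak *times*. Steady-state rejection at the notch frequency is
essentially complete; the residual on finite records is edge transient
(about 2 % RMS on a 60 s record, concentrated in the first and last second).

## QRS detection

Classic Pan–Tompkins stage sequence with all lengths in milliseconds
(converted by rounding to samples, so 128 and 256 Hz behave identically):
5–15 Hz third-order Butterworth band-pass (zero-phase), centred five-point
derivative, squaring, 150 ms moving-window integration, dual adaptive
thresholds (`npk + 0.25 (spk − npk)`, exponential update 0.125/0.875) on the
integrated and band-passed signals, 200 ms refractory period, T-wave
rejection by slope comparison inside 360 ms, and search-back with a halved
threshold when no beat appears within 1.66 × the mean of the last eight RR
intervals. Thresholds are initialised from the first 2 s of signal.

Two implementation details matter:

* the filtered-signal threshold is compared against the *local peak* of the
  band-passed signal within ±75 ms of the integrated-signal candidate, not
  the sample under the candidate — the band-passed QRS rings, and the
  integrated maximum can coincide with one of its zero-crossings;
* accepted beats are refined to the band-passed maximum within ±80 ms, which
  is what bounds the timing error by roughly one sample period.

Detections are invariant to overall gain (thresholds are self-scaling; the
test suite checks ×0.5 and ×2 exactly). No ectopic-beat rejection is applied
to the RR series — the method treats detected RR as NN.

## Tachogram and spectral features

The RR series (each interval time-stamped at its terminating beat) is
resampled by cubic spline onto a uniform 4 Hz grid and mean-removed. 4 Hz is
standard HRV practice; its Nyquist frequency (2 Hz) clears the 0.4 Hz HF band
edge by 5×.

The power spectrum is a Burg autoregressive estimate, default order 16 for a
240-sample one-minute tachogram (a compromise between resolving the LF and HF
peaks and keeping the fit stable), evaluated on a 1024-point grid over
[0, rate/2]. Three numerical safeguards:

* the input is standardised before the recursion (the AR polynomial is
  scale-invariant in exact arithmetic but not in floating point near
  singular fits) and a fixed-seed dither of 1e-6 relative SD (1e-12 in
  power) keeps noise-free deterministic inputs off the singular manifold;
* fitted pole radii are clamped to 0.999 so that near-unit-circle poles
  produce finite, grid-resolvable peaks;
* the density is rescaled so its trapezoidal integral over [0, rate/2]
  equals the sample variance, making band powers Parseval-consistent by
  construction.

Band powers integrate the density over VLF 0.003–0.04, LF 0.04–0.15 and HF
0.15–0.4 Hz (half-open bands). LF/HF with zero HF power yields an infinity
sentinel, clipped downstream. Table-level feature slots carry VLF, HF and
LF/HF; LF itself is computed but not part of the 13-feature vector.

## Time–frequency features

The smoothed pseudo Wigner–Ville distribution of the analytic (Hilbert)
tachogram is computed as the lag-domain FFT of the instantaneous
autocorrelation `x(n+p+k)·x*(n+p−k)`, time-smoothed by a window `g` and
frequency-smoothed by a window `h`, both symmetric and unit-sum. Frequency
bin m maps to `m·rate/(2·Nf)`, so the map spans [0, rate/2). Defaults:
Hamming `h` of length ≈ L/4 and Gaussian `g` of length ≈ L/10 (L = signal
length), both odd. With `h = g = δ` the implementation reduces to the raw
Wigner–Ville distribution and satisfies the time-marginal identity
Σₘ SPWVD(n, m) = |x(n)|²; the FFT path is verified against a brute-force
triple-loop evaluation of the definition to 1e-9.

Cross-term residue makes the distribution locally negative; the map keeps
those values (they are part of the distribution's algebra) and energy
features use a rectified copy `max(·, 0)`.

Features: the time axis is cut into 5 equal segments (12 s for a one-minute
window — the segment count is treated as authoritative over the "about 15 s"
description, and a 15-s-window option exists in the config); each segment's
energy is its mean rectified cell value; MAXw/MINw/DIFw/STDw summarise the
five energies (DIFw = max − min, STDw = sample SD). Band energies Evlf/Elf/
Ehf divide total band energy by the band width (0.037/0.11/0.25 Hz);
Fvlf/Flf/Fhf are band cell means. The first-order derivative feature takes
dⱼ = Eⱼ − Eⱼ₋₁, with the first window differenced against the last segment
energy of the *preceding* minute when that context exists (omitted
otherwise), and is summarised by the mean of |dⱼ| — the scalarisation is a
design choice (options: mean_abs / max_abs / sum_abs) since only the
derivative sequence itself is prescribed; the mean of magnitudes captures
"energy moves abruptly between windows" irrespective of sign.

## Nonlinear features

Poincaré SD1/SD2 are RMS *signed distances* of the (RRᵢ, RRᵢ₊₁) points from
the lines y = x and y = −x + 2·mean(RR) — the population convention with the
mean distance taken as zero. This makes SD1 = RMSSD/√2 an exact identity
(asserted to 1e-9) and SD1² + SD2² ≈ 2·Var(RR). SD2 is computed but excluded
from the default 13-feature vector, which carries SD1 and SD1/SD2. A zero
SD2 yields an infinity sentinel for the ratio.

DFA integrates the centred RR series, removes a least-squares line per
non-overlapping box, and fits a single scaling exponent α to log F(n) vs
log n over 16 log-spaced box sizes in [4, N/4]. First-order detrending and a
single overall α are the classic choices; the box range is ours (none is
prescribed). Requires N ≥ 64 intervals; the ≈ 65–85 beats of a one-minute
window sit just above this, so α from one-minute windows is a noisy but
usable feature (the calibration tests use N = 4096, where α recovers
(β+1)/2 of synthetic 1/f^β input to ±0.05–0.1).

## Classifiers and evaluation

Features are z-scored per training fold (means/SDs from training rows only);
infinity sentinels are clipped to the training fold's maximum before
standardisation. Scaling is a deliberate addition — the 13 features mix ms,
ms² and dimensionless ratios, and unscaled Euclidean k-NN would be dominated
by the ms² features; it can be disabled per spec object.

The MLP is input–5–1 with sigmoid hidden units and a linear output, trained
by full-batch gradient descent on the MSE of 0/1 targets with the classic
variable-learning-rate schedule: ×1.05 after an improving step, ×0.7 with
weight rollback after a step that worsens MSE by more than 4 %. Training
stops at MSE < 0.01 or 1000 iterations; prediction thresholds the linear
output at 0.5; clipped to [0, 1] it doubles as the event-probability score
for risk trajectories. Weights initialise uniform ±0.5 from a seed, and the
16 evaluation repetitions differ *only* through that seed (base_seed + r).

k-NN uses z-scored Euclidean distance, odd k ∈ {1,3,5,7,9} (default 7), with
equal distances resolved in training-row order via a stable sort — hand-built
on numpy because that tie-break is part of the contract; the test suite
cross-checks predictions against scikit-learn's implementation.

Sequential forward selection greedily adds the feature that maximises
leave-one-out accuracy on the training table, ties broken toward the lower
feature index, and stops when the best candidate no longer improves. Run
inside each LOO fold it is honest but expensive with the MLP scorer;
per-fold selection is therefore off by default and available via
`select_features=True`.

Evaluation: LOO over all n observations; confusion counts with SCD positive;
16 repetitions; summary metrics computed **from the averaged counts** (the
mean-of-per-run-metrics is also kept). Specificity follows its definition
TN/(TN+FP) throughout — the worked-example source table prints a specificity
column (values near 0.001 %) that is inconsistent with that definition given
its own count tables, and is not reproduced.

## Synthetic data

The generator is phenomenological, not a cardiovascular model:

* RR series: mean + LF and HF sinusoids + 1/f^β fractal noise (spectral
  synthesis: rFFT amplitudes ∝ f^(−β/2), random phases) scaled to a target
  SD, with an optional slow amplitude envelope (depth 0..1) that modulates
  all variability across the window;
* ECG: Gaussian P-QRS-T bumps at the cumulative beat times (R ≥ 3× T by
  default), plus additive baseline/powerline/white artifacts;
* cohorts: per-subject parameters drawn around class templates calibrated to
  published group statistics for short-term HRV in normal vs SCD-prone
  subjects — mean NN 876 ± 134 vs 706 ± 147 ms, SDNN 58.4 vs 64.2 ms, DFA α
  0.83 ± 0.15 vs 1.12 ± 0.18 (mapped to β = 2α − 1), LF/HF ≈ 0.75 in both
  classes — plus envelope depth 0.8 (SCD) vs 0.1 (normal), the one knob with
  no published magnitude, chosen once to emulate pre-arrest autonomic
  instability and drive the time–frequency features in the observed
  direction. Subjects whose sampled parameters produce an RR ≤ 200 ms series
  are redrawn deterministically within the master seed's stream.

What the generator does *not* emulate: arrhythmic morphology (VF onset),
ectopic beats, respiration–cardiac coupling, circadian nonstationarity, or
any channel/electrode effects. Passing tests therefore demonstrate that the
pipeline recovers *planted* class structure of the published direction and
rough magnitude — not clinical performance on Holter recordings.

## Problem sizes and determinism

Default study conditions: 35 subjects per class, one-minute windows, 4 Hz
tachogram, 16 evaluation repetitions. DFA calibration uses N = 4096 beats;
the QRS benchmark 200 beats × 5 seeds; the SPWVD brute-force cross-check a
32-sample signal (the double loop is O(L²·Nf)). Every random draw descends
from an explicit integer seed; identical seeds give bit-identical RR series,
feature tables and MLP weights on a fixed platform.

## Known limitations

* The baseline filter's fixed window fractions make its passband depend on
  record length; it is designed for one-minute windows.
* AR band powers on near-line spectra depend on the pole-damping constant;
  relative two-tone power is recovered to ~10 %, not exactly.
* DFA on 60–80 intervals has high variance; α is informative only jointly
  with the other features at this window length.
* The MLP's LOO accuracy varies a few percent across seeds (92–99 % on the
  default cohort); k-NN is deterministic and 3–5 points lower.
* Two-channel records are treated as independent observations, as in the
  source protocol; channels from one patient are of course correlated, and
  the evaluation does not account for that dependence.
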