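# scdhrv

Short-term heart-rate-variability (HRV) analysis for **sudden cardiac death
(SCD) risk prediction**. SCD kills within minutes of symptom onset, usually
through ventricular fibrillation, and the resting ECG of a person minutes away
from the event is indistinguishable from a healthy one by eye. The beat-to-beat
interval series, however, carries early signatures: reduced mean NN interval,
altered sympathovagal balance, a shifted long-range-correlation exponent, and —
most discriminative — abrupt redistribution of time–frequency energy from one
15-second window to the next.

`scdhrv` implements the full pipeline from raw ECG to a per-minute risk score:

1. **Preprocessing** — baseline-wander removal by a two-stage centred
   moving-average filter (window lengths 1/3 and 2/3 of the record) and a
   zero-phase IIR notch at the mains frequency (50/60 Hz).
2. **QRS detection** — Pan–Tompkins (band-pass 5–15 Hz, derivative, squaring,
   150 ms moving-window integration, dual adaptive thresholds, 200 ms
   refractory period, T-wave slope discrimination, search-back at 1.66 × the
   running RR average), all stage lengths specified in milliseconds so 128 Hz
   and 256 Hz recordings are treated identically.
3. **Feature extraction** — the 13-feature combinational HRV vector per
   one-minute window:
   * time domain: MNN, SDNN, RMSSD, pNN50 (pNN50 = 100·#{|ΔRR| > 50 ms}/N);
   * frequency domain: Burg autoregressive spectral power in VLF
     (0.003–0.04 Hz) and HF (0.15–0.4 Hz) bands, and the LF/HF ratio, on the
     4 Hz cubic-spline-resampled tachogram;
   * time–frequency: the smoothed pseudo Wigner–Ville distribution
     SPWVD(n, m) = Σₖ h(k) [Σₚ g(p) x(n+p+k) x*(n+p−k)] e^(−j2πkm/N),
     summarised by segment-energy statistics DIFw and STDw over 5 equal time
     windows and the first-order-derivative feature W_dif of the segment
     energies;
   * nonlinear: Poincaré SD1 and SD1/SD2 (RMS distances of the (RRᵢ, RRᵢ₊₁)
     cloud from y = x and y = −x + 2·mean), and the detrended-fluctuation
     scaling exponent α (α = 0.5 white, 1.0 1/f, 1.5 Brownian).
4. **Classification and evaluation** — sequential forward feature selection
   wrapped around a classifier, then either a 13–5–1 perceptron (sigmoid
   hidden, linear output, variable-learning-rate back-propagation, stop at
   MSE < 0.01 or 1000 iterations) or a k-nearest-neighbour vote (k odd,
   Euclidean, z-scored per training fold), scored by leave-one-out
   cross-validation repeated 16 times. Metrics from averaged confusion counts:
   AC = (TP+TN)/N, SN = TP/(TP+FN), SP = TN/(TN+FP), P = TP/(TP+FP).

A synthetic-data module generates labelled two-class cohorts (beat trains with
prescribed mean RR, LF/HF sinusoidal modulation, 1/f^β fractal noise, and a
nonstationarity envelope emulating pre-arrest autonomic instability, rendered
to ECG waveforms with Gaussian P-QRS-T morphology plus baseline/powerline/white
artifacts), so every stage is testable without access to Holter databases.

## Worked example

```python
from scdhrv import ScdRiskModel, KnnSpec
from scdhrv.pipeline import PipelineConfig, cohort_feature_table

table = cohort_feature_table(PipelineConfig(base_seed=1))   # 35 + 35 subjects
results = ScdRiskModel(table, classifier=KnnSpec(k=7)).fit(n_repeats=16, seed=1)
print(results.summary())
print("selected features:", results.selected_features())
```

prints

```
SCD risk model — repeated leave-one-out evaluation
====================================================
Observations:        70  (positive class: scd)
Classifier:          KnnSpec KnnSpec(k=7, zscore=True)
Repetitions:         16
Feature selection:   off
----------------------------------------------------
Averaged counts:     TP=30.000  TN=34.000  FP=1.000  FN=5.000
Accuracy:            91.43 %
Sensitivity:         85.71 %
Specificity:         97.14 %
Precision:           96.77 %
====================================================

selected features: ['stdw_tf', 'pnn50', 'rmssd']
```

Of the 35 synthetic at-risk subjects, 30 are recognised on every
leave-one-out repetition (k-NN is deterministic, so all 16 rows coincide);
one healthy subject is misflagged. Forward selection picks the
time–frequency window-energy spread `stdw_tf` first — the same family of
features that dominates separability on real pre-arrest recordings — and
stops after three features. The MLP classifier on the same table reaches
95.7 % leave-one-out accuracy.

The same pipeline is scriptable from the shell:

```bash
scdhrv run --seed 1 --n-per-class 35 --out runs/demo     # end-to-end
scdhrv simulate --n-per-class 5 --ecg --out cohort/      # ECG waveforms
scdhrv detect cohort/scd000_ecg.csv                      # beat times (s)
```

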