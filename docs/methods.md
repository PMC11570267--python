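# Methods

`rhythmshift` quantifies how the *waveform* of diurnal gene expression —
not just its amplitude, period or phase — changes between conditions,
typically between young and old plant leaves sampled across a light/dark
cycle. This note describes the models, the estimators, the synthetic-data
generator the test suite runs against, and the numerical choices made where
the design was genuinely open.

## Time conventions

All times are Zeitgeber time (ZT): decimal hours since lights-on, on the
interval [0, 24) with circular wraparound. The entrainment schedule assumed
for interpretation (not computation) is LD 16:8 — lights-off at ZT16 —
recorded as metadata only. "Noon" defaults to ZT8, the midpoint of the light
phase. Free-running (circadian) analyses use an unconstrained period.

## Waveform parameterization (FWHM analysis)

A single daily cycle is a curve of (time, value) samples. It is min-max
normalized so min = 0 and max = 1, then scanned for maximal contiguous
regions with value >= 0.5, wrapping across the cycle boundary in diurnal
mode. When there is exactly one such region, the ascending and descending
half-maximum crossings are located by linear interpolation between the
bracketing samples:

    t* = [t2 (f1 - 1/2) - t1 (f2 - 1/2)] / (f1 - f2),

which returns t1 or t2 when an endpoint equals 1/2 exactly (that endpoint
convention is deliberate and tested). FWHM is the circular distance from the
ascending to the descending crossing; it measures the hours per day spent
above half of peak expression. Curves with zero or more than one
super-half-max region report the segment count and no duration — multi-peak
adjudication is delegated to the permutation test below rather than guessed.

The crest is the maximum sample (earliest-time tie-break); the trough is the
minimum sample with the same tie-break, flagged when tied. The ascending
section is (crest − trough) mod 24 and the descending section its
complement, so the two always sum to the cycle length.

Multi-day single traces (e.g. luciferase luminescence) are detrended by
subtracting a centered running mean (default window 24 h). The outer
half-window on each side is distorted by the shrinking window; the `trim`
option drops it and is recommended before period estimation. The
free-running period is estimated by a cosinor scan: ordinary least squares
of mesor + a·cos + b·sin at each candidate period on a grid (default
20–30 h, step 0.05 h), keeping the period with the highest R². The fit
p-value is Bonferroni-gated by the number of scanned periods before a trace
is called rhythmic, because the scan maximizes over many correlated tests. A
single-component cosinor is slightly biased for strongly skewed waveforms
(harmonics leak across periods over a finite window); the period tests
therefore use sinusoidal generator shapes, and printed periods from skewed
reporter data should be treated as approximate.

## Rhythmicity detection (cosinor)

Each gene in a genes × samples matrix is fit by OLS to

    y(t) = M + A cos(2π(t − φ)/24)

via the linear regressors {1, cos(2πt/24), sin(2πt/24)}; A and φ come from
the two rhythm coefficients, and significance is the F-test of those two
coefficients against the intercept-only model. A gene is called cycling when
the raw p-value falls below 0.0005. No multiple-testing correction is
applied — the raw cutoff *is* the detection rule, exposed as a parameter.
The type-I rate of the F-test at this threshold is verified by simulation
(20,000 null genes, binomial interval). Zero-variance genes get amplitude 0
and p = 1. Amplitude change between ages is classified on the old/young
amplitude ratio with default cutoffs 2/3 ("lower") and 3/2 ("higher");
the cutoffs are package defaults, configurable.

## Single-oscillation genes and the FWHM-change test

With r replicates at each of T time points, a *permutation curve* draws one
replicate value per time point uniformly at random (r^T combinations,
sampled with replacement). An ensemble of n = 10,000 such curves per gene
yields:

* the **single-FWHM ratio** — the fraction of curves with exactly one
  super-half-max region after min-max normalization. A ratio > 0.95 defines
  a single-oscillation gene (SOG). Constant (degenerate) resampled curves
  count as non-single.
* the **ensemble-mean FWHM** (and circular-mean crossings), averaged over
  the single-FWHM curves, used for the daily FWHM timetable.

The FWHM-change test between two ages computes ΔFWHM = mean FWHM(old) −
mean FWHM(young) over the two ensembles and a two-sided p-value by
resampling group labels between the pooled ensemble FWHM values. A change is
significant only when p < 0.05 **and** |ΔFWHM| > 2 h, and its direction
(shortened/lengthened) is the sign of ΔFWHM.

Two caveats are intentional and documented. First, ensemble values within
one age share the same underlying r×T measurements, so the label-resampling
p-value is anti-conservative at the dataset level; the 2-h gate is what
controls the realized rate of significant calls, which stays at or below
0.05 under the null in simulation. Second, the test's SOG precondition
re-draws ensembles internally, which would re-randomize borderline calls;
callers that have already adjudicated SOG status (the pipeline, the CLI)
pass `sog_threshold=None` to skip the re-check. Tests run at n = 1,000
permutations for speed; n is a parameter and defaults to 10,000.

## Physiological time (circular ridge regression)

Two ridge-penalized linear regressions map a per-sample expression profile
x to the cosine and sine of its sampling time:

    o1 ≈ cos(2πt/24),   o2 ≈ sin(2πt/24),

and the predicted time is the angle of the output point,
t̂ = (24/2π)·atan2(o2, o1) mod 24. The norm √(o1² + o2²) is reported as a
confidence proxy. Features are centered and scaled on the training samples
so the shared penalty treats genes comparably (the source procedure is
silent on scaling; this is the package's choice). The penalty defaults to
the ridge regressor's standard value 1.0. Validation is leave-one-time-
point-out: all samples of one ZT are held out, the model refit, and the
held-out samples' circular errors recorded; on study-design synthetic data
(6 ZTs × 3 replicates, ≥ 500 cycling features, noise cv 0.1) the maximum
error stays well under the 2-h bound the procedure is expected to meet.
Errors between clock times are always circular, err(a,b) = min(|a−b|,
24−|a−b|) ∈ [0, 12], which is a metric on the circle (tested).

Trained on a reference age (features default to the common-SOG list in the
pipeline), the model maps any other matrix onto the reference clock: per
query ZT the replicate predictions are combined by circular (vector) mean —
an arithmetic mean is wrong on the circle — giving a subjective-time curve
whose consecutive spans sum to a full day. The distance of each query ZT
from a reference clock time (default ZT8) summarizes how much of the
reference day the query age experiences.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions every
downstream guarantee is measured under.

**Waveform family.** w(t) = baseline + amplitude · s(t)^k, where s(t) is a
piecewise half-cosine ramp rising 0→1 over `rise` hours before the crest and
falling 1→0 over `fall` hours after it (rise + fall = period), extended
periodically. Phase, skew and width are controlled independently: k = 1
gives an FWHM of exactly half the period regardless of skew (the ramp passes
0.5 at each ramp midpoint), k > 1 narrows the peak and 0 < k < 1 broadens it
beyond half the period — broad evening waveforms (e.g. a 12.6-h FWHM)
require k < 1, which is why the constraint is k > 0 rather than k ≥ 1.
`sharpness_for_fwhm` inverts the closed-form crossing geometry to hit a
target FWHM exactly. Ground-truth FWHM is computed on a dense grid (step
0.001 h) centered on the crest, independently of the analysis module, and
cross-checked against the closed form in the tests.

**Designs emulated.** Transcriptome mode: ZT1, 5, 9, 13, 17, 21 × 3
replicates per age. qPCR mode: 30-min sampling over 24 h. Reporter mode:
multi-day traces at 20-min (or finer) intervals, optional non-24-h period
and linear trend. Cycling-gene parameters draw uniformly from peak phase
[0, 24), rise [6, 18] h (fall = 24 − rise), sharpness [1, 3], amplitude
[2, 10], baseline [0.5, 2]; flat genes have constant mean in [1, 10]. These
ranges are the package's calibration — the source data report no noise
magnitudes or replicate variances — chosen so cosinor detection at
α = 0.0005 is near-ceiling for cycling genes at low noise while flat genes
stay at the nominal false-positive rate.

**Noise.** Default multiplicative lognormal, mean-preserving, with
coefficient of variation `noise_cv` (default 0.1 for transcriptome mode,
0.05 for qPCR-like dense sampling; the realistic range is 0.05–0.2).
Additive Gaussian (sd = cv·mean) is retained for analytic checks. All
randomness flows from one seed; each gene draws from a sub-stream keyed by
(seed, gene index), so generated matrices are stable when genes are appended.

**Age effects.** Per age: amplitude scaling, phase shift, and
sharpen/broaden (multiply/divide sharpness by a factor, default 2) applied
to a stable random fraction of cycling genes. Rise + fall is untouched, so
the period is preserved.

**What the generator does not emulate.** Real RNA-seq count noise
(overdispersion, mean–variance coupling beyond a constant cv), gene–gene
correlation, batch effects, missing samples, and waveforms outside the
powered-ramp family (plateaus, shoulders, genuine multi-peak rhythms beyond
the constructed bimodal fixtures). Passing tests therefore demonstrate
correctness of the estimators under controlled waveform/noise conditions,
not performance on any particular real dataset.

## Pipeline and descriptive outputs

`run_full_analysis` chains simulate → cosinor per age → SOG tests per age →
common-SOG partition → FWHM-change tests → physiological time (LOOCV +
subjective-time curve) → summaries: ZT-by-ZT Pearson correlation matrix with
best and second-best reference matches (replicate-averaged profiles over the
feature set), PCA coordinates of samples (optionally after dividing each
gene by its per-age mean, which merges amplitude-separated ages), a polar
histogram of peak-time bins (default width 4 h, matching the 6-ZT grid) by
FWHM-change direction, and the per-gene FWHM timetable. Every count in the
JSON report is recomputable from the emitted TSV tables; the report records
the seed and a configuration hash (excluding the output path).

## Problem sizes in the shipped checks

The test suite and the acceptance script run at sizes chosen for a single
CPU: 10 simulation seeds and 500 features for the cross-validation bound;
10,000 permutation curves for the single-FWHM gate; 1,000-curve ensembles
with 300–500 label resamples for the change-test properties (150–200 null
genes); 20,000 null genes for the cosinor type-I interval. Defaults in the
library remain at the full-scale values (n = 10,000 permutations).

## Known limitations

* The cosinor period scan is a stand-in where no period-estimation algorithm
  is prescribed; it is exact for sinusoids and slightly biased for skewed
  waveforms.
* The label-resampling p-value of the FWHM-change test is anti-conservative
  in isolation (see above); interpret significance only jointly with the
  2-h gate, as the procedure defines.
* FWHM estimates from 4-h-spaced transcriptome sampling carry interpolation
  error of up to ~1 h for broad, flat-topped waveforms; the permutation
  ensemble averages over replicate noise but not over the sampling grid.
* `detect_cycling` applies a raw threshold by design; at 0.0005 with ~20,000
  genes, ~10 false positives are expected and no FDR control is attempted.
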