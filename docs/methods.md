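# Methods

## Scope and data model

The package analyzes epoched electrophysiological time series: 1 s epochs
at 256 Hz (both configurable), each labeled with one of four states (EC,
EO, BSL, VS) and a subject identifier, over one or more spatial units
(cortical parcels or channels). All stages — feature extraction,
classification, clustering — operate on this representation; real
recordings can be supplied through the HDF5/CSV containers in
`statefeats.io`, and the synthetic generator produces cohorts with the
same structure so the full pipeline is testable without any recording.

## Synthetic cohort generator

Each epoch is a sum of four independent components:

1. **Aperiodic background**: Gaussian white noise whose spectral amplitudes
   are shaped by f^(−χ/2) (DC zeroed), giving an expected power spectrum
   ∝ f^(−χ). χ is state-dependent (EC 1.5, EO 1.3, BSL 1.4, VS 1.15 — the
   flattest slope under stimulation, the usual excitability signature). The
   background scale (5.0) was chosen so broadband background sd is
   comparable to the oscillation amplitudes, as in real recordings.
2. **Oscillations**: sinusoids with uniform random phase and, when the
   burst fraction is below 1, a rectangular on/off envelope of that duty
   cycle at a uniformly random onset (the simplest model of isolated
   bursts). Default presets put alpha (10 Hz) in every state with
   amplitude EC 1.2 > BSL 0.8 > VS 0.55 > EO 0.45 and gamma (60 Hz) in the
   task states with amplitude VS 0.45 > BSL 0.1.
3. **Baseline drift**: a per-epoch constant offset that follows a random
   walk across each state's contiguous epoch sequence, scaled by a
   state-dependent drift amplitude (EC largest, 0.6). Within a 1 s epoch a
   sub-0.5 Hz drift is effectively constant, so the offset representation
   is exact at this epoch length; the walk makes mean/median informative
   across blocks.
4. **Sensor noise**: i.i.d. Gaussian, sd 0.2 in all states.

Between-subject variability multiplies every positive magnitude by
exp(σ·z) with σ = `subject_sd` (default 0.15; center frequencies use
0.2σ so peaks stay in-band). All draws flow through
`numpy.random.SeedSequence` streams spawned from one master seed; a fixed
configuration is bit-reproducible.

The default cohort — 5 subjects × 10 epochs/state × 4 units — is a
deliberately compact stand-in for a real multi-subject study; the
generator scales to arbitrary sizes. What the generator does **not**
emulate: cross-unit coupling and source leakage, non-sinusoidal waveform
shape, heavy-tailed artifacts, non-stationarity beyond rectangular bursts
and drifts. Passing tests therefore demonstrate the pipeline's correctness
and the recoverability of the encoded contrasts, not real-data effect
sizes — the presets are calibrated to reproduce orderings (alpha EC > EO,
gamma VS > BSL), which is all the downstream qualitative checks assert.

## Spectra and spectral feature sets

Per-epoch spectra are single-taper periodograms (Hann by default) with
"spectrum" normalization: for the untapered variant the one-sided power
values over all bins sum to the signal's mean square, so non-DC power sums
to the population variance — the variance↔total-power identity asserted in
the tests at 1e-8 relative tolerance. One-second epochs give exactly 1 Hz
resolution, as the fullFFT set (power at 1..100 Hz) requires. Band power
is the arithmetic mean over a band's bins, boundary bins inclusive on both
sides (adjacent bands share edge bins; double counting across distinct
features is harmless for classification). Band-passed TimeFeats use a
4th-order zero-phase (forward–reverse) Butterworth band-pass, matching the
filter family typical of M/EEG preprocessing; its edge transients are an
accepted cost at 1 s epochs.

## TimeFeats (41)

Composition: 22 catch22 + 2 aperiodic + 5 distribution + 2 Hjorth +
1 Hurst + 1 zero crossings + 1 mean curve length + 7 entropy/complexity.
The registry is fixed and ordered; every epoch yields exactly one value
per entry, with NaN (never an exception) wherever a definition breaks
down on degenerate input. Conventions that matter:

- **Mean curve length** uses raw first differences with no sampling-rate
  scaling; the sampling rate is constant within a study, and the raw form
  keeps the feature dimensionally simple.
- **Kurtosis is non-excess** (a Gaussian scores 3); skewness/kurtosis are
  the standardized 3rd/4th central moments; sd uses the N−1 denominator.
- **Zero crossings** are counted on the mean-removed signal (removes
  drift-induced bias; exact zeros count as positive).
- **Hurst** is the classical rescaled-range estimate: slope of log(R/S)
  over dyadic windows 8..N/2; inputs shorter than 64 samples give NaN.
  R/S has a known small-sample upward bias (white noise at N = 8192 reads
  ≈ 0.55); the method name is recorded so a DFA variant can be swapped in.
- **Entropies** use the field's standard defaults: sample/approximate
  entropy with m = 2, r = 0.2·sd; permutation entropies with order 3,
  delay 1, normalized to [0, 1]; spectral entropy is the Shannon entropy
  of the normalized non-DC periodogram divided by log(#bins); Lempel–Ziv
  is the LZ76 phrase count of the median-binarized signal normalized by
  N/log₂N; Higuchi FD uses k_max = 10.
- **catch22** descriptors follow the published definitions of the set and
  are computed on the z-scored signal, in a fixed documented order. Where
  the published material leaves a micro-convention open the following
  choices apply: the auto-mutual-information histogram pads the data range
  by ±0.1 with 5 even bins; the Wang periodicity feature detrends with a
  least-squares cubic spline with two interior knots at N/3 and 2N/3; the
  embedding-distance feature uses numpy's "auto" histogram rule; DFA uses
  50%-overlapping windows while the rs-range variant uses disjoint ones;
  both fluctuation features fit the two-regime split by minimizing total
  squared error over split points with at least 6 points per regime.
  These choices can shift individual values slightly relative to other
  implementations of the set but preserve each feature's definition and
  its behavior on the oracle signals used in the tests.

## Peak-exclusion aperiodic estimation

Per spatial unit: (1) average the Hann spectra of all epochs; (2) fit a
robust log–log seed line (OLS, then refit on the bins at or below the
median residual, which tracks the aperiodic floor under peaks); (3)
iteratively take the largest residual ≥ 0.1 log₁₀-units, fit a Gaussian
(height bounded by twice the residual, σ within 0.5–6 Hz, i.e. bandwidth
2σ within 1–12 Hz), subtract it, and repeat up to 6 peaks; (4) exclude
[center − bw, center + bw] (multiplier 1×, configurable) around every
retained peak; (5) per epoch, OLS of log₁₀ power on log₁₀ frequency over
the retained 1–100 Hz bins. Fixed (no-knee) aperiodic form only; offset is
defined at log₁₀ f = 0. Zero-power bins are dropped with a warning; fewer
than 3 usable bins yields a NaN fit that flows into the imputation stage.

On synthetic epochs with a sustained alpha oscillation, the masked fit
recovers χ ∈ {0.5, 1, 1.5, 2} within ±0.15 (mean over 50 epochs) while the
unmasked fit is consistently more biased — the motivating property of the
procedure. Exact numerical parity with reference spectral-parameterization
software is a non-goal; the contract is the recovery property.

## Classification

Observations are epochs; columns are feature × spatial-unit
(feature-major order). Preprocessing per fold, fitted on training rows
only and frozen: all-NaN training columns dropped with a warning; NaN →
train column mean; subtract train median and divide by train IQR (IQR 0 →
scale 1); elementwise tanh; PCA retaining the smallest component count
whose cumulative explained-variance ratio reaches 0.90. Two PCA layouts
mirror the two analysis modes: one global PCA over all columns
(within/between schemes) or one PCA per feature across its unit columns,
blocks concatenated (across-scheme feature-set runs, preserving all 41
feature blocks).

The classifier is a soft-margin SVM, RBF kernel with C = 10 and
γ = 1/(n_columns × mean column variance) computed on the transformed
training block (the conventional "default gaussian kernel" width rule);
multiclass is one-vs-one majority voting with ties broken by summed
pairwise decision values. Balanced accuracy (unweighted mean of per-class
recall over classes present in the test labels) is reported per fold and
pooled over concatenated test predictions.

Fold construction: *within* runs one classifier per subject with k-fold
partitions (default 5 on the compact cohort; 10 on longer recordings);
*between* is leave-one-subject-out, or a grouped k-fold that never splits
a subject when fewer folds are requested; *across* rotates, per subject,
the k-th contiguous chunk of each state block into the test set (10 folds
≈ 90/10), with a single-split 85/15 mode for fast runs. Test chunks are
contiguous inside each condition's recording block — the form of
contiguity that limits leakage between filter-overlapping neighboring
epochs — rather than across a subject's whole concatenated timeline, which
would starve training folds of entire classes when states are recorded in
blocks. A permutation null (true labels shuffled against fixed pooled
predictions) provides the chance reference; with four balanced states it
centers on 0.25.

## Feature clustering

One vector per feature: its values concatenated over all spatial units and
all subjects' epochs (imputed with column means first, the same values the
classifier sees). Distance 1 − |Pearson r|, so anti-correlated features
count as redundant; complete linkage. Zero-variance features are flagged
as NaN rows and must be removed before linkage. On the default cohort the
location features (mean, median — driven by the drift walk) merge at
distance ≈ 0.03 while the width family (sd, mean curve length, aperiodic
offset — all amplitude-driven) forms a separate group; the two families
stay apart up to high linkage heights, reproducing the expected
redundancy structure. Since catch22 z-scores its input, the width family
here is carried by the raw-unit features only.

## Problem sizes and determinism

The shipped analyses and checks use the compact default cohort
(5 × 40 × 4 units; 200 observations, 164 TimeFeats columns), 50-epoch
aperiodic recovery runs and 500–1000-draw permutation nulls — sizes chosen
so a full run completes in minutes on one CPU while every assertion is
comfortably inside its tolerance. Every stochastic step draws from a named
stream derived from a single seed; rerunning any stage with the same
configuration reproduces its outputs bit-identically.

## Known limitations

- The generator's effect sizes are synthetic orderings, not fitted to any
  real cohort; absolute accuracies on this data say nothing about real
  M/EEG decoding rates.
- Independent spatial units: no connectivity, no leakage, so unit counts
  only add redundancy-free dimensions — optimistic relative to source space.
- catch22 micro-conventions as listed above; the Hurst R/S small-sample
  bias; filtfilt edge transients on 1 s banded epochs.
- The per-feature PCA mode assumes each feature's unit columns are jointly
  informative; with a single unit it reduces to a no-op per feature.
- Knee-mode aperiodic spectra (flattening below a corner frequency) are
  not modeled; spectra violating the fixed power-law form will bias the
  slope.
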