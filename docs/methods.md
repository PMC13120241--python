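# Methods

This note documents the models, numerical choices and limitations behind
`enofuse`. The package implements a complete odour–image fruit-ripeness
analysis chain and a synthetic campaign generator that stands in for field
data, so every claim below is exercised by the test suite on simulated
inputs.

## Acquisition model

Temperature-modulated metal-oxide (MOX) gas sensors are driven through a
fixed heater-voltage (VH) schedule: a pre-heating stage at 5 V followed by
the five analysis levels 7, 5.5, 5, 6, 6.5 V separated by 0 V rests. Two
modulated protocols are shipped — a 10-minute acquisition (30 s stages,
5 min preheat, 6000 samples at 10 Hz) and a 48-minute acquisition (300 s
stages, 20 min preheat, 28,800 samples) — plus a continuous constant-5 V
protocol. The stage tables sum to 30 s less than the nominal acquisition
lengths; we extend the final 6.5 V stage to absorb the remainder so the
nominal point counts are exact, while analysis segments use the nominal
stage durations (so every active-level segment is 300 samples for the short
protocol and 3000 for the long one, and the 30 s extension is recorded but
not analysed). Segment boundaries are half-open sample-index intervals at
10 Hz, which partitions the trace without duplicated samples. The saved
trace includes the preheat period; this is required for the point counts to
work out and is configurable.

## Synthetic campaign generator

The generator emulates an open-air monitoring campaign and is first-class,
tested code. Its defaults are the study conditions for every property the
package asserts.

**Response model.** MOX transients are approximated as first-order: within
each heater stage the deviation from baseline relaxes exponentially toward
a plateau `amplitude(class, sensor) * (VH/7)²`, with separate rise
(8 s) and decay (15 s) time constants — the standard approximation for
heater-modulated MOX kinetics; the quadratic voltage term reflects heater
power. The channel value is `baseline × drift(day) + deviation + noise`
(baselines 0.8–1.2 V, Gaussian read noise sd 0.02 V).

**Class structure.** Ripe fruit emits more volatiles, so ripe amplitudes
exceed unripe ones sensor-wise (gap ≈ 0.15–0.2 V against a day-effect
multiplicative sd of 0.12). These defaults place linear-classifier
cross-validation accuracy in the 75–90 % band — separable but far from
ceiling, which is what open-air electronic-nose data looks like. Class
balance is exact; labels are temporally clustered (`label_time_correlation`
= 0.6): ripening is gradual, so the ripe class concentrates in the late
campaign. This clustering, together with the per-day amplitude effect
(drawn from a day-keyed RNG stream shared by all samples of a day), is the
mechanism that makes shuffled cross-validation optimistic relative to
block-wise splitting.

**Environment.** Temperature and humidity follow daily sinusoids
(18 ± 6 °C, 65 ± 15 %RH, antiphase, afternoon peak, per-day phase jitter)
clipped to the reference-grid hull. Responses of sensors 2–5 are distorted
through the true RS/R0 surface at the instantaneous conditions via the
divider equation (below); sensor 1 is left undistorted because no
reference surface exists for it — mirroring exactly what the correction
can and cannot undo. Drift is a multiplicative baseline factor, linear in
days (0.2 %/day) or a step at the batch boundary (day 12), since slow
drift and sensor repositioning between batches are not distinguishable
from the data; both are exposed.

**Image side.** No pixels are rendered; the vision model is represented by
its outputs. Each sample's scene holds one fruit of its class plus a
Poisson number of the other class; per-fruit detection probability,
confidence distribution and misclassification rate depend on the lighting
category (well-lit, backlit, artificial, night). Config validation
enforces that backlit ripe fruit is detected less often and less
confidently than well-lit ripe fruit. Night samples (default fraction 0.5)
have no image at all.

**What the generator does not emulate:** real MOX cross-sensitivity
spectra, second-order drift chemistry, detector failure modes beyond the
categorical lighting model, or any correlation between odour noise and
image noise (the two error processes are conditionally independent given
the label). Passing tests therefore demonstrate the correctness and the
qualitative mechanisms of the analysis chain, not field performance.

## Feature extraction

From each modulated trace: the per-sensor maximum and range of the 7 V
segment, plus the maximum of the EWMA-smoothed signal at
α ∈ {0.1, 0.01, 0.001} for all 5 sensors × 5 levels — 2·5 + 3·5·5 = 85
features (the *large* set), or the 10 7 V summaries alone (*small*). The
EWMA is the normalised weighted sum with weights (1−α)^(m−i), computed by
an O(M) recursion over the weighted numerator and denominator and verified
against the explicit sum to 1e−10; it is computed within each modulation
segment independently, with no carry-over across levels. Continuous
acquisitions are cut into 10-minute windows yielding mean, population
standard deviation, max, min and RMS per sensor (25 features). Population
rather than sample sd is an arbitrary documented constant choice.

Feature scaling is per-feature min-max with extrema learned on training
folds only and applied unchanged to test folds; test values are not
clipped to [0, 1], because between-batch distribution shift is part of
what the evaluation measures. Zero-range features map to 0 with a warning.
Environment readings can instead be appended as two extra features before
scaling (87 / 12 wide tables); samples lacking readings are excluded with
a warning.

## Environmental correction

Sensor resistance depends on ambient temperature and humidity through the
ratio RS/R0 relative to the reference condition (20 °C, 65 %RH). A
thin-plate-spline RBF surface interpolates reference (temp, RH, RS/R0)
triples exactly (no smoothing — every reference point is reproduced;
queries outside the convex hull extrapolate with a warning). The corrected
output voltage follows from the resistor-divider algebra with the sensor
resistance rescaled by 1/α:

    Ṽout = VC / ((VC/Vout − 1)·(1/α) + 1),   VC = 5 V.

α = 1 is the identity and the transformation is strictly increasing in
Vout. Correction applies to sensors 2–5 only; sensor 1 passes through.
Vendor datasheets publish RS/R0 only as curves, so the shipped per-sensor
reference grids are synthetic monotone surfaces (ratio decreasing in
temperature and humidity, 1 at the reference point), overridable from CSV;
module correctness rests on round-trip recovery against a known surface
(exact to 1e−9 V on traces, 1e−6 on features in the noise-free setting),
not on datasheet fidelity.

## Classifier suite and evaluation

Logistic regression, random forest, gradient-boosted trees, SVM and a
one-hidden-layer MLP are delegated to scikit-learn; the extreme learning
machine is implemented natively: a random sigmoid hidden layer (seeded
uniform(−1,1) weights, never trained) with output weights solved in closed
form by ridge-regularised least squares on ±1 targets, verified against an
independent `lstsq` solution to 1e−8. Confidence is the winning-class
probability where available, else the logistic of the decision margin
(SVM). Balanced class weights `n_total / (n_classes · n_c)` are applied
everywhere except the MLP (scikit-learn's implementation accepts no sample
weights — a known limitation). Hyperparameters are fixed documented
defaults; no per-run optimisation.

Three cross-validation schemes: label-stratified shuffled 10-fold;
leave-5-day-out, where unique days are sorted chronologically and
partitioned into *contiguous* 5-day blocks each held out once (randomised
blocks would defeat the temporal-confound logic); and stratified grouped
10-fold with 24-hour windows as groups for continuous data. Every
evaluation repeats over seeds (default 25, reduced in tests and scripts
for speed) with means and spreads reported. Metrics — accuracy, per-class
precision and recall, macro F1 (macro because the per-class definition is
the honest choice under imbalance), confusion matrix — are computed from
first principles and cross-checked against scikit-learn in tests;
zero-denominator ratios report 0 with a flag.

## Vision decision and fusion

Detections below the confidence threshold (default 0.8) are dropped;
greedy per-class non-maximum suppression (IoU threshold 0.5, descending
confidence, deterministic coordinate tie-break) merges overlaps; any
surviving ripe box labels the image ripe with the best ripe confidence,
otherwise unripe with confidence `max(1 − best filtered-out ripe
confidence, best surviving unripe confidence)` — 1.0 when nothing
ripe-like was proposed at any confidence. This negative-class confidence
is a documented convention (no standard definition exists) and is
configurable. Raising the threshold can never create a new ripe label.
Accuracy of the intermittently available image modality is reported both
over available samples and projected to all samples with missing images
counted as errors.

Late fusion: max-confidence takes the more confident modality's label,
falling back to odour when the image is unavailable (odour sensing works
at night) and on exact ties; majority voting over ≥3 voters drops
unavailable voters, degrades to max-confidence below three, and breaks
even splits by the most confident voter. The odour fallback is what lets
fused all-sample accuracy exceed both unimodal all-sample accuracies when
half the images are missing. The agreement analysis selects samples where
the image produced a prediction and both labels match; with roughly
independent error processes at accuracies a, b > 0.5 the agreed subset
concentrates at accuracy ≈ ab/(ab + (1−a)(1−b)), well above either
modality — the basis for using agreed samples as pseudolabels.

## Problem sizes and numerical conventions

Default test/script problem sizes are chosen for desk-scale runs: 40–50
samples per class over 20–25 days for CV studies, 10 seeded replicates for
the optimism ordering, n = 1000–5000 for fusion Monte-Carlo, 500 samples
for the permuted-label null. Zero-range min-max maps to zeros, not NaN.
All randomness flows from explicit integer seeds through numpy Generators
(per-sample and day-keyed streams derive from the campaign seed), so any
reported number is reproducible from its manifest.

## Known limitations

- The MLP is the one suite member without class weighting.
- Deep sequence models (1D-CNN/LSTM) are out of scope; the conditioning
  chain for them (split → downsample → baseline-subtract → min-max) is
  implemented and tested, and any external model can be fused through the
  shared Prediction interface.
- The shipped RS/R0 grids are synthetic stand-ins, not datasheet data.
- Detector training and mAP evaluation are out of scope; the image model
  enters only through its detection outputs.
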