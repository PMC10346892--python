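# Methods

## Problem and model

`gaitann` classifies seven locomotion/posture activities (sitting, standing,
level walking, ramp ascent/descent, stair ascent/descent) from 19 lower-limb
wearable-sensor channels sampled at 500 Hz: waist accelerometer x/y and
gyroscope x; accelerometer x/z and gyroscope y on each thigh and shank; and
knee/ankle goniometer angles on both sides. The design goal is a classifier
light enough for embedded, real-time use: handcrafted time-domain features
feed a single-hidden-layer network instead of a deep feature extractor.

The pipeline is:

1. **Transition removal.** The per-sample label stream is split into maximal
   single-activity runs; 250 samples (0.5 s) are deleted from each side of
   every label change, because ground truth near a transition is unreliable.
   The split is symmetric; runs left shorter than one window are dropped.
2. **Five-pass segmentation.** Each run is tiled with non-overlapping
   25-sample windows (0.05 s), restarting the tiling at offsets
   0, 5, 10, 15, 20. The union of the five passes equals a stride-5 sliding
   window; incomplete trailing windows are discarded.
3. **Nine features per window per channel:** mean, median, population
   standard deviation, min, max, initial value, final value, mean absolute
   deviation about the window mean (MAV) and waveform length (WL, the sum of
   absolute first differences). The median is the sorted median
   (`median_mode="sorted"`); a strict raw-center-sample variant is available
   (`median_mode="center"`). Min/max are values, not indices. The standard
   deviation divides by W, not W−1.
4. **Context stacking.** Feature rows of 3 consecutive windows *of the same
   circuit, activity run and segmentation pass* are concatenated oldest
   first and labeled by the newest window, giving the feed-forward network a
   0.15 s memory. Width: 3 × 9 × 19 = 513.
5. **Scaling and balancing.** Columns are z-scored with statistics fitted on
   the training split only (zero-variance columns are centered with scale 1).
   The training split is then downsampled so all seven classes match the
   smallest class count; evaluation splits stay unbalanced so reported
   accuracy reflects the natural label mix (`balance_eval=True` balances them
   too).

**Network.** 513 inputs → 100 tanh hidden units → 7 *independent* sigmoid
outputs (one-vs-rest, not softmax; prediction is the argmax, ties to the
lowest class index). Cost is the summed binary cross-entropy normalized by
N plus an L2 penalty λ/(2N)·Σw² over non-bias weights, with λ = 2 by
default. Predictions are clipped to [1e−12, 1−1e−12] before the logarithms.

**Trainer.** Full-batch Polack–Ribière nonlinear conjugate gradients with a
Wolfe-condition line search in the style of the classical `fmincg`/
`minimize` routine: quadratic/cubic interpolation inside the bracket, cubic
extrapolation outside it (limits: interpolation guard 0.1, extrapolation ×3,
at most 20 cost evaluations per search, slope-ratio cap 100), sufficient
decrease c₁ = 0.01 and strong curvature c₂ = 0.5. A failed line search
restarts along steepest descent; two consecutive failures terminate. The
accepted-iteration cost sequence is non-increasing by construction and the
best-seen parameters are returned. Training is bitwise deterministic given
data, seed and configuration. The nominal budget is 1000 full-batch
iterations ("epochs"); the synthetic task converges far earlier, so the
experiment drivers here use 50.

**Evaluation.** Leave-one-subject-out: one fold per subject, whose circuits
are all held out for testing (4 drawn per fold); each remaining subject
contributes 8 training and 2 validation circuits (seeded draws). With the
default 8 × 10 study each fold is 56/14/4 circuits. Reported metrics are the
confusion matrix in fixed activity order, accuracy, and one-vs-rest per-class
F1 = TP/(TP + (FP+FN)/2); a class absent from truth and predictions scores 0
with a degenerate flag, keeping macro averages conservative. Fold metrics
are averaged unweighted. Per-row preprocessing and inference wall times are
reported for information only — they are machine-dependent and never
asserted against reference values.

## Synthetic data generator

Real benchmark recordings are an optional input; the shipped generator
produces circuits with the statistical structure the classifier relies on,
so the whole pipeline is testable offline. Each circuit concatenates one
labeled segment per element of the fixed activity sequence (even circuits:
sit, stand, walk, ramp ascent, walk, stair descent, walk, stand, sit; odd
circuits the stair-ascent/ramp-descent variant), with segment durations
drawn uniformly from 4–10 s.

Per (activity, channel) the signal is

    offset + subject_shift + a·sin(2πft + φ) + r·a·sin(4πft + 2φ) + ε,

with amplitude `a` and gait frequency `f` scaled per subject, phase φ drawn
independently per (segment, channel), harmonic ratio `r`, and Gaussian noise
ε. Defaults ship in `gaitann/data/activity_profiles.csv` (accelerometers in
m/s², gyroscopes in deg/s, goniometers in deg). Sitting and standing are
aperiodic (f = 0) with distinct baselines. Parameter choices encode the
separations a practitioner would expect: cadence falls from walking
(0.95 Hz) to stairs (0.55–0.65 Hz); forward/axial accelerometer baselines
shift with segment tilt on ramps and stairs by more than the within-stride
oscillation amplitude, so posture channels separate the dynamic classes;
goniometer baselines for walking vs. ramps differ by less than their stride
amplitude, so joint angles alone are genuinely ambiguous — this is what
makes the goniometer-only ablation underperform the full channel set.

Subject variability: log-normal amplitude and cadence scales (log-sd 0.20
and 0.10) and an additive per-channel baseline shift, Gaussian with sd =
0.35 × a channel scale (the dispersion of that channel's per-activity
baselines, floored at 0.15 × its largest amplitude). These spreads are the
"moderate" study condition: seen-subject validation stays high while
held-out-subject accuracy drops by a few points, reproducing the
seen-vs-unseen gap qualitatively. Setting the spreads to zero makes classes
a near-deterministic function of the features (the pipeline then reaches
≥99% seen-subject accuracy), and widening them degrades unseen-subject
accuracy monotonically — both are tested.

What the generator does **not** emulate: biomechanical coupling between
channels (phases are independent, real gait is phase-locked across joints),
transitional kinematics between activities (segments switch abruptly; the
preprocessor removes boundaries anyway), within-segment cadence drift, and
sensor artifacts (drift, saturation, dropout). Passing tests therefore show
the pipeline's correctness and its qualitative behaviour under subject
variation, not field performance on real recordings.

## Numerical and design choices

- Windows are 0-based half-open `[start, start+W)`; window starts within a
  pass are `o, o+W, o+2W, …`.
- Scaler scale floor 1e−12 (constant columns pass through centered).
- Balancing, fold draws and weight initialization all derive their RNG
  streams from the experiment seed, never from data content, so permuting a
  held-out subject's data cannot change the trained weights (tested
  bitwise).
- Weight init: uniform in ±√(6/(fan_in+fan_out)) per layer, seeded;
  an explicit `init_scale` overrides both layers.
- Line-search guards: non-finite costs are treated as Armijo failures so the
  search shrinks the step; negative discriminants in the cubic fits fall
  back to bisection-style steps.
- Circuit files round-trip float64 exactly (`%.17g` on write,
  `float_precision="round_trip"` on read).
- Experiment problem sizes: the default synthetic study (8 subjects × 10
  circuits) yields ≈430k feature windows; the experiment drivers compute
  features and context stacking once per circuit and reuse them across all
  folds, and fold scaler statistics are aggregated from per-circuit moments
  so the unbalanced training matrix is never materialized. Smaller studies
  (2–4 subjects, shorter segments) are used in unit tests where the full
  scale adds nothing.

## Known limitations

- The generator's independence assumptions (phase, noise, subject shifts)
  make the synthetic task easier than real recordings at equal nominal
  noise; absolute accuracies here do not transfer to real data.
- Only downsampling is offered for class balance; no class weighting.
- The trainer is full-batch by design (that is the method); it does not
  scale to datasets that exceed memory.
- Inference timing is a wall-clock measurement of a single-row path and
  varies with BLAS, CPU and load.
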