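# Methods

`gaitmood` implements a complete digital-phenotyping pipeline that asks
whether questionnaire-measured anxiety (GAD-7, 0–21) and depression
(PHQ-9, 0–27) severity can be recognized from depth-camera skeleton
recordings of natural walking.  This note documents the models, the
numerical choices, and what the synthetic validation does and does not
establish.

## Processing model

**Input.** Per subject: a walk of about two minutes along a straight
footpath, back and forth, recorded as 25 Kinect-v2 joints × 3 camera-space
coordinates (X lateral, Y vertical, Z distance, meters) at 30 Hz, plus the
subject's GAD-7 total and PHQ-9 total with its nine item scores.

**Denoising.** Each joint-axis series is smoothed with a width-5
sliding-window Gaussian filter, kernel c = [1, 4, 6, 4, 1]/16:

    Out[i] = (In[i] + 4·In[i+1] + 6·In[i+2] + 4·In[i+3] + In[i+4]) / 16.

The formula is implemented literally as written — a causal window whose
output is 4 samples shorter than its input — rather than re-centered.  The
induced 2-frame lag is irrelevant to FFT amplitude moduli, and keeping the
printed index alignment makes the unit-impulse and ramp oracles exact.
A smoothed frame is marked invalid if *any* of the five frames under its
window was invalid, since its value mixes in unusable coordinates; its
facing flag comes from the window's center frame.  Filtering runs on the
full per-axis series before segmentation so segment boundaries see no
filter edge effects.

**Re-centering.** Every frame is re-expressed with the SpineBase (pelvic
root) joint as origin and SpineBase dropped, leaving 24 joints.  This
removes the walker's absolute position relative to the camera.  Smoothing
and re-centering are both linear, so their order is immaterial (verified
to 1e-9 relative tolerance in the tests); the pipeline denoises first.

An important consequence: re-centering removes whole-body translation, so
*walking speed itself leaves no trace in the features* — severity signal
must be carried by within-body kinematics (cadence, arm swing, stride
amplitude, head height, lateral sway).  The synthetic effect model still
modulates speed, but recovery rests on the other parameters.

**Segmentation.** Only frames in which the walker faces the camera are
usable (joint tracking degrades from behind).  When the recording carries
a facing annotation it is used directly; otherwise facing is inferred from
the sign of the smoothed SpineBase Z-velocity (approaching = front), with
runs shorter than 15 frames (0.5 s) relabelled as turning.  Maximal
valid front-facing runs are tiled into non-overlapping 64-frame windows
anchored at each run start; one window per subject is drawn uniformly at
random.  64 frames ≈ 2.1 s covers at least one gait cycle at normal
cadence and is a power of two, as the FFT requires.  A subject with no
candidate window is excluded (logged, never fatal).

**Features.** For each retained joint and axis the unscaled DFT
X_k = Σ_n x_n·e^(−i2πkn/64) is evaluated and all 64 amplitudes |X_k| kept,
giving 24 × 3 × 64 = 4608 columns.  All 64 bins are retained — including
the mirror half redundant for real signals — keeping the feature count
literal; the duplication is harmless to correlation ranking.  Columns are
z-scored across subjects using the population (divide-by-n) SD; the
convention is recorded because the choice is otherwise arbitrary, and all
downstream Pearson correlations are invariant to it.  Zero-variance
columns become zeros rather than NaN.

**Selection.** Per (joint, axis) group the 5 of 64 columns with the
largest |Pearson r| against the target score are kept: 5 × 3 × 24 = 360
features.  Ties at the fifth rank break toward the lower frequency index,
for determinism.  Zero-variance columns get r = 0.

Selection fitted on the full sample *before* cross-validation leaks target
information into the evaluation.  Both orders are implemented: the
as-published full-sample order, and a nested mode that re-runs selection
inside every training fold.  All synthetic validation in this package uses
the nested (honest) mode; the leaky order exists for fidelity and is
clearly flagged.  Z-scoring is global in both modes — it is a monotone
per-column rescaling whose leakage is negligible next to selection's.

**Models and evaluation.** 10-fold cross-validation with seeded shuffling;
accuracy for regression is the single Pearson r between pooled out-of-fold
predictions and observed scores (per-fold averaging is available as an
option).  Regression models: SLR (one-variable least squares on the single
feature with minimal training SSE), LR (least squares with a 1e-8 ridge
term so the n < p selected matrix stays solvable), epsilon-SVR and nu-SVR
(RBF kernel, C = 1, ε = 0.1 / ν = 0.5), and GP (RBF kernel plus white
noise, hyperparameters by marginal-likelihood optimization, y normalized).
These defaults stand in for WEKA-style learners whose hyperparameters the
underlying study design leaves unstated; all are recorded in code and
sweepable.  Classification per PHQ-9 item splits subjects into
non-symptomatic (item = 0) and symptomatic (1–3); folds are
class-stratified; precision, recall and F-measure of the symptomatic class
come from pooled confusion counts.  K-Star's entropic distance is not
re-implemented: a clearly-labelled surrogate (inverse-distance-weighted
5-NN) takes its slot.  A stratum in which either class has fewer members
than folds raises a "too few cases" signal that the study table renders as
"no valid results" — the suicidality item's typical fate.  Gender-
stratified analyses re-run feature selection within the stratum.

Significance stars on r use the standard t transform at pooled n.  A
one-sided permutation p-value for CV accuracy permutes the pairing of
pooled predictions and scores (10⁴ draws); this tests independence without
re-fitting and is the recovery criterion below.

## Synthetic cohort

The generator stands in for human recordings so every stage is testable.
It emulates the documented movement correlates of low mood — slower walk,
reduced arm swing, reduced vertical head movement, larger lateral sway —
without claiming biomechanical fidelity.

A latent severity s ~ Gamma(shape 1.5, mean 5) (right-skewed: most
subjects in the healthy range) drives everything.  PHQ-9 item scores are
min(3, Poisson(w_k·s)) with item propensities w_k fixed so that anhedonia
and low energy are commonly endorsed and suicidality is rare (~2%
nonzero); the PHQ-9 total is the item sum by construction.  GAD-7 is a
noisy rescaling of s clipped to [0, 21].  Gender is Bernoulli(100/179),
age ~ N(24.2, 1.5) — a graduate-student-like sample.

Gait parameters are baseline + slope × PHQ-9 total + N(0, jitter), clipped
to physical bounds.  Baselines: cadence 1.85 steps/s, stride amplitude
0.25 m, arm swing 0.12 m, head height 0.66 m above SpineBase, lateral sway
0.025 m, speed 1.10 m/s, coordinate noise SD 5 mm (typical depth-camera
jitter).  The full-strength ("strong") slopes with the default jitters
yield severity–cadence and severity–arm-swing correlations near −0.6;
"weak" halves the slopes (r ≈ −0.35) and "none" zeroes them.  No
quantitative human effect sizes exist for this mapping, so these scales
are stated study conditions of the synthetic validation, not estimates of
the true human effect.

Kinematics: a rigid 25-joint template; arms and legs swing sinusoidally at
the cadence as rigid rotations about shoulder/hip (arms antiphase to the
ipsilateral leg), so bone lengths are exactly constant at zero noise.  The
upper body bobs vertically at twice the cadence (amplitude 8% of stride)
and sways laterally at half of it.  The torso translates along Z over a
5 m walkable span, turning in 0.5 s at each end; turning frames are
invalid with unknown facing, and the skeleton rotates 180° for the return
pass.  Each subject gets a random gait phase; every draw is reproducible
from a single integer seed (per-subject seeds spawn from a SeedSequence).

What the generator does **not** emulate: tracking occlusion and outlier
artifacts beyond frame-validity flags, double-support timing, stride
variability, asymmetry, posture (slump appears only as reduced head
height), fatigue drift, and any camera-physics noise structure.  Passing
the validation below therefore shows the *pipeline* is correct and
calibrated — that it recovers effects of the stated form and invents none
under the null — not that human anxiety or depression is detectable at any
particular accuracy.  The published human-sample accuracies (r ≈ 0.5
overall, up to 0.74 in women) require the original recordings and are
treated as context.

## Validation design

* **Oracle equivalence** — the filter against direct convolution, the FFT
  amplitudes against a naive O(N²) DFT sum (1e-9 relative), the feature
  ranking against exhaustive per-group sorting.
* **Null calibration** — 100 zero-effect cohorts of n = 180: mean CV r
  (LR, nested selection) within 3 SE of 0.  Pooled CV r is only
  null-centered when predictions carry variance; a near-mean predictor
  anti-tracks fold composition and biases r negative (a documented CV
  artifact), which the high-dimensional selected feature set avoids.
* **Parameter recovery** — one strong-effect cohort of n = 180: GP CV
  r > 0 at permutation p < 0.01; and mean CV r strictly increasing across
  effect scales {none, weak, strong} (20 replicates each at n = 120).
* **Determinism** — two runs of the full file-based pipeline from one
  config produce byte-identical manifests (recordings are written with
  %.17g floats, which round-trip float64 exactly).

Problem sizes (100/20 replicates, n = 120–180, LR for replicated
experiments and GP for the single recovery run) were chosen to keep the
whole validation in the tens of minutes on one core while leaving the
statistical margins wide; they are part of the stated study conditions.

## Known limitations

* The two cameras of the original apparatus are modelled as one usable
  stream; no cross-camera fusion is attempted.
* The raw-record ambiguity (accelerations vs positions) is resolved as
  positions, the only reading consistent with re-centering at SpineBase.
* The K-Star surrogate is a different learner; its numbers are not
  comparable to entropic K-Star beyond order of magnitude.
* Whether smoothing preceded or followed the facing split in the original
  procedure is unstated; this pipeline smooths first (and marks windows
  touching invalid frames invalid), which the commutativity of the linear
  stages makes immaterial for the features.
* CV folds are a seeded shuffle; regression folds are unstratified, so
  fold-to-fold target imbalance contributes variance at small n.
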