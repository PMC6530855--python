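# gaitmood

Recognizing anxiety and depression severity from skeleton-tracked gait.

Self-report questionnaires such as the GAD-7 (anxiety, 0–21) and PHQ-9
(depression, 0–27) are the workhorses of mental-health screening, but they
cannot be administered continuously.  Natural gait, recorded contactlessly
by a depth camera (Kinect v2: 25 named skeleton joints at 30 Hz), carries
known correlates of low mood — slower walk, reduced arm swing, reduced
vertical head movement, larger lateral sway.  `gaitmood` implements the
full low-level-feature pipeline that turns such recordings into severity
estimates, for researchers in digital phenotyping and movement analysis:

1. **Denoise** each joint-axis series with a width-5 sliding Gaussian
   filter, kernel [1, 4, 6, 4, 1]/16;
2. **Re-center** every frame on the SpineBase joint (24 joints remain);
3. **Segment**: keep camera-facing runs, tile them into contiguous
   64-frame (~2 s) windows, draw one window per subject;
4. **Features**: unscaled DFT amplitudes |X_k|, k = 0…63, per joint axis
   → 24 × 3 × 64 = 4608 columns, z-scored across subjects;
5. **Select** the 5 columns with largest |Pearson r| against the target
   per (joint, axis) → 5 × 3 × 24 = 360 features;
6. **Evaluate** with 10-fold cross-validation: regression of the
   questionnaire totals (SLR, LR, ε-SVR, ν-SVR, Gaussian process; accuracy
   = Pearson r between pooled out-of-fold predictions and observed
   scores), and per-PHQ-9-item classification of symptomatic (item 1–3)
   vs non-symptomatic (0) subjects (logistic, a K-Star surrogate, C-SVC;
   precision / recall / F of the symptomatic class).

Because full-sample feature selection leaks the target into the
evaluation, a *nested* mode re-runs selection inside every training fold;
all calibration and recovery results below use it.

A first-class synthetic cohort generator emulates the study design (2-min
back-and-forth walks with turning structure, right-skewed questionnaire
scores, a latent severity that modulates gait parameters with configurable
effect size), so the whole pipeline is testable without human recordings.
See `docs/methods.md` for the model, parameter defaults, and what the
synthetic validation does and does not establish.

## Worked example

```python
import gaitmood as gm
from gaitmood.features import make_selector
from gaitmood.modeling import CVConfig, cross_validate_regression, permutation_pvalue

# 180 subjects whose severity modulates gait at full strength
# (severity-cadence / arm-swing correlations ~ -0.6)
subjects, features, excluded = gm.build_cohort_features(
    gm.effect_model("strong"), n=180, rng_seed=7,
)
y = subjects["phq9"].astype(float).to_numpy()
res = cross_validate_regression(
    features, y, "GP",
    CVConfig(rng_seed=3, nested_selection=True),
    selector=make_selector(),
)
p = permutation_pvalue(res.predictions, res.targets, rng_seed=1)
print(f"GP 10-fold CV r = {res.pearson_r:.3f}  (n = {res.n}, permutation p = {p:.1e})")
```

Output:

```
GP 10-fold CV r = 0.800  (n = 180, permutation p = 1.0e-04)
```

The Gaussian-process model recovers the injected severity–gait coupling:
pooled out-of-fold predictions correlate 0.80 with the PHQ-9 scores, far
beyond chance (no permutation of the score pairing reached the observed
r in 10⁴ draws).  With zero injected effect the same pipeline is
calibrated: its CV r averages 0.00 across 100 replicate cohorts.

The same study can be run end to end from the shell, writing recordings,
segments, features, report tables and a checksummed manifest:

```sh
gaitmood simulate --n 60 --seed 1 --effect-size strong --out demo
gaitmood validate demo
gaitmood preprocess --in demo --out demo --seed 1
gaitmood evaluate --run-dir demo --seed 1 --nested-selection
# or, equivalently, one config file (see examples/run.yaml):
gaitmood run --config examples/run.yaml
```

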