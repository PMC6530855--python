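# A complete study run: simulate a 60-subject strong-effect cohort,
# preprocess, extract features and evaluate every model on all strata.
seed: 1
n_subjects: 60
effect_size: strong      # none | weak | strong | numeric scale
duration_s: 120.0
fs_hz: 30.0
use_facing_metadata: true
nested_selection: true   # honest per-fold feature selection
n_folds: 10
regression_models: [SLR, LR, eSVR, nSVR, GP]
classification_models: [SL, KStarSurrogate, CSVC]
strata: [all, male, female]
out_dir: gaitmood_run
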