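# gaitfall

Fall-risk gait analysis for older adults, end to end: synthetic shoe-mounted
IMU walking signals with planted ground-truth events, Butterworth filtering
and heel-strike/toe-off detection, spatiotemporal gait variables (walking
speed, stride length, cadence, stance phase, stride time, three
stride-to-stride CVs, gait asymmetry), questionnaire-based risk labelling,
per-walking-speed gradient-boosted tree classification, and a full
evaluation panel (ROC/AUC, sensitivity/specificity, PPV/NPV, likelihood
ratios, confidence intervals, feature-importance ranking, group
descriptives).

No real cohort is required: the `synthetic` module generates (a) raw
per-foot IMU traces whose anteroposterior-axis maxima mark heel strikes and
vertical-axis maxima mark toe-offs at known sample indices, and (b) cohort
feature tables drawn from group-specific (high- vs low-risk) distributions,
with fall-questionnaire answers consistent with the stored label.

## Command-line interface

```bash
# raw-signal path
gaitfall simulate-signals --out walk/ --seed 1
gaitfall detect-events --in walk/ --out events.csv --cutoff 10 --order 2 --trim 2
gaitfall extract-features --events events.csv --height 1.6 --distance 20 --out features.csv

# cohort path
gaitfall simulate-cohort --out cohort.csv --seed 1
gaitfall label --in cohort.csv --out labelled.csv          # optional --rule rule.yaml
gaitfall train --in labelled.csv --speed preferred --out model.json --seed 1
gaitfall evaluate --model model.json --test labelled.csv --out report.json

# full protocol: synthetic cohort -> three per-speed models -> reports + manifest
gaitfall run --out results_dir --seed 1
```

File layouts (IMU CSV + JSON sidecar, events CSV, cohort CSV columns) are
documented in `gaitfall/io.py` and `gaitfall/synthetic.py`.

## Protocol

Each walking speed (slower / preferred / faster) gets its own model over 14
predictors: the nine gait variables at that speed plus age, sex, BMI,
education level, and physical activity.  Features are min–max scaled on the
training split; the cohort is split 70/30 stratified by label; 10-fold
cross-validation on the training split selects hyperparameters; headline
metrics are computed on the 30% holdout at a 0.5 probability threshold.
Confidence intervals: Wilson (proportions), DeLong (AUC), log-method
(likelihood ratios).

The default synthetic cohort draws features independently per group (the
real data are correlated), which makes classification easier than reality —
published metric values therefore act as lower bounds that the synthetic
benchmark is expected to meet or exceed.

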