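# suitas

Multivariate predictive modeling of the subjective experience of threat
anticipation under uncertainty, for fMRI researchers building and
evaluating whole-brain "neural signatures" of self-reported emotional
state.

In the paradigm this package models, participants anticipate possible
electric shocks under cues signaling certain safety or low / medium /
high uncertainty, and rate their anxious arousal from 1 to 5 after every
trial.  A *signature* is a voxel weight map **w** (plus intercept *b*)
over a gray-matter mask: its response to an activation map **x** (the
per-trial or per-rating GLM beta vector) is the dot product

    ŷ = wᵀx + b

interpreted as the predicted rating.  The weights are fit with a linear
ε-insensitive support vector regression (C = 1, ε = 0.1) on per-rating
beta maps pooled across participants, and evaluated with
participant-grouped 10 × 10-fold cross-validation (all maps of a
participant stay in one fold, so no model is scored on a participant it
saw).  Around that core the package provides:

* **`suitas.images`** — NIfTI volume/mask I/O and the frozen
  mask-vectorization contract shared by all stages.
* **`suitas.simulate`** — a synthetic-cohort generator with a known
  multivariate ground truth (distributed blob patterns, an
  arousal-like confound correlated with ratings, a condition-cue
  pattern, smooth Gaussian noise, optional HRF-convolved BOLD), so every
  downstream claim can be scored against the generating truth.
* **`suitas.glm`** — double-gamma HRF, per-rating / per-trial design
  matrices (24-parameter motion set, FD spike regressors, DCT drifts,
  run intercepts), voxelwise OLS.
* **`suitas.signature`** — SVR training, grouped cross-validation,
  prediction–outcome correlation, explained variance score (EVS),
  Fisher-z-averaged within-participant correlations, within-individual
  (single-trial) models.
* **`suitas.inference`** — permutation tests for r and for Δr between
  two predictions, participant-resampling bootstrap of the weight map,
  two-alternative forced choice (high 4/5 vs low 1/2 maps) with exact
  binomial p and Cohen's d, Benjamini–Hochberg FDR, voxelwise group
  t-maps.
* **`suitas.encoding`** — structure-coefficient (forward-model)
  transformation A_v = cov(x_v, ŷ)/Var(ŷ) and the positive conjunction
  "core system" across within-individual weight and encoding maps.
* **`suitas.similarity`** — cross-application of signatures to foreign
  datasets, spatial weight-map correlations (unthresholded or
  bootstrap-thresholded), ROI cosine-similarity profiles with
  contribution fractions.
* **`suitas.subsystems`** — ROI-restricted retraining and random
  voxel-subsampling performance curves, the "is any single system
  sufficient?" analyses.
* **`suitas` CLI** — `simulate`, `glm`, `train`, `apply`, `bootstrap`,
  `encode`, `core`, `compare`, `subsample`, and `run` (an end-to-end
  pipeline with JSON manifests and content-hash checks).

## Worked example

Train and evaluate a signature on a synthetic cohort of 30 participants
(4 runs × 20 trials each, ~44 no-shock trials per participant):

```python
import numpy as np
from suitas import simulate
from suitas.signature import CVScheme, cross_validate, stack_maps, train
from suitas.inference import forced_choice

spec = simulate.SyntheticSpec(seed=1)               # the default cohort
series, truth, mask = simulate.simulate_cohort(spec)
maps = [m for bs in series for m in simulate.aggregate_by_rating(bs)]
X, ratings, participants = stack_maps(maps)          # 149 maps x 1872 voxels

cv = cross_validate(X, ratings, participants,
                    CVScheme(n_folds=10, n_repeats=10, seed=1))
model = train(X, ratings, mask=mask)
cosine = model.weights @ truth.anxiety_pattern.values / np.linalg.norm(model.weights)
fc = forced_choice(model, X, ratings, participants)

print(f"CV r = {cv.overall_r:.2f}, EVS = {100 * cv.evs:.0f}%")
print(f"within-participant r = {cv.within_mean_r:.2f} ± {cv.within_mean_se:.2f}")
print(f"forced-choice accuracy = {100 * fc.accuracy:.0f}%, d = {fc.cohens_d:.2f}")
print(f"cosine(weights, generating pattern) = {cosine:.2f}")
```

```
CV r = 0.95, EVS = 86%
within-participant r = 0.99 ± 0.00
forced-choice accuracy = 100%, d = 24.29
cosine(weights, generating pattern) = 0.77
```

`CV r` is the Pearson correlation between cross-validated predicted and
actual ratings across all maps; `EVS` the explained variance score
1 − MSE/Var(actual); the within-participant r is averaged on the
Fisher-z scale; the forced choice compares each participant's averaged
high (4/5) against low (1/2) rating map; and the cosine measures how
well the trained weight direction recovers the generating "anxiety"
pattern.  The synthetic default cohort is deliberately an easier,
recovery-testable regime than real fMRI cohorts — see `docs/methods.md`
for what these numbers do and do not show.

The same pipeline from the shell:

```bash
suitas run --config config.yaml --out runs/demo
```

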