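# Methods

## The model

The package implements a population-level decoding model of subjective
anxious arousal during uncertain threat anticipation.  Per-rating (or
per-trial) GLM beta maps, vectorized over a binary analysis mask in a
frozen voxel order (ascending linear index, last axis fastest), are the
features; the 1–5 self-reported rating is the target.  The decoder is a
linear ε-insensitive support vector regression with C = 1 and ε = 0.1 —
hyperparameters fixed, no grid search — and its application to a new map
is always the plain dot product wᵀx + b, also after optional z-score
feature scaling (the scaling is estimated on training maps only and
folded into the weights and intercept).  The underlying QP is solved by
scikit-learn's libsvm backend; a finite iteration cap
(`TrainConfig.max_iter`, default 5·10⁶) guards against SMO cycling at
very small tolerances, and the test suite verifies the solver against an
independent KKT-enumeration solution of the dual on small problems.

Evaluation follows the decoding-literature conventions:

* **prediction–outcome correlation** — Pearson r between predicted and
  actual ratings, across all maps and within each participant;
  within-participant values are averaged on the Fisher-z scale
  (r clipped to ±(1 − 10⁻¹²)) and back-transformed, with a
  participant-resampling bootstrap SE;
* **explained variance score** — EVS = 1 − mean((y − ŷ)²)/Var(y).  This
  is the uncentered (coefficient-of-determination) form: a constant
  prediction scores 0 and a constant offset is penalized.  It can be
  negative for poor predictors;
* **cross-validation** — repeated participant-grouped k-fold
  (10 × 10 by default): participants are partitioned into folds fresh in
  each repeat, every map is predicted only by models that never saw its
  participant (asserted, not assumed), and per-map predictions are
  averaged across repeats before computing metrics.  How the original
  analyses pooled predictions over repeats is not public; averaging is
  this package's documented choice;
* **forced choice** — per participant, the averaged rating-4/5 map
  against the averaged rating-1/2 map; correct iff the high response
  exceeds the low response, ties scored ½; two-sided exact binomial p
  against chance and Cohen's d = mean/sd of the paired response
  differences.

## Inference

All resampling p-values use the add-one convention
p = (1 + #extreme)/(1 + n), so p is never exactly 0, and every routine
takes an explicit seed.

* **Permutation test for r** — ratings shuffled against fixed-model
  responses (or labels shuffled before refitting in CV mode), one-sided
  by default, 5000 shuffles at full scale.
* **Permutation test for Δr** — the difference of two
  prediction–outcome correlations on row-matched sets.  The null swaps,
  per matched row independently with probability ½, the
  (response, target) pair between the two sets and recomputes Δr.  This
  scheme is this package's documented interpretation (it is
  antisymmetric in the two sets, yields p ≈ 1 for identical sets, and is
  exchangeable under equal performance); the original test is named but
  not specified in the source literature.  Unequal-length sets are
  paired by random subsampling to the common length.
* **Bootstrap weight map** — participants resampled with replacement
  (keeping all their maps), the signature retrained per replicate;
  z = mean/sd per voxel with a two-sided normal-approximation p.
  Replicates whose resampled ratings collapse to one value are redrawn
  so the replicate count stays fixed.  Threshold masks at p < 0.001 and
  p < 0.01 reproduce the display convention of bootstrap-thresholded
  signature maps.
* **Group maps** — voxelwise one-sample t-tests (one- or two-sided) with
  zero-variance voxels flagged and given limit p-values;
  Benjamini–Hochberg step-up FDR for thresholding.

## Encoding maps and the core system

Decoder weights are backward-model quantities; the forward
(activation) pattern a decoder tracks is reconstructed per participant
as the structure coefficients A = cov(X)·W / Var(WᵀX), equivalently
A_v = cov(x_v, ŷ)/Var(ŷ), with trial-centered columns and unbiased
(n − 1) covariances.  W is normalized to unit Euclidean norm inside the
transform: the latent ŷ is defined only up to scale, and fixing ‖W‖ = 1
makes A exactly invariant to positive rescaling of the weights (the raw
formula scales as 1/k under W → kW; the direction is unchanged either
way).  The *core system* is the conjunction of one-sided group t-tests
(BH-FDR q < 0.05) over the per-participant weight maps AND their
encoding maps, keeping voxels with positive group means in both; a
signed variant returns the mirrored negative conjunction.  Centering is
per concatenated session (the per-run option is not implemented; the
source procedure does not state it).

## Similarity and subsystem analyses

Cross-application of a signature to a foreign dataset uses the same
dot-product responses and metrics and feeds the Δr test for specificity
claims.  Spatial similarity between weight maps is Pearson r over
in-mask voxels; when thresholded, over the union of each map's
bootstrap-surviving voxels with values zeroed outside their own
surviving set (union vs intersection being unstated in the source, the
union is the package's choice).  The permutation p shuffles one map's
voxel values without preserving smoothness — a known limitation that
anticonservatively narrows the null for smooth maps.  ROI profiles use
cosine similarity between the positively thresholded weight vector and
the ROI indicator; ribbons are normalized by the report-wide maximum
cosine, and per-ROI contributions assign each in-ROI voxel to the model
with the largest absolute thresholded weight (ties split evenly) — a
documented reading of an ambiguous "relative contribution" quantity,
chosen because it is symmetric and sums to 1 per ROI.

Subsystem analyses retrain the signature restricted to ROI voxels under
the identical CV scheme, and build performance-versus-feature-count
curves from uniform random voxel subsets (without replacement within a
repetition, independent across repetitions) of a source mask, which
equates feature counts when comparing whole-brain against single-system
models.

## The synthetic-data generator

`simulate.SyntheticSpec` encodes the anticipation paradigm: 4 cue
conditions (safety, low, medium, high uncertainty), 5 valid trials per
condition per run, 4 runs, cue durations 6–10 s (8 s for the
low-uncertainty cue), shock probability 0.6 for each uncertain condition
and 0 under safety, retrospective 1–5 ratings.  Ratings are Gaussian
around nondecreasing condition means (1.2, 2.4, 3.3, 4.3; sd 0.8),
rounded and clipped — reproducing the partial coverage of the rating
scale (3–5 observed levels per participant) and ≈ 44 no-shock trials
per participant.  A trial's beta vector is

    β_t = A·g_s·rating_t·p_anx + c_amp·c_t·p_arousal + v_amp·v_t·p_cue + ε_t

with unit-norm multi-blob patterns (Gaussian bumps truncated at the blob
radius, disjoint supports), a participant gain g_s ~ log-normal(0, σ_g),
an autonomic-arousal-like covariate c_t sharing a latent Gaussian with
the rating (correlation 0.5), a standardized condition-cue covariate
v_t, and spatially smooth Gaussian noise whose per-voxel sd is
calibrated exactly via the L2 norm of the discrete smoothing kernel.
Two optional regional-coding knobs (both default 0) let each blob encode
a noisy, participant-idiosyncratic copy of the rating: per-trial
per-region jitter (`regional_noise_sd`, rating units) and per-participant
per-region log-normal gain (`regional_gain_sigma`).  They exist because
with purely shared coding a single region carrying a third of the signal
is nearly as predictive as the whole pattern — the distributed-coding
regime that subsystem analyses probe has to be a property of the
generative model, not an accident of noise.

An optional BOLD-level generator convolves trial boxcars with the
double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1, ratio 6,
32 s kernel — the conventional parameterization; the source names but
does not parameterize its HRF) on a TR/16 grid sampled at frame
midpoints, adds AR(1) noise (stationary sd, lag-1 autocorrelation φ),
and returns motion-like random-walk nuisance regressors.  The GLM module
shares the same regressor builder, so noiseless simulated BOLD is
recovered exactly by OLS.  GLM estimation is plain OLS without
prewhitening: the betas feed a cross-validated decoder, where residual
autocorrelation costs efficiency, not validity.  High-pass filtering
uses DCT drift columns with a 128 s cutoff (configurable; the source is
silent on filtering).

### Default operating point, and what passing tests show

Defaults: signal_amplitude 1.0, noise_sd 0.5 per voxel, smoothing FWHM
3 mm on a 3 mm grid, confound and cue amplitudes 0.3, σ_g = 0.1, grid
18 × 18 × 15 (≈ 1870 mask voxels), 3 blobs of radius 7.5 mm.  This
operating point was chosen so that ground-truth recovery is testable:
the package's recovery contract (population weight direction within
cosine ≥ 0.7 of the generating pattern on the default cohort) fails in
regimes that are individually realistic — strong participant-gain
heterogeneity makes the ε-SVR absorb per-participant calibration into
noise directions, and noise smoothed at the blob scale rotates the
discriminative direction away from the pattern (precisely the
backward/forward-model discrepancy the structure-coefficient transform
exists to correct).  The default cohort is therefore an intentionally
benign, high-SNR regime: cross-validated r ≈ 0.95 here, versus ≈ 0.6 in
real cohorts.  Passing tests demonstrate the correctness and calibration
of the machinery and the recoverability of a known truth — not that
real-data effect sizes are reproduced, which desk-scale synthetic
cohorts cannot and do not claim.

Features of real data the generator does not emulate: physiological
(cardiac/respiratory) noise structure, motion artifacts beyond drift
regressors, EPI distortion, spatial nonstationarity of noise, habituation
or learning across runs, and rating-scale use differences across
participants beyond the condition means.

## Numerical choices and degenerate inputs

Grids must match exactly (affine tolerance 10⁻⁴ mm); there is no
implicit resampling.  Out-of-mask voxels unvectorize to 0.  Non-finite
in-mask values are rejected at load.  Rating levels with no events are
omitted from designs, never zero-filled; rank-deficient designs raise an
error naming the collinear columns (QR with pivoting).  Constant
training ratings, zero-variance actual ratings, and zero-variance
latents raise typed errors; constant predictions are flagged rather than
silently correlated.  Forced-choice ties score ½.  Blob placement uses
rejection sampling over voxels at least half a blob radius inside the
mask (a blob clipped by a convex mask keeps a compact connected
support), with pairwise center separation ≥ 2·radius + 2 voxels by
default.

## Problem sizes

The test and acceptance suites run cohorts of 6–30 participants on
masks of ≈ 200–5700 voxels, 1–4 runs, with 100–500 permutation shuffles
and 150–5000 bootstrap replicates; the calibration check uses 200 null
cohorts and the recovery, specificity and subsystem checks use 10 seeds
each.  These sizes are the package's chosen study conditions for a
complete run on a single CPU.

## Known limitations

The ε-SVR weight map, not a ridge or PLS equivalent, is the only
decoder; nonlinear kernels and hyperparameter search are out of scope by
design.  The spatial-correlation permutation null ignores smoothness.
The Δr permutation scheme and the ROI contribution rule are documented
interpretations of underspecified procedures.  The pipeline stores
per-participant beta series as 4-D NIfTI, which is convenient but not
BIDS-derivative-compliant.
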