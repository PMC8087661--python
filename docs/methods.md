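# Methods

## The analysis

`taskpca` implements a classification pipeline for two-group task-fMRI
studies in which each participant contributes several task-contrast images
(here: sleep-related pictures, sleep-related sounds, and a Stroop task) and
the question is whether the *covariance structure across tasks*, rather than
any single task's activation, separates patients from controls.

The pipeline has five stages.

### 1. ROI beta extraction

Given a task-contrast beta volume and an integer atlas (AAL, 90 cerebral
regions), the value of region r for task t is the mean of the voxels whose
beta exceeds 0.1 × the region's maximum beta. Because the threshold is
strictly positive whenever the maximum is, only positive voxels contribute;
a region whose maximum is ≤ 0 is reported as 0 with a coverage flag. Ties at
exactly 0.1 × max are excluded (strict inequality). The rule is applied per
region per task; volumes must share the atlas grid (no resampling is
performed — registration is upstream preprocessing and out of scope).

Twelve poorly covered regions (bilateral olfactory cortex, amygdala,
superior parietal gyrus, paracentral lobule, middle temporal pole, pallidum)
are excluded by a fixed list, retaining 78 of 90 regions. A data-driven
alternative (`mode="coverage"`: drop any region flagged uncovered in any
participant) is provided because "poorly covered" is ultimately a property
of the data.

### 2. Per-participant PCA across tasks

Each participant's 78 × 3 matrix X (ROIs × tasks) is column-centered,
divided by √(n−1) with n = 3 tasks, and decomposed by SVD, X′ = U Σ Vᵀ.
Rows (ROIs) are treated as observations and tasks as variables; the
78-dimensional left singular vectors U are the component loadings used as
features, and explained-variance proportions are σ²ₖ/Σσ². This orientation
is the only one that yields 78-dimensional loadings with a nonzero third
component. The task-side coordinates V scaled by the singular values are
kept as scores; U·scoresᵀ reconstructs the centered, scaled input.

Eigenvector sign is indeterminate, so two conventions are applied before
loadings are pooled across participants: within a participant, each
component is oriented so its largest-magnitude entry is positive; across
participants, each component vector is flipped, if needed, to have
nonnegative inner product with the elementwise median of the
within-convention-oriented vectors. The alignment is idempotent and never
changes loading magnitudes. Any cross-subject orientation rule is a modeling
choice — results of the pooled stages can in principle depend on it, and the
original analysis does not state one; the median reference was chosen as a
robust consensus direction.

Degenerate matrices (zero variance after centering) raise an error rather
than returning silent zero components. Singular-value ties are broken by
decomposition order, which is deterministic for a fixed LAPACK routine.

### 3. Feature tables

For each component k, column j of the p × m feature table is participant
j's component-k loading vector (78 × 40 at the study dimensions); analogous
single-task tables take one task's raw ROI beta column per participant.
Labels use patient = 1, control = 0.

### 4. LASSO-logistic feature selection

Selection minimizes the penalized binomial objective
(1/N) Σ [log(1+e^{η}) − yη] + λ‖β‖₁ over a descending grid of 100
log-equispaced λ values from λmax (the smallest penalty with an all-zero
fit, computed from the KKT conditions at the null model) down to
0.01·λmax. λ is chosen to minimize the leave-one-out cross-validated
binomial deviance −2[y log p̂ + (1−y) log(1−p̂)], summed over folds, with
held-out probabilities clipped at 1e-8; ties break toward the larger λ
(sparser model). Features are standardized internally (population SD,
re-computed inside each training fold); reported coefficients are on the
original scale; the intercept is unpenalized.

The solver is iteratively-reweighted least squares with cyclic coordinate
descent on the weighted quadratic approximation, warm-started along the
path and JIT-compiled. The default convergence threshold (1e-12 on the
squared coordinate step and relative objective decrease) is far tighter
than selection requires; tests verify agreement with a generic convex
minimizer to 1e-6 in coefficients at a tightened threshold, and the sum
versus mean of fold deviances does not affect the argmin.

### 5. RBF-SVM classification and metrics

The soft-margin SVM with kernel exp(−γ‖xᵢ−xⱼ‖²) is fit on the selected
features only. C and γ are each searched over 20 log-equispaced values in
[0.1, 10] (resolution configurable), scoring each pair by pooled
leave-one-out accuracy; ties break toward the smallest C, then the smallest
γ (maximum regularization). The winning pair's pooled held-out predictions
form a single confusion matrix from which five metrics are computed:
accuracy (TP+TN)/N, recall TP/(TP+FN), precision TP/(TP+FP), specificity
TN/(TN+FP), and F2 = 5PR/(4P+R) from exact fractions. Zero-denominator
metrics report 0 with a flag. Display values are rounded to two decimals
with round-to-nearest on the double (the convention of R's `round`, which
the reported values follow: 29/40 = 0.725 prints as 0.72 and 27/40 = 0.675
as 0.68).

By default, feature selection runs **once on the full sample** before the
SVM cross-validation loop, replicating the original analysis. This leaks
label information across folds and inflates the error estimate's optimism;
`nested=True` re-runs selection and the hyperparameter search inside every
fold (predicting the training-fold majority class when a fold selects
nothing) for an honest generalization estimate.

`reconstruct_confusion` inverts the printed-metric rounding: given 2-dp
recall and specificity and the group sizes, an exhaustive search over
TP ∈ 0..n₊, TN ∈ 0..n₋ returns every integer confusion matrix that prints
those values. With 19/21 groups, the four reported family results are each
pinned down uniquely, which is what makes exact reproduction of the
published metric tables possible without the raw data.

## The synthetic data generator

No raw beta matrices are publicly deposited, so the generator emulates the
study conditions and makes every stage testable end to end. Each
participant's matrix is X = U_s diag(s) Vᵀ + ε, shifted by a constant so
every entry is positive (mirroring positive-voxel averaging; a constant
shift is absorbed by column centering, leaving the planted structure
recoverable exactly at zero noise):

* **Group patterns** U_g: orthonormal 78 × 3 matrices with zero column
  means, shared between groups except that the patient group's component-2
  pattern is perturbed at six effect ROIs — by default the regions reported
  as discriminative (bilateral inferior frontal gyrus pars orbitalis, right
  calcarine, right lingual, left inferior occipital, left inferior
  temporal).
* **Per-subject jitter**: U_s re-orthonormalizes U_g + jitter·G with G
  Gaussian; this produces the between-subject loading variability a pooled
  analysis must tolerate (the real data show substantial between-subject
  spread in explained proportions). The mechanism is a stand-in — no
  between-subject variance model is published.
* **Singular values** s: √0.70, √0.20, √0.10 scaled by 3.0, so the three
  components explain ≈ 70/20/10 % of variance, matching the reported
  regime, with entries landing in the reported 0.1–0.5 beta-value range.
* **Noise** ε: independent Gaussian(0, 0.05²) per entry — the simplest
  model consistent with the pipeline's assumptions.
* **Task mixing** V: a fixed orthonormal 3 × 3 matrix (seed-independent).
* **Seeding**: one master seed; per-subject streams derived through
  `SeedSequence`, so equal seeds give bitwise-equal datasets.

Default sizes are 19 patients vs 21 controls, 78 ROIs, 3 tasks,
effect size 0.5 (a strong, easily recoverable perturbation of a unit-norm
pattern), jitter 0.05, noise SD 0.05, 8 voxels per ROI in voxel mode.

In voxel mode the generator also emits an integer label volume and per-task
beta volumes whose supra-threshold voxel means equal the requested ROI
values exactly, with planted sub-threshold and negative voxels (and
negative-only voxels in the 12 excluded regions) to exercise the extraction
filter.

**What the generator does not emulate:** hemodynamics and task design,
spatial autocorrelation beyond ROI-level structure, realistic anatomical
geometry (the synthetic label volume is a block layout), non-Gaussian
noise, or any clinical covariate structure. Passing the synthetic
parameter-recovery tests therefore shows the pipeline recovers the kind of
low-rank cross-task group effect it assumes — not that such an effect is
identifiable in arbitrary real data.

## Problem sizes used in tests

The test suite runs the oracle comparisons on tiny instances (≤ 4 features,
≤ 10 participants for the LASSO objective; ≤ 10 points for the SVM dual),
the PCA oracle on 100 seeded 78 × 3 matrices, parameter recovery on 50
seeded datasets at the full study dimensions (selection stage) and 25
seeded datasets for the four-family comparison with a 6 × 6 SVM grid, and
plumbing tests on reduced dimensions (12 ROIs, 12 participants). The
acceptance script runs one full-size pipeline at the default 20 × 20 grid
and a 10-seed recovery rate.

## Known limitations

* The cross-subject sign alignment is a design choice the original analysis
  leaves unstated; pooled-loading results can depend on it.
* The default (non-nested) topology reproduces the original analysis,
  including its cross-fold information leak; its metrics should be read as
  descriptive of that procedure, not as unbiased generalization estimates.
* λmax is computed from the full sample; in a leave-one-out fold the
  all-zero penalty can be slightly larger, so the first grid point is not
  guaranteed to be null within every fold (the standard grid convention).
* The per-subject jitter model is a plausible stand-in, not an estimate
  from data.
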