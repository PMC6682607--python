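# Methods

## Model and pipeline

The pipeline estimates a function from a subject's 3D activation image to a
continuous score.  Images are vectorized row-major over the voxel grid;
voxels non-finite in any subject are dropped for all subjects, and only
voxels with a nonzero atlas label enter kernels (label 0 is background by
convention).  For every training/evaluation split the stages run in a fixed
order:

1. **Confound residualization.**  Voxel-wise ordinary least squares of
   activation on [1, age, gender], coefficients estimated on the training
   subjects and applied unchanged to held-out subjects.  The target score is
   *not* residualized by default (`CVSpec.residualize_target` enables it);
   removing the confound signal from the features is the primary control,
   and residualizing the target as well changes the units of the reported
   MSE.  A covariate that is constant within a training fold (e.g. a single
   gender in a small fold) is dropped for that fold with a warning — its
   effect is absorbed by the intercept.
2. **Region kernels.**  One linear Gram matrix per region over the region's
   voxels.
3. **Normalization.**  K ← K / c with c = trace(K[train, train]) / n_train,
   so every region's training block has trace n_train regardless of voxel
   count.  The trace convention is the standard kernel-toolbox choice; the
   constant is kept so held-out rows are scaled identically.  A region whose
   training trace is (near-)zero — for instance one whose entire signal was
   a confound — is dropped with a warning rather than imputed.
4. **Centering.**  Implicit feature-space centering about the training mean:
   `Kc[i,j] = K[i,j] − m_i − m_j + g` with m the mean over training columns
   and g the training-block grand mean.  This applies to training *and*
   held-out rows using training statistics only, and guarantees the
   zero-row-sum training block the learner assumes.

No statistic derived from held-out subjects ever enters the confound
coefficients, normalization constants or centering means; the tests assert
that replacing held-out rows with garbage leaves every training-block
quantity bit-identical.

## SimpleMKL

The learner minimizes J(d) over the probability simplex, where J(d) is the
optimal ε-SVR dual objective on K(d) = Σ d_m K_m:

J(d) = max_β { yᵀβ − ½ βᵀK(d)β − ε‖β‖₁ : Σβ_i = 0, |β_i| ≤ C }.

J is convex in d and, by Danskin's theorem, ∂J/∂d_m = −½ βᵀK_m β at the
current dual optimum.  The solver is reduced-gradient descent: the largest
component of d anchors the sum-to-one constraint, the descent direction
zeroes coordinates at the boundary with a non-improving gradient, and the
step walks to successive simplex boundaries while J decreases, finishing
with Armijo backtracking.  When several components hit zero in one step all
are removed and d is renormalized.  d starts uniform at 1/M (the reference
initialization; deterministic).  Termination: the MKL duality gap
max_m S_m − Σ_m d_m S_m (S_m = ½ βᵀK_m β) relative to |J| falls below `tol`
(default 1e−5), or `max_iter` (default 200) is reached, in which case the
best iterate is returned with a warning.  J is asserted non-increasing
across iterations; a violation is logged as a solver bug.

The inner dual is solved exactly by libsvm (through scikit-learn).  The
binding is called directly in the hot path to avoid per-call estimator
overhead — the iteration count here is tens of thousands of small solves —
with the public estimator as fallback; both produce identical coefficients.
An independent SLSQP quadratic-program solve of the same dual serves as the
oracle in the tests, never as the implementation.

Kernels entering a fit are validated symmetric PSD (eigenvalues ≥
−1e−8·λ_max, tiny negatives repaired with a 1e−10·λ_max diagonal jitter);
simplex combinations of validated kernels are PSD by construction and skip
the check.

Targets are centered by their training mean before fitting and the mean is
restored at prediction.  ε defaults to 0.1 on the centered targets; with
scores of standard deviation ≈ 3 this is a mild tube, and it is exposed in
the configuration along with C.

## Evaluation

Fold assignment is a seeded uniform partition into k near-equal folds,
computed in *subject-id order* so results do not depend on file ordering;
score-quantile stratification is available behind a flag but off by default.
Nested threefold CV with the same scheme inside and outside: the inner loop
scores each candidate C (default grid 0.1, 1, 10, 100 — log-spaced around
the unit scale of trace-normalized, centered kernels) by mean inner-fold
MSE, ties to the smallest C.  Outer-fold predictions are pooled into a
single (r, MSE) pair; each subject is predicted exactly once, and provenance
is asserted at run time.

The permutation test shuffles scores across subjects (images and covariates
stay attached to their subjects) and reruns the entire nested pipeline per
permutation, including confound fits and inner C selection — the
conservative, leakage-free scope.  p = (#{null ≥ observed r} + 1)/(n_perm + 1)
(≤ for MSE), so p is never 0.  Kernel stacks are cached per training-fold
across permutations: the stack is a pure function of images, covariates and
the fold split, never of the targets, so the cache changes nothing but run
time.  Default n_perm is 1000; the calibration tests use 99.  Multi-scale
runs flag scales with both p_r and p_mse below α/n_scales (Bonferroni).

The interpretive weight maps written by the CLI come from a refit on all
subjects at the modal outer-fold C.  They are labelled as interpretive in
the results JSON and never feed the performance estimates, since a model
refit on everyone has no held-out data.

## Synthetic studies

The generator emulates the study design the pipeline targets: n = 56
subjects (confirmatory analog n = 36), ages uniform 18–25, ~70% women, a
116-region Voronoi parcellation of a central ellipsoid "brain" on a 24³
grid (Lloyd-relaxed so every region has ≥ 8 voxels), and scores on an
instrument-like scale (mean 10, SD 3).  Each subject's image is smooth
Gaussian noise (FWHM 2 voxels, unit SD) plus a latent amplitude u_s times a
fixed random-sign voxel pattern confined to the signal regions — a
multivariate pattern, not a mean shift, matching the premise that the
information is distributed.  The per-voxel pattern magnitude defaults to
0.5 noise-SD, a moderate single-voxel effect that leaves recovery clearly
possible but noisy at n ≈ 50.  A smooth spatial mode carrying an age/gender
effect is added to the images by default so the residualization stage has
real work to do.

The score is a·u + b·z(age) + c·z(gender) + e with a = √effect_size,
b = c = √(confound_r2/2); u is orthogonalized in-sample against the
covariates and e against everything, so realized variance fractions equal
the requested ones exactly (corr(score, u) = √effect_size by construction).
Defaults: effect_size 0.3, confound_r2 0.1.

What passing tests on these studies do **not** show about real data: the
generator has no hemodynamic or task structure, no scanner artefacts or
motion, no between-region correlation of signal, and its confounds are
exactly linear.  Recovery rates and calibration measured here are therefore
best-case statements about the estimator, not about fMRI.

## Problem sizes in the test suite

Validation runs use reduced problem sizes chosen as the package's own test
conditions: parameter recovery uses 20 replicates of n = 50 subjects, 16³
grids and 20 regions (2 carrying signal); type-I-error calibration uses 200
null studies of n = 24 subjects, 10³ grids, 5 regions, 99 permutations each
with a single-point C grid; the end-to-end smoke run uses the full default
scale (n = 56, 24³, 116 regions) with a reduced permutation count.  The
acceptance script mirrors these, with 5 recovery replicates and 60 null
studies.

## Known limitations

- The SimpleMKL path, like any L1-type selector, need not select both of two
  regions carrying correlated information; only total predictive performance
  is guaranteed, not which duplicate wins.
- Small-n threefold CV makes r estimates noisy; replicate-level means are
  the meaningful summary.
- No resampling: inputs on mismatched grids are rejected, not aligned.
- Exact reproducibility across BLAS implementations is not guaranteed below
  ~1e−8; seeds fix everything else.
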