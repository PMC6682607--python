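# parcelmkl

Region-wise **multiple kernel learning (MKL) regression** for whole-brain
activation images: predict a continuous per-subject score — for example the
severity of a hypo/mania-related symptom — from 3D statistical contrast maps,
while learning *which anatomical regions* carry the predictive pattern.

## Who this is for

Neuroimaging groups running individual-differences ("brain–behaviour")
prediction studies: n ≈ 30–60 subjects, one contrast image per subject
(NIfTI-1), an integer-labelled anatomical parcellation (e.g. a 116-region
atlas) on the same voxel grid, and a subject table with the target score and
nuisance covariates (age, gender).  Plain whole-brain multivariate models
predict well but are hard to interpret voxel-by-voxel; the region-kernel
decomposition used here yields a sparse, anatomically organised account of
where the predictive information lives.

## The model

Each subject's image is split by the atlas into M regional activation
patterns, and one linear kernel is built per region:

```
K_m(i, j) = ⟨ x_i^(m), x_j^(m) ⟩        m = 1 … M regions
```

after (1) residualizing voxel values on [1, age, gender] with coefficients
estimated on training subjects only, (2) normalizing each kernel so its
training-block trace equals the number of training subjects (regions with
more voxels must not dominate), and (3) mean-centering in feature space with
training statistics.  The predictor is an ε-insensitive support vector
regression on the convex combination

```
K(d) = Σ_m d_m K_m ,     d_m ≥ 0,  Σ_m d_m = 1 ,
```

with the simplex weights **d** learned jointly with the SVR by SimpleMKL
(reduced-gradient descent on J(d), the optimal SVR dual objective, using
∂J/∂d_m = −½ βᵀK_m β).  The L1/simplex geometry drives most d_m to exactly
zero: unselected regions contribute *nothing* to predictions, and the
nonzero d_m rank regions by contribution.  Both the region weights d and the
per-voxel primal weights `w_v = d_m Σ_i β_i x̃_{i,v}` can be written back as
brain images.

Performance is estimated by **nested threefold cross-validation** (outer
loop: pooled out-of-fold predictions → Pearson r and MSE; inner loop:
soft-margin parameter C chosen by MSE), and significance by a **permutation
test** that reruns the entire pipeline — confound fits, kernel statistics,
inner C selection — on label-shuffled data, with Bonferroni correction when
several scales are modelled.

## Worked example

No imaging data ships with the package; the `simulate` module generates a
study with the generative structure the model assumes (planted multivariate
signal in known regions, age/gender confounding, smooth noise):

```bash
parcelmkl simulate --out study/ --seed 0               # 56 subjects, 116 regions
parcelmkl run --subjects study/subjects.csv --atlas study/atlas.nii.gz \
              --out results/ --n-perm 99 --seed 0
```

or from Python (`examples/04_nested_cv_and_significance.py`, 40 subjects,
10 regions, signal planted in region 2):

```
out-of-fold r   = 0.386   (p = 0.01, 99 permutations)
out-of-fold MSE = 7.609 (p = 0.01)
C selected per outer fold: [1.0, 1.0, 1.0]
consensus top region: 2 (planted signal was region 2)
```

Here r is the correlation between actual and out-of-fold predicted scores
(each subject predicted by a model that never saw it), the MSE is in squared
score units, the p-values come from 99 full-pipeline permutations (add-one
convention, so p ≥ 1/100), and the consensus ranking — kernel weights
averaged over the outer-fold models — correctly identifies the planted
region.  `run` writes `results.json`, an actual-vs-predicted CSV for scatter
plots, and two NIfTI weight maps (region weights, voxel weights) from an
interpretive refit on all subjects.

The other scripts in `examples/` walk through study simulation, kernel
algebra, sparse region selection, and mask-restricted confirmatory analysis
(`parcelmkl run --mask vlpfc_mask.nii.gz ...` mirrors testing an a-priori
region in an independent sample).

## Scope

The pipeline starts from first-level contrast images: fMRI preprocessing,
GLM estimation, spatial normalization and atlas construction are upstream
responsibilities.  Images, atlas and mask must already share one voxel grid
(no resampling is performed, by design).  Nonlinear kernels and
classification are out of scope.
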