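"""Estimate out-of-sample performance and its significance.

Nested threefold cross-validation: the outer loop pools out-of-fold
predictions into (Pearson r, MSE); the inner loop picks the SVR soft-margin
parameter C by mean squared error.  A permutation test then reruns the whole
pipeline on shuffled scores to calibrate significance.
"""

import warnings

from parcelmkl import (
    CVSpec,
    SimulationConfig,
    permutation_test,
    simulate_study,
    study_to_analysis_inputs,
)

warnings.filterwarnings("ignore")

cfg = SimulationConfig(n_subjects=40, shape=(12, 12, 12), n_regions=10,
                       signal_regions=(2,), effect_size=0.4, seed=3)
dataset, parcellation, table = study_to_analysis_inputs(simulate_study(cfg))

spec = CVSpec(c_grid=(0.1, 1.0, 10.0), seed=0, mkl_tol=1e-4)
result = permutation_test(dataset, parcellation, table, spec,
                          n_perm=99, seed=11)

print(f"out-of-fold r   = {result.r:.3f}   (p = {result.p_r}, 99 permutations)")
print(f"out-of-fold MSE = {result.mse:.3f} (p = {result.p_mse})")
print(f"C selected per outer fold: {result.selected_C}")
print(f"consensus top region: {result.region_ranking[0]} "
      f"(planted signal was region {cfg.signal_regions[0]})")
print("each subject was predicted exactly once, by a model that never saw it;")
print("p-values use the add-one convention, so they can never be exactly 0.")
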