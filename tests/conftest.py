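import numpy as np
import pytest

from parcelmkl import (
    SimulationConfig,
    simulate_study,
    study_to_analysis_inputs,
)
from parcelmkl.kernels import build_kernel_stack
from parcelmkl.nifti import Grid, Parcellation, VoxelDataset


@pytest.fixture(scope="session")
def small_study():
    """A quick planted-signal study: 30 subjects, 8 regions, 12^3 grid."""
    cfg = SimulationConfig(
        n_subjects=30, shape=(12, 12, 12), n_regions=8, signal_regions=(1,),
        effect_size=0.5, confound_r2=0.1, seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_inputs(small_study):
    return study_to_analysis_inputs(small_study)


@pytest.fixture()
def toy_dataset():
    """Deterministic 6-subject dataset over a 4x4x1 grid, two block regions."""
    rng = np.random.default_rng(7)
    shape = (4, 4, 1)
    data = rng.standard_normal((6, 16))
    coords = np.column_stack(np.unravel_index(np.arange(16), shape))
    ds = VoxelDataset(data, [f"s{i}" for i in range(6)], Grid(shape, np.eye(4)), coords)
    labels = np.zeros(shape, int)
    labels.ravel()[:8] = 1
    labels.ravel()[8:] = 2
    parc = Parcellation(labels, {1: "left", 2: "right"},
                        {1: np.arange(8), 2: np.arange(8, 16)})
    return ds, parc


@pytest.fixture()
def toy_stack(toy_dataset):
    ds, parc = toy_dataset
    return build_kernel_stack(ds, parc, np.arange(6), keep_features=True)
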