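"""Synthetic study generator: atlas, activation images, covariates, scores.

Emulates the statistical structure the region-kernel regression assumes: a
cohort of young-adult subjects, each with one 3D activation image made of
spatially smooth Gaussian noise plus a subject-specific latent amplitude
times a fixed multivariate (random-sign) voxel pattern confined to a few
"signal" regions of a block/Voronoi parcellation; a continuous symptom score
that mixes that latent amplitude with linear age and gender confounding and
independent noise.

The score decomposition is calibrated exactly in-sample: the latent is
orthogonalized against the covariates and the score noise against
everything, so the realized variance fractions equal ``effect_size`` and
``confound_r2`` by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "make_atlas",
    "simulate_study",
    "write_study",
    "study_to_analysis_inputs",
]

_FWHM_TO_SIGMA = 1.0 / 2.35482


@dataclass
class SimulationConfig:
    """Study-generator settings.

    Defaults mirror the primary-cohort conditions the pipeline is meant for:
    56 subjects aged 18-25 (70% women), a 116-region whole-brain atlas, the
    multivariate signal confined to a single left-ventral-prefrontal-like
    region, the brain pattern explaining 30% of score variance and age/gender
    another 10%.
    """

    n_subjects: int = 56
    shape: tuple[int, int, int] = (24, 24, 24)
    n_regions: int = 116
    signal_regions: tuple[int, ...] = (1,)
    effect_size: float = 0.3  # score variance fraction from the brain pattern
    confound_r2: float = 0.1  # score variance fraction from age+gender
    noise_sd: float = 1.0  # image background noise scale
    signal_amplitude: float = 0.5  # per-voxel pattern magnitude per latent unit
    smooth_fwhm: float = 2.0  # voxels
    score_mean: float = 10.0  # instrument-like location
    score_sd: float = 3.0  # instrument-like scale
    confounds_in_images: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0 or self.confound_r2 < 0:
            raise ValueError("variance fractions must be non-negative")
        if self.effect_size + self.confound_r2 >= 1:
            raise ValueError("effect_size + confound_r2 must be < 1")
        if self.n_subjects < 6:
            raise ValueError("need at least 6 subjects")
        if min(self.shape) < 4 or self.n_regions < 2:
            raise ValueError("grid too small or fewer than 2 regions")
        if not set(self.signal_regions) <= set(range(1, self.n_regions + 1)):
            raise ValueError("signal_regions must be atlas region ids")


@dataclass
class SimulatedStudy:
    images: np.ndarray  # (n_subjects, *shape)
    atlas: np.ndarray  # int label volume, 0 background
    table: pd.DataFrame  # subject_id, score, age, gender
    affine: np.ndarray
    ground_truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def make_atlas(config: SimulationConfig) -> np.ndarray:
    """Voronoi parcellation of a central brain ellipsoid into n_regions.

    Seed points are drawn inside the ellipsoid and relaxed by a few Lloyd
    iterations so regions are compact and near-equal; generation retries
    until every region has >= 8 voxels.
    """
    shape = np.asarray(config.shape)
    rng = np.random.default_rng(config.seed)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    center = (shape - 1) / 2.0
    radii = shape * 0.46
    inside = (((grid - center) / radii) ** 2).sum(axis=-1) <= 1.0
    coords = grid[inside].astype(float)
    if len(coords) < config.n_regions * 8:
        raise ValueError(
            f"grid {tuple(shape)} too small for {config.n_regions} regions of >= 8 voxels"
        )
    for _attempt in range(20):
        seeds = coords[rng.choice(len(coords), config.n_regions, replace=False)]
        for _ in range(8):  # Lloyd relaxation
            d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(-1)
            assign = d2.argmin(axis=1)
            for r in range(config.n_regions):
                sel = assign == r
                if sel.any():
                    seeds[r] = coords[sel].mean(axis=0)
        counts = np.bincount(assign, minlength=config.n_regions)
        if counts.min() >= 8:
            labels = np.zeros(tuple(shape), dtype=np.int16)
            labels[tuple(coords.astype(int).T)] = assign + 1
            return labels
    raise RuntimeError("could not generate an atlas with all regions >= 8 voxels")


def _orthonormalize_against(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residualize v on the columns of basis, then scale to unit variance."""
    coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
    r = v - basis @ coef
    sd = r.std()
    if sd < 1e-12:
        raise RuntimeError("degenerate residual during score calibration")
    return r / sd


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate images, atlas, covariates and a calibrated score.

    score = sd * (a*u + b*z(age) + c*z(gender) + e) + mean, with
    a = sqrt(effect_size), b = c = sqrt(confound_r2 / 2), and
    sd(e) chosen so the standardized parts sum to variance 1.  u (the image
    latent), the covariates and e are mutually orthogonalized in-sample, so
    the realized fractions match the requested ones exactly.
    """
    rng = np.random.default_rng(config.seed)
    atlas = make_atlas(config)
    n = config.n_subjects

    age = rng.uniform(18.0, 25.0, n)
    gender = (rng.random(n) < 0.7).astype(float)  # 1 = female, ~70%
    if np.ptp(gender) == 0:  # tiny-n edge: force both levels present
        gender[rng.integers(n)] = 1.0 - gender[0]
    ones = np.ones(n)
    cov_basis = np.column_stack([ones, age, gender])

    for _retry in range(5):
        u_raw = rng.standard_normal(n)
        try:
            u = _orthonormalize_against(u_raw, cov_basis)
            break
        except RuntimeError:
            continue
    else:
        raise RuntimeError("score calibration failed after retries")
    z_age = (age - age.mean()) / age.std()
    z_gender = (gender - gender.mean()) / (gender.std() if gender.std() > 0 else 1.0)
    e_raw = rng.standard_normal(n)
    e = _orthonormalize_against(e_raw, np.column_stack([cov_basis, u]))

    a = np.sqrt(config.effect_size)
    b = c = np.sqrt(config.confound_r2 / 2.0)
    resid_var = 1.0 - config.effect_size - config.confound_r2
    score_std = a * u + b * z_age + c * z_gender + np.sqrt(resid_var) * e
    score = config.score_mean + config.score_sd * score_std

    # fixed multivariate random-sign pattern on the signal regions: each
    # signal voxel carries +-signal_amplitude per unit of the latent, so the
    # regional pattern (not its mean) encodes the subject's amplitude
    pattern = np.zeros(config.shape)
    for rid in config.signal_regions:
        sel = atlas == rid
        pattern[sel] = rng.choice([-1.0, 1.0], size=int(sel.sum()))
    pattern *= config.signal_amplitude

    sigma = config.smooth_fwhm * _FWHM_TO_SIGMA
    images = np.empty((n, *config.shape), dtype=np.float64)
    conf_pattern = None
    if config.confounds_in_images:
        # broad smooth spatial mode carrying the covariate effect
        conf_pattern = ndimage.gaussian_filter(rng.standard_normal(config.shape), 3.0)
        conf_pattern /= np.abs(conf_pattern).max()
    for s in range(n):
        noise = rng.standard_normal(config.shape)
        if sigma > 0:
            noise = ndimage.gaussian_filter(noise, sigma)
            noise /= noise.std()
        img = config.noise_sd * noise + u[s] * pattern
        if conf_pattern is not None:
            img = img + (0.3 * z_age[s] + 0.3 * z_gender[s]) * conf_pattern
        images[s] = img

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{s + 1:03d}" for s in range(n)],
            "score": score,
            "age": age,
            "gender": gender,
        }
    )
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return SimulatedStudy(
        images=images,
        atlas=atlas,
        table=table,
        affine=affine,
        ground_truth={
            "signal_regions": list(config.signal_regions),
            "latent": u,
            "pattern": pattern,
            "coefficients": {"brain": a, "age": b, "gender": c},
        },
        config=config,
    )


def study_to_analysis_inputs(study: SimulatedStudy):
    """Assemble the in-memory analysis containers from a simulated study.

    Equivalent to writing the study to disk and reloading it, minus the
    float32 storage rounding: the voxel grid, column order and parcellation
    derivation follow the same row-major conventions as the NIfTI loaders.
    """
    from .nifti import Grid, SubjectTable, VoxelDataset, parcellation_from_labels

    n, *shape = study.images.shape
    grid = Grid(tuple(shape), np.asarray(study.affine))
    data = study.images.reshape(n, -1)
    coords = np.column_stack(np.unravel_index(np.arange(data.shape[1]), tuple(shape)))
    dataset = VoxelDataset(
        np.ascontiguousarray(data),
        study.table["subject_id"].tolist(),
        grid,
        coords,
    )
    parcellation = parcellation_from_labels(study.atlas, dataset)
    table = SubjectTable(
        study.table["subject_id"].tolist(),
        study.table["score"].to_numpy(float),
        study.table[["age", "gender"]].to_numpy(float),
        ["age", "gender"],
    )
    return dataset, parcellation, table


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, object]:
    """Write images/atlas as NIfTI-1 and the subject table as CSV.

    Returns the file manifest: image paths (in subject order), atlas path,
    table path.  The CSV matches the loader schema (subject_id, score, age,
    gender, image_path).  The generator config is echoed to JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_paths = []
    for i, sid in enumerate(study.table["subject_id"]):
        p = out / f"{sid}.nii.gz"
        nib.save(nib.Nifti1Image(study.images[i].astype(np.float32), study.affine), p)
        img_paths.append(str(p))
    atlas_path = out / "atlas.nii.gz"
    nib.save(nib.Nifti1Image(study.atlas.astype(np.int16), study.affine), atlas_path)
    df = study.table.copy()
    df["image_path"] = img_paths
    table_path = out / "subjects.csv"
    df.to_csv(table_path, index=False)
    if study.config is not None:
        cfg = asdict(study.config)
        cfg["shape"] = list(cfg["shape"])
        cfg["signal_regions"] = list(cfg["signal_regions"])
        (out / "simulation_config.json").write_text(json.dumps(cfg, indent=2))
    return {"images": img_paths, "atlas": str(atlas_path), "table": str(table_path)}
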