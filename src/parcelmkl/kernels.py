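"""Per-region linear kernels with train/test-separated normalization,
centering and confound removal.

Every statistic that enters a kernel stack — confound regression
coefficients, normalization constants, centering means — is estimated on the
training subjects only and then applied to all rows, so held-out subjects
never leak into the training-block kernels.

Pipeline order is fixed: residualize confounds -> per-region linear kernel ->
normalize (training trace = n_train) -> center (about the training mean in
feature space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nifti import Parcellation, VoxelDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConfoundModel",
    "KernelStack",
    "DegenerateRegionError",
    "fit_confound_model",
    "residualize_confounds",
    "compute_region_kernel",
    "normalize_kernel",
    "center_kernel",
    "build_kernel_stack",
]

# training-trace of an unnormalized kernel below this (relative to feature
# scale) marks the region as degenerate (no variance left to learn from)
_DEGENERATE_TRACE = 1e-12


class DegenerateRegionError(ValueError):
    """Raised when a region's kernel has (near-)zero training trace."""


@dataclass
class ConfoundModel:
    """Per-voxel least-squares fit of activation on [1, covariates].

    ``coefficients`` has shape (n_voxels, q+1); column 0 is the intercept.
    Estimated on training subjects only and applied unchanged to held-out
    subjects.
    """

    coefficients: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_covariates(self) -> int:
        return self.coefficients.shape[1] - 1


def _design(covariates: np.ndarray) -> np.ndarray:
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.ndim == 2 and covariates.shape[0] == 1 and covariates.shape[1] > 1:
        pass  # single subject row
    return np.column_stack([np.ones(covariates.shape[0]), covariates])


def fit_confound_model(
    train_data: np.ndarray,
    train_covariates: np.ndarray,
    covariate_names: list[str] | None = None,
) -> ConfoundModel:
    """Fit the voxel-wise confound regression on the training fold.

    Requires at least q+2 subjects and a full-rank [intercept | covariates]
    design; rank deficiency (e.g. a constant covariate, duplicating the
    intercept) is reported with the offending columns.
    """
    X = _design(train_covariates)
    n, p = X.shape
    names = covariate_names or [f"cov{j}" for j in range(p - 1)]
    if n < p + 1:
        raise ValueError(f"need >= {p + 1} training subjects for {p - 1} covariates, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify columns not adding rank beyond the intercept
        bad = []
        kept = X[:, :1]
        for j in range(1, p):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(names[j - 1])
            else:
                kept = cand
        raise ValueError(f"confound design is rank-deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, np.asarray(train_data, dtype=float), rcond=None)
    return ConfoundModel(coef.T, list(names))


def residualize_confounds(
    model: ConfoundModel, data: np.ndarray, covariates: np.ndarray
) -> np.ndarray:
    """Remove the fitted confound effect: data - [1, covariates] @ coef.T.

    Valid for training or held-out subjects; coefficients are never re-fit
    here, so identical inputs always produce identical residuals.
    """
    X = _design(covariates)
    data = np.asarray(data, dtype=float)
    if X.shape[1] != model.coefficients.shape[1]:
        raise ValueError(
            f"covariate dimension {X.shape[1] - 1} does not match model "
            f"({model.n_covariates})"
        )
    if data.shape[1] != model.coefficients.shape[0]:
        raise ValueError("voxel dimension does not match confound model")
    return data - X @ model.coefficients.T


def compute_region_kernel(data: np.ndarray, voxel_columns: np.ndarray) -> np.ndarray:
    """Linear Gram matrix over one region's voxels: K[i,j] = <x_i, x_j>."""
    voxel_columns = np.asarray(voxel_columns)
    if voxel_columns.size == 0:
        raise ValueError("empty voxel column list")
    Xr = np.asarray(data, dtype=float)[:, voxel_columns]
    return Xr @ Xr.T


def normalize_kernel(K: np.ndarray, train_index: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide by the training-block mean diagonal, so train trace = n_train.

    Compensates for regions having different voxel counts.  Returns the
    constant so test kernel rows can be scaled identically.
    """
    train_index = np.asarray(train_index)
    tr = float(np.trace(K[np.ix_(train_index, train_index)]))
    if tr <= _DEGENERATE_TRACE * max(1, K.shape[0]):
        raise DegenerateRegionError("zero training trace (all-zero region)")
    c = tr / len(train_index)
    return K / c, c


def center_kernel(
    K: np.ndarray, train_index: np.ndarray
) -> tuple[np.ndarray, dict[str, float | np.ndarray]]:
    """Implicit feature-space centering about the training mean.

    For any rows i, j (train or test):
        Kc[i,j] = K[i,j] - m_i - m_j + g
    where m_i is the mean of K[i, train] and g the grand mean of the training
    block.  On the training block this equals H K H with H = I - 11^T/n_t.
    Returns stats (per-row means need the train columns, so the stats kept
    are the train column means and grand mean) for centering new data.
    """
    train_index = np.asarray(train_index)
    if train_index.size == 0:
        raise ValueError("train_index must be non-empty")
    col_means = K[:, train_index].mean(axis=1)  # m_i for every row i
    grand = float(K[np.ix_(train_index, train_index)].mean())
    Kc = K - col_means[:, None] - col_means[None, :] + grand
    stats = {"train_col_means": K[train_index][:, train_index].mean(axis=0), "grand_mean": grand}
    return Kc, stats


@dataclass
class KernelStack:
    """Per-region normalized+centered Gram matrices over all subjects.

    The matrices cover the full subject set of the dataset they were built
    from, but every statistic in them derives from ``train_index`` rows only;
    the train x train block is what the learner sees, and test x train rows
    give out-of-sample kernel evaluations.

    ``features`` holds the transformed (residualized, per-region scaled,
    train-mean-centered) voxel matrix used for primal weight-map extraction.
    """

    kernels: dict[int, np.ndarray]
    norm_constants: dict[int, float]
    center_stats: dict[int, dict]
    train_index: np.ndarray
    region_voxels: dict[int, np.ndarray]
    features: np.ndarray | None = None

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.kernels)

    @property
    def n_subjects(self) -> int:
        return next(iter(self.kernels.values())).shape[0]

    def train_block(self, region_id: int) -> np.ndarray:
        t = self.train_index
        return self.kernels[region_id][np.ix_(t, t)]

    def cross_block(self, region_id: int, rows: np.ndarray) -> np.ndarray:
        """rows x train kernel values for out-of-sample prediction."""
        return self.kernels[region_id][np.ix_(np.asarray(rows), self.train_index)]

    def save(self, path: str) -> None:
        """Serialize to a single NumPy archive (.npz) for caching."""
        payload: dict[str, np.ndarray] = {
            "region_ids": np.array(self.region_ids),
            "train_index": self.train_index,
        }
        for rid in self.region_ids:
            payload[f"kernel_{rid}"] = self.kernels[rid]
            payload[f"norm_{rid}"] = np.array(self.norm_constants[rid])
            payload[f"voxels_{rid}"] = self.region_voxels[rid]
            payload[f"ctrmeans_{rid}"] = np.asarray(
                self.center_stats[rid]["train_col_means"]
            )
            payload[f"ctrgrand_{rid}"] = np.array(
                self.center_stats[rid]["grand_mean"]
            )
        if self.features is not None:
            payload["features"] = self.features
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path: str) -> "KernelStack":
        with np.load(path) as z:
            rids = [int(r) for r in z["region_ids"]]
            return cls(
                kernels={r: z[f"kernel_{r}"] for r in rids},
                norm_constants={r: float(z[f"norm_{r}"]) for r in rids},
                center_stats={
                    r: {
                        "train_col_means": z[f"ctrmeans_{r}"],
                        "grand_mean": float(z[f"ctrgrand_{r}"]),
                    }
                    for r in rids
                },
                train_index=z["train_index"],
                region_voxels={r: z[f"voxels_{r}"] for r in rids},
                features=z["features"] if "features" in z else None,
            )

    def combined(self, weights: dict[int, float]) -> np.ndarray:
        K = np.zeros((self.n_subjects, self.n_subjects))
        for rid, w in weights.items():
            if w != 0.0:
                K += w * self.kernels[rid]
        return K


def build_kernel_stack(
    dataset: VoxelDataset,
    parcellation: Parcellation,
    train_index: np.ndarray,
    confound_model: ConfoundModel | None = None,
    covariates: np.ndarray | None = None,
    keep_features: bool = False,
) -> KernelStack:
    """Residualize -> region kernels -> normalize -> center, train-stat only.

    Regions whose kernel degenerates (zero training variance, e.g. after a
    confound removes all signal) are dropped with a warning; an error is
    raised only if nothing survives.
    """
    train_index = np.asarray(train_index)
    data = np.asarray(dataset.data, dtype=float)
    if confound_model is not None:
        if covariates is None:
            raise ValueError("covariates required when a confound model is given")
        data = residualize_confounds(confound_model, data, covariates)
    kernels: dict[int, np.ndarray] = {}
    norms: dict[int, float] = {}
    stats: dict[int, dict] = {}
    region_voxels: dict[int, np.ndarray] = {}
    feats = np.array(data, copy=True) if keep_features else None
    for rid in parcellation.region_ids:
        cols = parcellation.region_voxels[rid]
        K = compute_region_kernel(data, cols)
        try:
            K, c = normalize_kernel(K, train_index)
        except DegenerateRegionError:
            logger.warning("region %d degenerate after residualization; dropped", rid)
            if feats is not None:
                feats[:, cols] = 0.0
            continue
        K, st = center_kernel(K, train_index)
        kernels[rid] = K
        norms[rid] = c
        stats[rid] = st
        region_voxels[rid] = np.asarray(cols)
        if feats is not None:
            block = feats[:, cols] / np.sqrt(c)
            feats[:, cols] = block - block[train_index].mean(axis=0)
    if not kernels:
        raise ValueError("all regions degenerate; no kernels built")
    return KernelStack(kernels, norms, stats, train_index, region_voxels, feats)
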