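"""Reading, writing and aligning NIfTI images, atlases, masks and subject tables.

The analysis operates on a subjects x voxels matrix assembled from per-subject
3D statistical contrast images that all live on one voxel grid.  Voxel columns
are ordered row-major over the grid (0-based indices), so kernels built from a
given set of images are reproducible bit-for-bit.  No resampling is performed:
images, atlas and mask must share identical dimensions and voxel-to-world
affines; aligning them is a preprocessing responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Grid",
    "VoxelDataset",
    "Parcellation",
    "SubjectTable",
    "GridMismatchError",
    "load_images",
    "load_parcellation",
    "load_subject_table",
    "apply_mask",
    "write_weight_images",
]


class GridMismatchError(ValueError):
    """Raised when an image is not on the reference voxel grid."""


@dataclass(frozen=True)
class Grid:
    """Voxel grid: 3D shape plus voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def matches(self, other: "Grid", atol: float = 0.0) -> bool:
        return self.shape == other.shape and (
            np.array_equal(self.affine, other.affine)
            if atol == 0.0
            else np.allclose(self.affine, other.affine, atol=atol)
        )


@dataclass
class VoxelDataset:
    """Subjects x voxels activation matrix with grid metadata.

    ``voxel_index`` maps each column back to its (i, j, k) voxel coordinate,
    in row-major order over the grid, so weight vectors can be written back
    as 3D images.
    """

    data: np.ndarray  # (n_subjects, n_voxels) float64, all finite
    subject_ids: list[str]
    grid: Grid
    voxel_index: np.ndarray  # (n_voxels, 3) int

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("data rows must match subject_ids")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicated subject_ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in assembled dataset")
        if self.voxel_index.shape != (self.data.shape[1], 3):
            raise ValueError("voxel_index must have one row per data column")
        shp = np.asarray(self.grid.shape)
        if self.voxel_index.size and (
            self.voxel_index.min() < 0 or np.any(self.voxel_index >= shp)
        ):
            raise ValueError("voxel_index coordinates outside grid")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def flat_index(self) -> np.ndarray:
        """Row-major linear index of each column within the grid."""
        return np.ravel_multi_index(self.voxel_index.T, self.grid.shape)


@dataclass
class Parcellation:
    """Integer label volume plus the region -> dataset-column map."""

    labels: np.ndarray  # 3D int volume, 0 = background
    region_table: dict[int, str]  # region id -> name
    region_voxels: dict[int, np.ndarray]  # region id -> column indices

    def __post_init__(self) -> None:
        cols: list[np.ndarray] = list(self.region_voxels.values())
        if cols:
            flat = np.concatenate(cols)
            if len(np.unique(flat)) != len(flat):
                raise ValueError("region_voxels overlap: a voxel in two regions")
        for rid, idx in self.region_voxels.items():
            if len(idx) == 0:
                raise ValueError(f"region {rid} has no voxels")

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_voxels)


@dataclass
class SubjectTable:
    """Per-subject target score and confound covariates."""

    subject_ids: list[str]
    target: np.ndarray  # (n,) score in instrument units
    covariates: np.ndarray  # (n, q), e.g. age, gender(0/1)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != len(self.subject_ids):
            self.covariates = self.covariates.T
        if np.ptp(self.target) == 0:
            raise ValueError("target score is constant across subjects")
        if len(self.target) != len(self.subject_ids):
            raise ValueError("target length must match subject_ids")

    def reorder(self, subject_ids: list[str]) -> "SubjectTable":
        """Align rows to the given subject order (e.g. a VoxelDataset's)."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            idx = [pos[s] for s in subject_ids]
        except KeyError as e:
            raise ValueError(f"subject {e.args[0]!r} missing from table") from None
        return SubjectTable(
            list(subject_ids),
            self.target[idx],
            self.covariates[idx],
            list(self.covariate_names),
        )


def _grid_of(img: nib.Nifti1Image) -> Grid:
    return Grid(tuple(int(s) for s in img.shape[:3]), np.asarray(img.affine))


def load_images(paths: list[str]) -> VoxelDataset:
    """Assemble per-subject 3D images into a subjects x voxels matrix.

    All images must share dimensions and affine.  Columns are restricted to
    voxels that are finite in every subject (a voxel that is NaN/Inf in any
    one image is dropped for all), in row-major grid order.  Subject ids
    default to the file stem of each path.
    """
    if not paths:
        raise ValueError("empty image path list")
    imgs = [nib.load(str(p)) for p in paths]
    ref = _grid_of(imgs[0])
    for p, img in zip(paths, imgs):
        g = _grid_of(img)
        if not g.matches(ref):
            raise GridMismatchError(
                f"image {p} grid {g.shape} does not match reference {ref.shape} "
                "(or affines differ)"
            )
    data = np.stack([np.asarray(img.get_fdata(), dtype=np.float64).ravel(order="C")
                     for img in imgs])
    finite = np.all(np.isfinite(data), axis=0)
    keep = np.flatnonzero(finite)
    coords = np.column_stack(np.unravel_index(keep, ref.shape))
    ids = [_stem(p) for p in paths]
    return VoxelDataset(data[:, keep], ids, ref, coords)


def _stem(path: str) -> str:
    import os

    name = os.path.basename(str(path))
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return os.path.splitext(name)[0]


def load_parcellation(
    path: str,
    dataset: VoxelDataset,
    region_names: dict[int, str] | None = None,
) -> Parcellation:
    """Load an integer-labelled atlas and map regions to dataset columns.

    Regions are the nonzero labels that overlap the dataset's surviving
    voxels; labels must be integer-valued.  Regions whose voxels were all
    dropped from the dataset are omitted with a warning.
    """
    img = nib.load(str(path))
    if not _grid_of(img).matches(dataset.grid):
        raise GridMismatchError(f"atlas {path} is not on the dataset grid")
    vol = np.asarray(img.get_fdata())
    if not np.allclose(vol, np.round(vol)):
        raise ValueError(f"atlas {path} has non-integer labels")
    return parcellation_from_labels(np.round(vol).astype(int), dataset, region_names)


def parcellation_from_labels(
    labels: np.ndarray,
    dataset: VoxelDataset,
    region_names: dict[int, str] | None = None,
) -> Parcellation:
    """Build a Parcellation from an in-memory integer label volume."""
    labels = np.asarray(labels)
    if labels.shape != dataset.grid.shape:
        raise GridMismatchError("label volume shape does not match dataset grid")
    flat = labels.ravel(order="C")[dataset.flat_index()]
    present = np.unique(flat)
    present = present[present != 0]
    if present.size == 0:
        raise ValueError("no nonzero atlas labels overlap the dataset voxels")
    all_labels = np.unique(labels)
    dropped = sorted(set(all_labels[all_labels != 0].tolist()) - set(present.tolist()))
    if dropped:
        logger.warning("atlas regions with no surviving voxels dropped: %s", dropped)
    region_voxels = {int(r): np.flatnonzero(flat == r) for r in present}
    names = region_names or {}
    table = {int(r): names.get(int(r), f"region_{int(r)}") for r in present}
    return Parcellation(labels, table, region_voxels)


def apply_mask(
    dataset: VoxelDataset, parcellation: Parcellation, mask: np.ndarray | str
) -> tuple[VoxelDataset, Parcellation]:
    """Restrict the dataset (and re-derive the parcellation) to mask==1 voxels.

    ``mask`` is a binary volume on the dataset grid, or a path to one.  Used
    for confirmatory analyses restricted to an a-priori region set (e.g. a
    bilateral ventrolateral-prefrontal mask).
    """
    if isinstance(mask, (str,)) or hasattr(mask, "__fspath__"):
        img = nib.load(str(mask))
        if not _grid_of(img).matches(dataset.grid):
            raise GridMismatchError(f"mask {mask} is not on the dataset grid")
        mask = np.asarray(img.get_fdata())
    mask = np.asarray(mask)
    if mask.shape != dataset.grid.shape:
        raise GridMismatchError("mask shape does not match dataset grid")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary (values 0/1)")
    inmask = mask.ravel(order="C")[dataset.flat_index()].astype(bool)
    if not inmask.any():
        raise ValueError("mask removes all dataset voxels")
    keep = np.flatnonzero(inmask)
    sub = VoxelDataset(
        dataset.data[:, keep],
        list(dataset.subject_ids),
        dataset.grid,
        dataset.voxel_index[keep],
    )
    parc = parcellation_from_labels(parcellation.labels, sub, parcellation.region_table)
    return sub, parc


def load_subject_table(
    path: str,
    target_column: str = "score",
    covariate_columns: tuple[str, ...] = ("age", "gender"),
    id_column: str = "subject_id",
) -> tuple[SubjectTable, list[str]]:
    """Read the subject CSV; returns the table and the image paths column.

    Expected columns: subject_id, <target>, covariates, image_path.
    """
    df = pd.read_csv(path)
    missing = [c for c in (id_column, target_column, *covariate_columns) if c not in df]
    if missing:
        raise ValueError(f"subject table {path} missing columns: {missing}")
    table = SubjectTable(
        df[id_column].astype(str).tolist(),
        df[target_column].to_numpy(dtype=float),
        df[list(covariate_columns)].to_numpy(dtype=float),
        list(covariate_columns),
    )
    paths = df["image_path"].astype(str).tolist() if "image_path" in df else []
    return table, paths


def voxel_vector_to_volume(
    values: np.ndarray, dataset: VoxelDataset
) -> np.ndarray:
    """Scatter a per-column vector back into a 3D volume (background 0)."""
    vol = np.zeros(dataset.grid.shape, dtype=float)
    vol.ravel(order="C")[dataset.flat_index()] = values
    return vol


def write_weight_images(
    fit,
    parcellation: Parcellation,
    dataset: VoxelDataset,
    region_path: str,
    voxel_path: str,
) -> None:
    """Write region-weight and voxel-weight volumes as NIfTI images.

    The region image carries each region's learned kernel weight at every one
    of its voxels; the voxel image carries the per-voxel primal weights.
    Background (and unselected regions in the voxel map) are 0.
    """
    from .mkl import extract_weight_maps

    maps = extract_weight_maps(fit, dataset, parcellation)
    region_vec = np.zeros(dataset.n_voxels)
    for rid, cols in parcellation.region_voxels.items():
        region_vec[cols] = maps.region_weights.get(rid, 0.0)
    for path, vec in ((region_path, region_vec), (voxel_path, maps.voxel_weights)):
        vol = voxel_vector_to_volume(vec, dataset)
        nib.save(nib.Nifti1Image(vol.astype(np.float32), dataset.grid.affine), str(path))
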