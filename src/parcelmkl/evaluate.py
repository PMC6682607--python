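"""Nested cross-validation, permutation significance and metrics.

The outer cross-validation loop estimates out-of-sample performance; within
each outer training set an inner loop of the same form selects the SVR
soft-margin parameter C by mean squared error.  Every training-fold
computation (confound regression, kernel statistics, MKL fit) uses only that
fold's training subjects, so each subject is predicted exactly once by a
model that never saw it.

Significance is assessed by permutation: target scores are shuffled across
subjects (images and covariates stay attached to their subjects) and the
entire nested pipeline — confound fits, kernel statistics, inner C selection
— is re-run per permutation.  Because the kernel stacks depend only on
images, covariates and the fold split (never on the targets), stacks are
cached per training fold across permutations; this is an exact reuse, not an
approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

from .kernels import KernelStack, build_kernel_stack, fit_confound_model
from .mkl import MKLFit, predict, simple_mkl_fit
from .nifti import Parcellation, SubjectTable, VoxelDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CVSpec",
    "EvaluationResult",
    "make_folds",
    "inner_select_C",
    "run_nested_cv",
    "permutation_test",
    "pearson_r",
    "mse",
    "bonferroni_threshold",
]

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)


@dataclass
class CVSpec:
    """Cross-validation and solver configuration.

    ``c_grid`` is the candidate set for the SVR soft-margin parameter C,
    selected in the inner loop by mean squared error (ties go to the smallest
    C).  ``seed`` drives the fold assignment (and nothing else here).
    """

    n_outer_folds: int = 3
    n_inner_folds: int = 3
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    seed: int = 0
    epsilon: float = 0.1
    mkl_tol: float = 1e-5
    mkl_max_iter: int = 200
    use_confounds: bool = True
    residualize_target: bool = False
    stratify_folds: bool = False


@dataclass
class EvaluationResult:
    """Pooled out-of-fold predictions and the derived performance metrics."""

    subject_ids: list[str]
    actual: np.ndarray
    predicted: np.ndarray
    r: float
    mse: float
    fold_of_subject: np.ndarray  # outer fold index per subject
    selected_C: list[float]  # per outer fold
    fold_weights: list[dict[int, float]]  # kernel weights per outer fold
    p_r: float | None = None
    p_mse: float | None = None
    null_r: np.ndarray | None = None
    null_mse: np.ndarray | None = None

    @property
    def fold_rankings(self) -> list[list[int]]:
        """Region ranking (weight-descending) within each outer fold."""
        return [
            [r for r, _ in sorted(w.items(), key=lambda kv: (-kv[1], kv[0]))]
            for w in self.fold_weights
        ]

    @property
    def mean_region_weights(self) -> dict[int, float]:
        """Kernel weights averaged over the outer-fold models."""
        from collections import defaultdict

        acc: dict[int, float] = defaultdict(float)
        for w in self.fold_weights:
            for rid, d in w.items():
                acc[rid] += d / len(self.fold_weights)
        return dict(acc)

    @property
    def region_ranking(self) -> list[int]:
        """Consensus ranking: regions ordered by mean kernel weight across
        outer folds (first = largest average contribution)."""
        mw = self.mean_region_weights
        return sorted(mw, key=lambda r: (-mw[r], r))


def pearson_r(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson product-moment correlation between actual and predicted."""
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    if len(actual) != len(predicted):
        raise ValueError("length mismatch")
    if len(actual) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        raise ValueError("undefined correlation: zero variance input")
    return float(_sstats.pearsonr(actual, predicted).statistic)


def mse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared error, in squared target units."""
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    if actual.shape != predicted.shape:
        raise ValueError("length mismatch")
    return float(np.mean((actual - predicted) ** 2))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test significance threshold alpha/n."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def make_folds(n_subjects: int, k: int, seed: int, scores: np.ndarray | None = None,
               stratify: bool = False) -> np.ndarray:
    """Seeded random partition into k near-equal folds; returns fold labels.

    With ``stratify`` the subjects are first ordered by score quantile so
    each fold spans the score range; default is an unstratified shuffle.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n_subjects:
        raise ValueError(f"cannot make {k} folds from {n_subjects} subjects")
    rng = np.random.default_rng(seed)
    labels = np.empty(n_subjects, dtype=int)
    if stratify and scores is not None:
        order = np.argsort(scores, kind="stable")
        # within score-sorted order, deal subjects round-robin with a random
        # rotation per block so assignment is still seed-dependent
        for start in range(0, n_subjects, k):
            block = order[start : start + k]
            labels[block] = rng.permutation(k)[: len(block)]
    else:
        perm = rng.permutation(n_subjects)
        for f, chunk in enumerate(np.array_split(perm, k)):
            labels[chunk] = f
    return labels


def _canonical_folds(subject_ids: list[str], k: int, seed: int,
                     scores: np.ndarray | None = None,
                     stratify: bool = False) -> np.ndarray:
    """Fold labels assigned in subject-id order, so the assignment (and
    hence every downstream number) is invariant to file ordering."""
    order = np.argsort(np.asarray(subject_ids, dtype=object), kind="stable")
    lab_sorted = make_folds(
        len(subject_ids), k, seed,
        scores=None if scores is None else np.asarray(scores)[order],
        stratify=stratify,
    )
    labels = np.empty(len(subject_ids), dtype=int)
    labels[order] = lab_sorted
    return labels


class StackCache:
    """Kernel stacks keyed by training-fold index (targets never enter)."""

    def __init__(self) -> None:
        self._stacks: dict[tuple, KernelStack] = {}

    def get(self, dataset: VoxelDataset, parcellation: Parcellation,
            table: SubjectTable, train_idx: np.ndarray, use_confounds: bool,
            keep_features: bool = False) -> KernelStack:
        key = (tuple(np.asarray(train_idx).tolist()), use_confounds)
        st = self._stacks.get(key)
        if st is None or (keep_features and st.features is None):
            model = None
            cov = None
            if use_confounds and table.covariates.shape[1] > 0:
                # a covariate constant within this training fold carries no
                # confounding information (absorbed by the intercept): drop it
                varying = np.ptp(table.covariates[train_idx], axis=0) > 0
                if not varying.all():
                    names = table.covariate_names or [
                        f"cov{j}" for j in range(table.covariates.shape[1])
                    ]
                    logger.warning(
                        "covariates constant in training fold dropped: %s",
                        [n for n, v in zip(names, varying) if not v],
                    )
                cov_all = table.covariates[:, varying]
                if cov_all.shape[1] > 0:
                    model = fit_confound_model(
                        dataset.data[train_idx], cov_all[train_idx],
                        [n for n, v in zip(table.covariate_names or [], varying) if v]
                        or None,
                    )
                    cov = cov_all
            st = build_kernel_stack(
                dataset, parcellation, train_idx, model, cov,
                keep_features=keep_features,
            )
            self._stacks[key] = st
        return st


def _target_for_fit(table: SubjectTable, train_idx: np.ndarray,
                    spec: CVSpec) -> tuple[np.ndarray, np.ndarray]:
    """Training targets and the full-length comparison targets.

    With ``residualize_target`` the score is regressed on the covariates
    using training-fold coefficients; both fitting and scoring then use the
    residualized score.
    """
    y = table.target
    if not spec.residualize_target or table.covariates.shape[1] == 0:
        return y[train_idx], y
    X = np.column_stack([np.ones(len(y)), table.covariates])
    coef, *_ = np.linalg.lstsq(X[train_idx], y[train_idx], rcond=None)
    resid = y - X @ coef
    return resid[train_idx], resid


def _fit_fold(dataset: VoxelDataset, parcellation: Parcellation,
              table: SubjectTable, train_idx: np.ndarray, C: float,
              spec: CVSpec, cache: StackCache) -> tuple[MKLFit, KernelStack, np.ndarray]:
    stack = cache.get(dataset, parcellation, table, train_idx, spec.use_confounds)
    y_train, y_full = _target_for_fit(table, train_idx, spec)
    fit = simple_mkl_fit(
        stack, y_train, C=C, epsilon=spec.epsilon,
        tol=spec.mkl_tol, max_iter=spec.mkl_max_iter,
    )
    return fit, stack, y_full


def inner_select_C(dataset: VoxelDataset, parcellation: Parcellation,
                   table: SubjectTable, spec: CVSpec,
                   train_index: np.ndarray | None = None,
                   inner_seed: int | None = None,
                   cache: StackCache | None = None) -> float:
    """Select C from ``spec.c_grid`` by inner k-fold CV mean squared error.

    The inner folds live entirely inside ``train_index`` (defaults to all
    subjects).  Duplicated grid values are collapsed; ties break to the
    smallest C.  A singleton grid is returned directly.
    """
    grid = sorted(set(float(c) for c in spec.c_grid))
    if not grid:
        raise ValueError("empty C grid")
    if len(grid) == 1:
        return grid[0]
    if train_index is None:
        train_index = np.arange(dataset.n_subjects)
    train_index = np.asarray(train_index)
    if cache is None:
        cache = StackCache()
    ids = [dataset.subject_ids[i] for i in train_index]
    labels = _canonical_folds(
        ids, spec.n_inner_folds,
        spec.seed if inner_seed is None else inner_seed,
        scores=table.target[train_index], stratify=spec.stratify_folds,
    )
    mean_mse = []
    for C in grid:
        errs = []
        n_failed = 0
        for f in range(spec.n_inner_folds):
            tr = train_index[labels != f]
            te = train_index[labels == f]
            try:
                fit, stack, y_full = _fit_fold(
                    dataset, parcellation, table, tr, C, spec, cache
                )
            except Exception as e:  # noqa: BLE001 - scored as a failed candidate
                logger.warning("inner fold failed for C=%g: %s", C, e)
                n_failed += 1
                continue
            yhat = predict(fit, stack, te)
            errs.append(mse(y_full[te], yhat))
        if n_failed == spec.n_inner_folds:
            mean_mse.append(np.inf)
        else:
            mean_mse.append(float(np.mean(errs)))
    if not np.isfinite(mean_mse).any():
        raise RuntimeError("all inner cross-validation fits failed")
    return grid[int(np.argmin(mean_mse))]


def run_nested_cv(dataset: VoxelDataset, parcellation: Parcellation,
                  table: SubjectTable, spec: CVSpec,
                  cache: StackCache | None = None) -> EvaluationResult:
    """Estimate out-of-sample (r, MSE) by nested cross-validation.

    For each outer fold: select C on the outer-training subjects by inner
    CV, fit confounds + kernels + MKL on them, predict the held-out fold.
    Out-of-fold predictions are pooled over all subjects before computing
    Pearson's r and the MSE.
    """
    table = table.reorder(dataset.subject_ids)
    n = dataset.n_subjects
    if cache is None:
        cache = StackCache()
    labels = _canonical_folds(
        dataset.subject_ids, spec.n_outer_folds, spec.seed,
        scores=table.target, stratify=spec.stratify_folds,
    )
    predicted = np.full(n, np.nan)
    actual = np.full(n, np.nan)
    seen = np.zeros(n, dtype=bool)
    selected: list[float] = []
    weights: list[dict[int, float]] = []
    for f in range(spec.n_outer_folds):
        tr = np.flatnonzero(labels != f)
        te = np.flatnonzero(labels == f)
        try:
            C = inner_select_C(
                dataset, parcellation, table, spec, train_index=tr,
                inner_seed=spec.seed + 1009 * (f + 1), cache=cache,
            )
            fit, stack, y_full = _fit_fold(
                dataset, parcellation, table, tr, C, spec, cache
            )
        except Exception as e:
            raise RuntimeError(f"outer fold {f} failed: {e}") from e
        assert not np.isin(te, fit.train_index).any(), "leakage: test row in training"
        if seen[te].any():
            raise RuntimeError("subject predicted more than once")
        seen[te] = True
        predicted[te] = predict(fit, stack, te)
        actual[te] = y_full[te]
        selected.append(C)
        weights.append(dict(fit.kernel_weights))
    assert seen.all(), "some subjects never predicted"
    return EvaluationResult(
        subject_ids=list(dataset.subject_ids),
        actual=actual,
        predicted=predicted,
        r=pearson_r(actual, predicted),
        mse=mse(actual, predicted),
        fold_of_subject=labels,
        selected_C=selected,
        fold_weights=weights,
    )


def permutation_test(dataset: VoxelDataset, parcellation: Parcellation,
                     table: SubjectTable, spec: CVSpec,
                     n_perm: int = 1000, seed: int = 0,
                     observed: EvaluationResult | None = None) -> EvaluationResult:
    """Permutation significance of the nested-CV model.

    Scores are shuffled across subjects while images and covariates stay
    attached; the full nested pipeline is re-run per permutation.  P-values
    use the add-one convention p = (#{null at least as good} + 1)/(n_perm+1),
    with "as good" meaning null r >= observed r, null MSE <= observed MSE.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    table = table.reorder(dataset.subject_ids)
    cache = StackCache()
    if observed is None:
        observed = run_nested_cv(dataset, parcellation, table, spec, cache=cache)
    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm)
    null_mse = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(len(table.target))
        t_perm = SubjectTable(
            list(table.subject_ids), table.target[perm], table.covariates,
            list(table.covariate_names),
        )
        res = run_nested_cv(dataset, parcellation, t_perm, spec, cache=cache)
        null_r[p] = res.r
        null_mse[p] = res.mse
    observed.null_r = null_r
    observed.null_mse = null_mse
    observed.p_r = float((np.sum(null_r >= observed.r) + 1) / (n_perm + 1))
    observed.p_mse = float((np.sum(null_mse <= observed.mse) + 1) / (n_perm + 1))
    return observed
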