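"""Sparse multiple kernel learning regression (SimpleMKL) over region kernels.

The model is an epsilon-insensitive support vector regression on the combined
kernel K(d) = sum_m d_m K_m, with the region weights d constrained to the
probability simplex (d_m >= 0, sum d_m = 1).  The simplex (L1) constraint
induces sparsity: most regions receive weight exactly 0 and contribute
nothing to predictions, so the nonzero d_m rank the anatomical regions by
their contribution to the model.

The outer problem min_d J(d), with J(d) the optimal SVR dual objective on
K(d), is convex and is minimized by reduced-gradient descent on the simplex
with an Armijo backtracking line search; by Danskin's theorem the gradient at
the current dual solution beta is dJ/dd_m = -1/2 beta^T K_m beta.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning as _SkConvergenceWarning
from sklearn.svm import SVR

try:  # low-overhead path: call the libsvm binding directly (same solver the
    # SVR estimator wraps); fall back to the public estimator if unavailable
    from sklearn.svm import _libsvm as _libsvm_direct

    _libsvm_direct.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - depends on sklearn internals
    _libsvm_direct = None

from .kernels import KernelStack
from .nifti import Parcellation, VoxelDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MKLFit",
    "WeightMaps",
    "ConvergenceWarning",
    "solve_svr_dual",
    "simple_mkl_fit",
    "predict",
    "extract_weight_maps",
]

# relative eigenvalue tolerance below which a kernel counts as PSD
_PSD_RTOL = 1e-8
_PSD_JITTER = 1e-10


class ConvergenceWarning(UserWarning):
    pass


def _check_psd(K: np.ndarray) -> np.ndarray:
    """Validate PSD-ness; tiny negative eigenvalues get a diagonal jitter."""
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kernel matrix is not symmetric")
    w = np.linalg.eigvalsh(K)
    lam_max = max(float(w[-1]), 1.0)
    if w[0] < -_PSD_RTOL * lam_max:
        raise ValueError(f"kernel is not positive semidefinite (min eig {w[0]:.3g})")
    if w[0] < 0:
        K = K + _PSD_JITTER * lam_max * np.eye(K.shape[0])
    return K


def solve_svr_dual(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    epsilon: float,
    tol: float = 1e-8,
    check_psd: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Solve the epsilon-insensitive SVR dual on a precomputed kernel.

    Returns (beta, b, J): dual coefficients beta_i = alpha_i - alpha*_i with
    |beta_i| <= C and sum beta_i = 0, the bias b from the KKT conditions, and
    the optimal dual objective
        J = y^T beta - 1/2 beta^T K beta - epsilon * ||beta||_1.

    ``check_psd=False`` skips the eigenvalue validation, for callers that
    already guarantee positive semidefiniteness (e.g. a simplex combination
    of validated kernels).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    y = np.asarray(y, dtype=np.float64)
    K = _check_psd(K) if check_psd else np.ascontiguousarray(K, dtype=np.float64)
    n = len(y)
    if not np.any(y):
        return np.zeros(n), 0.0, 0.0
    if _libsvm_direct is not None:
        out = _libsvm_direct.fit(
            K, y, svm_type=3, kernel="precomputed", C=C, epsilon=epsilon,
            tol=tol, cache_size=100.0, max_iter=2_000_000,
        )
        support, _, _, sv_coef, rho, _, _, fit_status, n_iter = out
        if fit_status != 0 or int(np.asarray(n_iter).max()) >= 2_000_000:
            raise RuntimeError(
                f"SVR solver did not converge (status {fit_status}, "
                f"{int(np.asarray(n_iter).sum())} iterations)"
            )
        beta = np.zeros(n)
        beta[support] = sv_coef.ravel()
        b = float(rho[0])
    else:  # pragma: no cover - exercised only without the direct binding
        svr = SVR(kernel="precomputed", C=C, epsilon=epsilon, tol=tol,
                  max_iter=2_000_000)
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=_SkConvergenceWarning)
            try:
                svr.fit(K, y)
            except _SkConvergenceWarning as w:  # libsvm hit max_iter
                raise RuntimeError(f"SVR solver did not converge: {w}") from None
        beta = np.zeros(n)
        beta[svr.support_] = svr.dual_coef_.ravel()
        b = float(svr.intercept_[0])
    J = float(y @ beta - 0.5 * beta @ K @ beta - epsilon * np.abs(beta).sum())
    return beta, b, J


@dataclass
class MKLFit:
    """A trained simplex-weighted multiple kernel regression model."""

    kernel_weights: dict[int, float]  # region id -> d_m (simplex)
    dual_coef: np.ndarray  # beta per training subject
    bias: float  # b, in target units
    C: float
    epsilon: float
    target_offset: float  # training mean of the target
    train_index: np.ndarray = field(default_factory=lambda: np.array([], int))
    objective: float = np.nan
    n_iter: int = 0
    converged: bool = True

    @property
    def region_ranking(self) -> list[int]:
        """Regions sorted by kernel weight, largest contribution first."""
        return [r for r, _ in sorted(
            self.kernel_weights.items(), key=lambda kv: (-kv[1], kv[0])
        )]

    @property
    def selected_regions(self) -> list[int]:
        return sorted(r for r, d in self.kernel_weights.items() if d > 0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel_weights": {str(k): v for k, v in self.kernel_weights.items()},
                "dual_coef": self.dual_coef.tolist(),
                "bias": self.bias,
                "C": self.C,
                "epsilon": self.epsilon,
                "target_offset": self.target_offset,
                "train_index": self.train_index.tolist(),
                "objective": self.objective,
                "n_iter": self.n_iter,
                "converged": self.converged,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MKLFit":
        d = json.loads(text)
        return cls(
            kernel_weights={int(k): v for k, v in d["kernel_weights"].items()},
            dual_coef=np.asarray(d["dual_coef"]),
            bias=d["bias"],
            C=d["C"],
            epsilon=d["epsilon"],
            target_offset=d["target_offset"],
            train_index=np.asarray(d["train_index"], dtype=int),
            objective=d["objective"],
            n_iter=d["n_iter"],
            converged=d["converged"],
        )


def _svr_on_weights(
    Ktr: list[np.ndarray], d: np.ndarray, yc: np.ndarray,
    C: float, epsilon: float, svr_tol: float,
) -> tuple[np.ndarray, float, float]:
    Kd = np.zeros((len(yc), len(yc)))
    for w, Km in zip(d, Ktr):
        if w > 0:
            Kd += w * Km
    # a simplex combination of the validated per-region kernels is PSD
    return solve_svr_dual(Kd, yc, C, epsilon, tol=svr_tol, check_psd=False)


def simple_mkl_fit(
    stack: KernelStack,
    y: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
    tol: float = 1e-5,
    max_iter: int = 200,
    svr_tol: float = 1e-8,
) -> MKLFit:
    """Learn simplex kernel weights jointly with the SVR by reduced gradient.

    ``y`` are the targets for the stack's training subjects, in original
    units; they are centered by their mean (stored as ``target_offset``)
    before fitting.  Iterates until the MKL duality gap
    max_m S_m - sum_m d_m S_m (with S_m = 1/2 beta^T K_m beta) falls below
    ``tol`` relative to |J|, or ``max_iter`` is reached (warning; the best
    iterate is returned).
    """
    if C <= 0 or tol <= 0:
        raise ValueError("C and tol must be positive")
    y = np.asarray(y, dtype=float)
    t = stack.train_index
    if len(y) != len(t):
        raise ValueError("y must have one entry per training subject")
    offset = float(y.mean())
    yc = y - offset
    rids = stack.region_ids
    M = len(rids)

    Ktr = [_check_psd(stack.train_block(r)) for r in rids]
    d = np.full(M, 1.0 / M)
    beta, b, J = _svr_on_weights(Ktr, d, yc, C, epsilon, svr_tol)
    n_iter = 0
    converged = M == 1

    for n_iter in range(1, max_iter + 1):
        if M == 1:
            converged = True
            break
        S = np.array([0.5 * beta @ Km @ beta for Km in Ktr])  # = -grad
        gap = float(S.max() - d @ S)
        if gap <= tol * max(abs(J), 1.0):
            converged = True
            break
        grad = -S
        mu = int(np.argmax(d))
        red = grad - grad[mu]
        D = -red
        D[(d <= 0) & (red > 0)] = 0.0
        D[mu] = 0.0
        D[mu] = -D.sum()
        if np.max(np.abs(D)) < 1e-15:
            converged = True
            break

        # walk to successive simplex boundaries while J keeps decreasing
        J_prev = J
        d_best, beta_best, b_best, J_best = d, beta, b, J
        d_cur, D_cur = d.copy(), D.copy()
        for _ in range(M):
            neg = D_cur < -1e-15
            if not neg.any():
                gamma_max = None
                break
            steps = -d_cur[neg] / D_cur[neg]
            gamma_max = float(steps.min())
            d_try = np.clip(d_cur + gamma_max * D_cur, 0.0, None)
            d_try /= d_try.sum()
            beta_t, b_t, J_t = _svr_on_weights(Ktr, d_try, yc, C, epsilon, svr_tol)
            if J_t < J_best - 1e-15:
                d_best, beta_best, b_best, J_best = d_try, beta_t, b_t, J_t
                # zero the components that just hit the boundary, redirect
                hit = np.isclose(d_cur + gamma_max * D_cur, 0.0, atol=1e-14) & neg
                d_cur, D_cur = d_try, D_cur.copy()
                D_cur[hit] = 0.0
                D_cur[mu] = 0.0
                D_cur[mu] = -D_cur.sum()
                if np.max(np.abs(D_cur)) < 1e-15:
                    gamma_max = None
                    break
            else:
                break
        else:
            gamma_max = None

        if gamma_max is not None and J_best >= J_prev - 1e-15:
            # Armijo backtracking between the current point and gamma_max
            gamma = gamma_max
            slope = float(grad @ D_cur)  # directional derivative (negative)
            accepted = False
            for _ in range(30):
                gamma *= 0.5
                d_try = np.clip(d_cur + gamma * D_cur, 0.0, None)
                d_try /= d_try.sum()
                beta_t, b_t, J_t = _svr_on_weights(
                    Ktr, d_try, yc, C, epsilon, svr_tol
                )
                if J_t <= J_best + 1e-4 * gamma * slope:
                    d_best, beta_best, b_best, J_best = d_try, beta_t, b_t, J_t
                    accepted = True
                    break
            if not accepted and J_best >= J_prev - 1e-15:
                converged = True  # no descent available: at a KKT point
                d, beta, b, J = d_best, beta_best, b_best, J_best
                break
        elif gamma_max is not None:
            # boundary walk improved; optionally refine with backtracking
            gamma = gamma_max
            for _ in range(10):
                gamma *= 0.5
                d_try = np.clip(d_cur + gamma * D_cur, 0.0, None)
                d_try /= d_try.sum()
                beta_t, b_t, J_t = _svr_on_weights(
                    Ktr, d_try, yc, C, epsilon, svr_tol
                )
                if J_t < J_best - 1e-15:
                    d_best, beta_best, b_best, J_best = d_try, beta_t, b_t, J_t
                else:
                    break

        if J_best > J_prev + 1e-10 * max(abs(J_prev), 1.0):
            logger.warning(
                "MKL objective increased (%.6g -> %.6g); solver issue", J_prev, J_best
            )
        d, beta, b, J = d_best, beta_best, b_best, J_best
        d = np.where(d < 1e-12, 0.0, d)
        d = d / d.sum()

    if not converged:
        warnings.warn(
            f"SimpleMKL did not reach tol={tol} in {max_iter} iterations; "
            "returning best iterate",
            ConvergenceWarning,
        )
    weights = {rid: float(w) for rid, w in zip(rids, d)}
    return MKLFit(
        kernel_weights=weights,
        dual_coef=beta,
        bias=b,
        C=C,
        epsilon=epsilon,
        target_offset=offset,
        train_index=np.asarray(t),
        objective=J,
        n_iter=n_iter,
        converged=converged,
    )


def predict(fit: MKLFit, stack: KernelStack, rows: np.ndarray) -> np.ndarray:
    """Predict scores for the given subject rows of a kernel stack.

    The stack must have been built with the fit's training index so its
    normalization/centering statistics match.  Prediction is the kernel form
        yhat_t = sum_i beta_i sum_m d_m K_m(t, i) + b + target_offset.
    """
    if set(fit.kernel_weights) - set(stack.kernels):
        raise ValueError("region set mismatch between fit and kernel stack")
    rows = np.asarray(rows)
    n = len(fit.dual_coef)
    acc = np.zeros((len(rows), n))
    for rid, w in fit.kernel_weights.items():
        if w > 0:
            acc += w * stack.cross_block(rid, rows)
    return acc @ fit.dual_coef + fit.bias + fit.target_offset


@dataclass
class WeightMaps:
    """Primal interpretation of an MKL fit.

    ``region_weights`` are the simplex kernel weights d_m; ``voxel_weights``
    are the per-voxel primal weights w_v = d_m * sum_i beta_i xt_{i,v} in the
    transformed (residualized/scaled/centered) feature space, zero outside
    selected regions.
    """

    region_weights: dict[int, float]
    voxel_weights: np.ndarray


def extract_weight_maps(
    fit: MKLFit, dataset: VoxelDataset, parcellation: Parcellation,
    stack: KernelStack | None = None,
) -> WeightMaps:
    """Compute region and voxel weight vectors for a fit.

    If ``stack`` (built with ``keep_features=True``) is not given, it is
    rebuilt from the dataset/parcellation without confounds.  Predictions
    from the returned voxel weights (dot product with a subject's transformed
    features, plus bias and offset) equal the kernel-form predictions.
    """
    if stack is None or stack.features is None:
        from .kernels import build_kernel_stack

        stack = build_kernel_stack(
            dataset, parcellation, fit.train_index, keep_features=True
        )
    feats = stack.features
    voxel_w = np.zeros(feats.shape[1])
    train_feats = feats[stack.train_index]
    for rid, dm in fit.kernel_weights.items():
        if dm > 0 and rid in stack.region_voxels:
            cols = stack.region_voxels[rid]
            voxel_w[cols] = dm * (fit.dual_coef @ train_feats[:, cols])
    return WeightMaps(dict(fit.kernel_weights), voxel_w)
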