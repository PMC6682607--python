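"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the SVR dual oracle
is a generic box-constrained quadratic program solved with SLSQP, kernels
are computed with explicit double loops, and centering is done on explicit
feature vectors.
"""

import numpy as np
from scipy.optimize import minimize


def svr_dual_qp(K, y, C, epsilon):
    """Solve the epsilon-SVR dual as a generic QP over (alpha, alpha*).

    maximize  -1/2 (a-a*)^T K (a-a*) + y^T (a-a*) - eps * sum(a+a*)
    s.t.      sum(a-a*) = 0,  0 <= a, a* <= C

    Returns (beta, bias, objective) with beta = a - a*.
    """
    n = len(y)
    K = np.asarray(K, float)
    y = np.asarray(y, float)

    def neg_obj(z):
        a, astar = z[:n], z[n:]
        beta = a - astar
        return 0.5 * beta @ K @ beta - y @ beta + epsilon * (a + astar).sum()

    def neg_grad(z):
        a, astar = z[:n], z[n:]
        beta = a - astar
        g = K @ beta - y
        return np.concatenate([g + epsilon, -g + epsilon])

    cons = {"type": "eq",
            "fun": lambda z: z[:n].sum() - z[n:].sum(),
            "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}
    res = minimize(
        neg_obj, np.zeros(2 * n), jac=neg_grad, method="SLSQP",
        bounds=[(0.0, C)] * (2 * n), constraints=[cons],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    a, astar = res.x[:n], res.x[n:]
    beta = a - astar
    # bias from KKT: free (margin) support vectors sit exactly on the tube
    f0 = K @ beta
    free_pos = (beta > 1e-6) & (beta < C - 1e-6)
    free_neg = (beta < -1e-6) & (beta > -C + 1e-6)
    cands = []
    cands.extend(y[free_pos] - f0[free_pos] - epsilon)
    cands.extend(y[free_neg] - f0[free_neg] + epsilon)
    b = float(np.mean(cands)) if cands else 0.0
    return beta, b, float(-neg_obj(res.x))


def gram_double_loop(X, cols):
    """Element-wise dot-product Gram matrix oracle."""
    Xr = np.asarray(X, float)[:, cols]
    n = Xr.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = sum(Xr[i, v] * Xr[j, v] for v in range(Xr.shape[1]))
    return K


def centered_feature_kernel(X, train_rows):
    """Kernel of explicitly train-mean-centered feature vectors."""
    X = np.asarray(X, float)
    Xc = X - X[train_rows].mean(axis=0)
    return Xc @ Xc.T
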