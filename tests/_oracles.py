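"""Independent slow oracles used only by the test suite.

These deliberately share no code with the package: the penalized
precision-matrix problem is handed to a generic smooth solver (L-BFGS-B)
after splitting each off-diagonal entry into positive and negative parts,
which turns the L1 penalty into a smooth bound-constrained objective.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def oracle_glasso(S: np.ndarray, lam: float, tol: float = 1e-12) -> np.ndarray:
    """Solve min_Theta -logdet(Theta) + tr(S Theta) + lam*||offdiag(Theta)||_1.

    Parameterization: diagonal entries free (positive), each upper off-diagonal
    entry split as P - N with P, N >= 0 so the objective is smooth.
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    iu = np.triu_indices(p, k=1)
    m = len(iu[0])

    def unpack(x):
        d = x[:p]
        off = x[p : p + m] - x[p + m :]
        T = np.zeros((p, p))
        T[iu] = off
        T = T + T.T
        T[np.diag_indices(p)] = d
        return T

    # the L1 norm counts both triangles, so each split pair carries 2*lam
    def fun(x):
        T = unpack(x)
        w = np.linalg.eigvalsh(T)
        if w.min() <= 1e-10:
            # infeasible (not PD): large value, line search will backtrack
            return 1e12

        sign, logdet = np.linalg.slogdet(T)
        return -logdet + np.trace(S @ T) + 2.0 * lam * (x[p:].sum())

    def grad(x):
        T = unpack(x)
        # gradient of -logdet + tr(S T) wrt T is S - inv(T)
        G = S - np.linalg.inv(T)
        gd = np.diag(G)
        goff = 2.0 * G[iu]  # symmetric: each off-diag appears twice
        return np.concatenate([gd, goff + 2.0 * lam, -goff + 2.0 * lam])

    x0 = np.concatenate([1.0 / np.diag(S), np.zeros(2 * m)])
    bounds = [(1e-8, None)] * p + [(0.0, None)] * (2 * m)
    res = minimize(
        fun,
        x0,
        jac=grad,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 10000, "ftol": tol, "gtol": 1e-12},
    )
    return unpack(res.x)
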