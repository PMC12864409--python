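"""Coordinate-descent graphical lasso core.

Solves, for a symmetric PSD input matrix ``S`` (typically a correlation
matrix) and penalty ``lam``::

    maximize_Theta  log det(Theta) - trace(S @ Theta) - lam * ||offdiag(Theta)||_1

over symmetric positive-definite matrices.  Only off-diagonal entries are
penalized, so at the optimum the estimated covariance ``W = Theta^{-1}``
satisfies ``diag(W) == diag(S)`` exactly.

The solver is the block coordinate-descent algorithm of Friedman, Hastie &
Tibshirani (one lasso regression per column of ``W``), JIT-compiled with
numba so that full penalty paths can be re-run thousands of times inside
bootstrap loops.  The core accepts a per-entry penalty matrix, which also
yields the support-constrained Gaussian MLE (zero penalty on a given edge
set, effectively infinite elsewhere) used for EBIC model scoring.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BIG = 1e12  # penalty standing in for +inf: forces an exact structural zero


@njit(cache=True)
def _lasso_cd(V, s, b, lam, tol, max_inner):
    """Minimize 0.5 b'Vb - s'b + sum_j lam[j]*|b_j| by cyclic coordinate descent.

    ``b`` is updated in place (warm start) and returned.
    """
    p = b.shape[0]
    for _ in range(max_inner):
        dmax = 0.0
        for j in range(p):
            g = s[j]
            for k in range(p):
                if k != j:
                    g -= V[j, k] * b[k]
            if g > lam[j]:
                bj = (g - lam[j]) / V[j, j]
            elif g < -lam[j]:
                bj = (g + lam[j]) / V[j, j]
            else:
                bj = 0.0
            d = abs(bj - b[j])
            if d > dmax:
                dmax = d
            b[j] = bj
        if dmax < tol:
            break
    return b


@njit(cache=True)
def _glasso_core(S, Lam, B, tol, max_iter, max_inner):
    """One glasso solve with per-entry penalties.

    ``B`` ((p-1) x p) holds warm-start lasso coefficients and is updated in
    place.  Returns (Theta, W, n_iter, converged).
    """
    p = S.shape[0]
    W = S.copy()  # off-diagonal penalty only: diag(W) stays diag(S)

    # scale for the convergence criterion
    off_mean = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                off_mean += abs(S[i, j])
                cnt += 1
    off_mean = off_mean / cnt if cnt > 0 else 1.0
    thresh = tol * max(off_mean, 1e-12)

    idx = np.empty(p - 1, np.int64)
    V = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    lam12 = np.empty(p - 1)
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        dmax = 0.0
        for col in range(p):
            k = 0
            for i in range(p):
                if i != col:
                    idx[k] = i
                    k += 1
            for a in range(p - 1):
                s12[a] = S[idx[a], col]
                lam12[a] = Lam[idx[a], col]
                for bcol in range(p - 1):
                    V[a, bcol] = W[idx[a], idx[bcol]]
            bvec = B[:, col]
            _lasso_cd(V, s12, bvec, lam12, tol * 0.1, max_inner)
            for a in range(p - 1):
                w_new = 0.0
                for bcol in range(p - 1):
                    w_new += V[a, bcol] * bvec[bcol]
                d = abs(w_new - W[idx[a], col])
                if d > dmax:
                    dmax = d
                W[idx[a], col] = w_new
                W[col, idx[a]] = w_new
        if dmax < thresh:
            converged = True
            break

    # recover the precision matrix from W and the lasso coefficients
    Theta = np.zeros((p, p))
    for col in range(p):
        k = 0
        for i in range(p):
            if i != col:
                idx[k] = i
                k += 1
        bvec = B[:, col]
        denom = W[col, col]
        for a in range(p - 1):
            denom -= W[idx[a], col] * bvec[a]
        t22 = 1.0 / denom
        Theta[col, col] = t22
        for a in range(p - 1):
            Theta[idx[a], col] = -bvec[a] * t22
    # symmetrize (column solves agree only up to convergence tolerance)
    for i in range(p):
        for j in range(i + 1, p):
            m = 0.5 * (Theta[i, j] + Theta[j, i])
            # preserve exact zeros produced by soft-thresholding
            if Theta[i, j] == 0.0 or Theta[j, i] == 0.0:
                m = 0.0
            Theta[i, j] = m
            Theta[j, i] = m
    return Theta, W, n_iter, converged


@njit(cache=True)
def _glasso_path_core(S, lambdas, tol, max_iter, max_inner):
    """Solve glasso at each penalty in ``lambdas`` (descending), warm-started.

    Returns (Thetas: (L,p,p), converged: (L,) bool).
    """
    p = S.shape[0]
    L = lambdas.shape[0]
    Thetas = np.empty((L, p, p))
    ok = np.empty(L, np.bool_)
    B = np.zeros((p - 1, p))
    Lam = np.empty((p, p))
    for li in range(L):
        for i in range(p):
            for j in range(p):
                Lam[i, j] = lambdas[li]
        Theta, W, n_iter, conv = _glasso_core(S, Lam, B, tol, max_iter, max_inner)
        Thetas[li] = Theta
        ok[li] = conv
    return Thetas, ok


class GlassoConvergenceError(RuntimeError):
    """Raised when coordinate descent fails to reach tolerance."""

    def __init__(self, gap: float, max_iter: int):
        self.gap = gap
        self.max_iter = max_iter
        super().__init__(
            f"graphical lasso did not converge in {max_iter} iterations "
            f"(duality gap {gap:.3e})"
        )


def _duality_gap(S: np.ndarray, Theta: np.ndarray, lam: float) -> float:
    p = S.shape[0]
    off = np.abs(Theta).sum() - np.abs(np.diag(Theta)).sum()
    return float(np.trace(S @ Theta) + lam * off - p)


def _check_input(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    return S


def glasso_fit(
    S: np.ndarray,
    lam: float,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    max_inner: int = 500,
) -> np.ndarray:
    """L1-penalized precision-matrix estimate (off-diagonal penalty).

    Parameters
    ----------
    S : symmetric positive semidefinite matrix (correlation or covariance).
    lam : non-negative penalty on off-diagonal absolute entries.

    Returns
    -------
    Theta : symmetric positive-definite precision estimate.
    """
    S = _check_input(S)
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    p = S.shape[0]
    offdiag = S - np.diag(np.diag(S))
    if p == 1 or lam >= np.abs(offdiag).max():
        # fully shrunk: diagonal precision
        return np.diag(1.0 / np.diag(S))
    B = np.zeros((p - 1, p))
    Lam = np.full((p, p), float(lam))
    Theta, W, n_iter, conv = _glasso_core(S, Lam, B, tol, max_iter, max_inner)
    if not conv:
        raise GlassoConvergenceError(_duality_gap(S, Theta, lam), max_iter)
    return Theta


def glasso_path(
    S: np.ndarray,
    lambdas: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    max_inner: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started glasso along a descending penalty sequence.

    Returns (Thetas, converged) with ``Thetas[i]`` the precision estimate at
    ``lambdas[i]``.
    """
    S = _check_input(S)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambdas must be non-increasing for warm starts")
    Thetas, ok = _glasso_path_core(S, lambdas, tol, max_iter, max_inner)
    if not ok.all():
        bad = int(np.flatnonzero(~ok)[0])
        raise GlassoConvergenceError(
            _duality_gap(S, Thetas[bad], float(lambdas[bad])), max_iter
        )
    return Thetas, ok


def constrained_mle(
    S: np.ndarray,
    support: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    max_inner: int = 500,
) -> np.ndarray:
    """Gaussian MLE of the precision matrix with a fixed zero pattern.

    ``support`` is a boolean matrix: True entries are free, False off-diagonal
    entries are constrained to exactly zero.  Implemented as a glasso solve
    with zero penalty on the support and an effectively infinite penalty
    elsewhere (soft-thresholding then keeps the excluded entries at exact
    zero).
    """
    S = _check_input(S)
    p = S.shape[0]
    support = np.asarray(support, dtype=bool)
    if support.shape != (p, p):
        raise ValueError("support must match S in shape")
    if not np.array_equal(support, support.T):
        raise ValueError("support must be symmetric")
    Lam = np.where(support, 0.0, _BIG)
    np.fill_diagonal(Lam, 0.0)
    B = np.zeros((p - 1, p))
    Theta, W, n_iter, conv = _glasso_core(S, Lam, B, tol, max_iter, max_inner)
    if not conv:
        raise GlassoConvergenceError(_duality_gap(S, Theta, 0.0), max_iter)
    return Theta
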