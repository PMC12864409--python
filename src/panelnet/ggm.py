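"""Regularized partial-correlation network estimation.

Pipeline: redundancy screen (optional) -> correlation matrix -> graphical
lasso over a log-spaced penalty path -> extended-BIC model selection ->
partial-correlation edge weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._glasso import (
    GlassoConvergenceError,
    constrained_mle,
    glasso_fit,
    glasso_path,
)

__all__ = [
    "GGMNetwork",
    "RedundancyReport",
    "correlation_matrix",
    "glasso_fit",
    "precision_to_partial",
    "ebic_score",
    "estimate_network",
    "redundancy_screen",
]

_EDGE_EPS = 1e-10  # entries below this magnitude count as structural zeros


@dataclass
class GGMNetwork:
    """Undirected partial-correlation network with its selection path."""

    node_labels: list[str]
    weights: np.ndarray
    lambda_selected: float
    ebic_selected: float
    gamma: float
    n: int
    cor_method: str
    path: list[tuple[float, int, float]] = field(default_factory=list)

    def edge_count(self) -> int:
        return int((np.abs(np.triu(self.weights, 1)) > _EDGE_EPS).sum())

    def edge_list(self) -> pd.DataFrame:
        ii, jj = np.triu_indices(len(self.node_labels), k=1)
        keep = np.abs(self.weights[ii, jj]) > _EDGE_EPS
        return pd.DataFrame(
            {
                "node_a": [self.node_labels[i] for i in ii[keep]],
                "node_b": [self.node_labels[j] for j in jj[keep]],
                "weight": self.weights[ii, jj][keep],
            }
        )

    def to_matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_labels, columns=self.node_labels)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "node_labels": self.node_labels,
            "weights": self.weights.tolist(),
            "lambda_selected": self.lambda_selected,
            "ebic_selected": self.ebic_selected,
            "gamma": self.gamma,
            "n": self.n,
            "cor_method": self.cor_method,
            "path": [list(rec) for rec in self.path],
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GGMNetwork":
        obj = json.loads(Path(path).read_text())
        return cls(
            node_labels=obj["node_labels"],
            weights=np.array(obj["weights"]),
            lambda_selected=obj["lambda_selected"],
            ebic_selected=obj["ebic_selected"],
            gamma=obj["gamma"],
            n=obj["n"],
            cor_method=obj["cor_method"],
            path=[tuple(rec) for rec in obj["path"]],
        )


@dataclass
class RedundancyReport:
    """Outcome of the node-redundancy (goldbricker-style) screen."""

    candidate_pairs: pd.DataFrame  # node_a, node_b, zero_order_r, prop_significant
    flagged_pairs: list[tuple[str, str]]
    r_min: float
    alpha: float
    prop_threshold: float


def correlation_matrix(
    X: pd.DataFrame | np.ndarray, method: str = "pearson"
) -> np.ndarray:
    """Sample correlation matrix after listwise deletion.

    Guaranteed symmetric with unit diagonal; eigenvalues below zero but
    within 1e-10 are clipped (correlation matrices are PSD up to rounding),
    harder violations raise.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    df = pd.DataFrame(X)
    df = df.dropna(axis=0)
    if len(df) < 3:
        raise ValueError("need at least 3 complete rows")
    sds = df.std(ddof=1)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance column(s): {zero_var}")
    vals = df.to_numpy(dtype=float)
    if method == "spearman":
        vals = stats.rankdata(vals, axis=0)
    S = np.corrcoef(vals, rowvar=False)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    w, V = np.linalg.eigh(S)
    if w.min() < -1e-10:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {w.min():.3e})")
    if w.min() < 0:
        S = (V * np.clip(w, 0, None)) @ V.T
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 1.0)
    return S


def precision_to_partial(Theta: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix: -Theta_ij/sqrt(Theta_ii*Theta_jj)."""
    Theta = np.asarray(Theta, dtype=float)
    if not np.allclose(Theta, Theta.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    w = np.linalg.eigvalsh(Theta)
    if w.min() <= 0:
        raise ValueError(
            f"precision matrix not positive definite (min eigenvalue {w.min():.3e})"
        )
    d = np.sqrt(np.diag(Theta))
    R = -Theta / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    return R


def ebic_score(loglik: float, n: int, E: int, p: int, gamma: float = 0.5) -> float:
    """Extended BIC: -2*loglik + E*log(n) + 4*gamma*E*log(p)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if E < 0 or gamma < 0:
        raise ValueError("E and gamma must be non-negative")
    return -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def gaussian_loglik(S: np.ndarray, Theta: np.ndarray, n: int) -> float:
    """Profile Gaussian log-likelihood (n/2)(logdet Theta - tr(S Theta))."""
    sign, logdet = np.linalg.slogdet(Theta)
    return 0.5 * n * (logdet - float(np.trace(S @ Theta)))


def estimate_network(
    X: pd.DataFrame,
    *,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    cor_method: str = "pearson",
    selection_loglik: str = "refit",
    refit_weights: bool = True,
) -> GGMNetwork:
    """EBIC-selected graphical-lasso network from one wave of scores.

    The penalty path runs log-spaced from lambda_max (the smallest penalty
    giving an empty graph) down to lambda_max * lambda_min_ratio; the model
    minimizing the EBIC is selected, ties resolved toward the sparser
    (larger-penalty) model.

    By default the EBIC log-likelihood is evaluated at the unpenalized MLE
    constrained to each candidate's zero pattern ("refit"), so that candidate
    graphs are compared by their support rather than by the shrinkage level
    of the penalized fit; ``selection_loglik="penalized"`` scores the
    penalized estimates directly.  With ``refit_weights=True`` (default) the
    reported edge weights are likewise the constrained-MLE partial
    correlations on the selected support, removing lasso shrinkage bias from
    the nonzero edges; ``refit_weights=False`` reports the penalized
    (shrunken) weights.
    """
    if selection_loglik not in ("refit", "penalized"):
        raise ValueError(f"unknown selection_loglik {selection_loglik!r}")
    df = pd.DataFrame(X).dropna(axis=0)
    labels = [str(c) for c in df.columns]
    n = len(df)
    p = len(labels)
    S = correlation_matrix(df, method=cor_method)

    lam_max = np.abs(S - np.diag(np.diag(S))).max()
    if lam_max <= 0:
        weights = np.zeros((p, p))
        score = ebic_score(gaussian_loglik(S, np.eye(p), n), n, 0, p, gamma)
        return GGMNetwork(labels, weights, 0.0, score, gamma, n, cor_method, [])
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    Thetas, _ = glasso_path(S, lambdas)

    path: list[tuple[float, int, float]] = []
    best = None
    score_cache: dict[bytes, float] = {}
    iu = np.triu_indices(p, k=1)
    for lam, Theta in zip(lambdas, Thetas):
        support = np.abs(Theta) > _EDGE_EPS
        E = int(support[iu].sum())
        if selection_loglik == "refit":
            key = support.tobytes()
            if key not in score_cache:
                Theta_score = constrained_mle(S, support)
                ll = gaussian_loglik(S, Theta_score, n)
                score_cache[key] = ebic_score(ll, n, E, p, gamma)
            score = score_cache[key]
        else:
            score = ebic_score(gaussian_loglik(S, Theta, n), n, E, p, gamma)
        path.append((float(lam), E, float(score)))
        # strict improvement required: ties stay with the larger penalty
        if best is None or score < best[2] - 1e-12:
            best = (float(lam), Theta, float(score))
    lam_sel, Theta_sel, ebic_sel = best
    if refit_weights:
        Theta_sel = constrained_mle(S, np.abs(Theta_sel) > _EDGE_EPS)
    weights = precision_to_partial(Theta_sel)
    return GGMNetwork(labels, weights, lam_sel, ebic_sel, gamma, n, cor_method, path)


def _steiger_z(r_ak: float, r_bk: float, r_ab: float, n: int) -> float:
    """Steiger's z for two dependent overlapping correlations sharing node k.

    Uses Fisher-transformed correlations and the back-transformed average
    correlation in the covariance term.
    """
    clip = lambda r: np.clip(r, -0.999999, 0.999999)
    z1 = np.arctanh(clip(r_ak))
    z2 = np.arctanh(clip(r_bk))
    rbar = np.tanh(0.5 * (z1 + z2))
    num = r_ab * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_ab**2)
    s = num / (1 - rbar**2) ** 2
    return float(np.sqrt(n - 3) * (z1 - z2) / np.sqrt(2 - 2 * s))


def redundancy_screen(
    X: pd.DataFrame,
    *,
    r_min: float = 0.50,
    alpha: float = 0.05,
    prop_threshold: float = 0.25,
) -> RedundancyReport:
    """Flag candidate-redundant node pairs (goldbricker-style screen).

    A pair whose zero-order correlation reaches ``r_min`` is flagged as
    redundant when fewer than ``prop_threshold`` of its correlations with the
    remaining nodes differ significantly (dependent overlapping-correlations
    z-test at level ``alpha``).
    """
    df = pd.DataFrame(X).dropna(axis=0)
    labels = [str(c) for c in df.columns]
    if len(labels) < 3:
        raise ValueError("redundancy screen needs at least 3 nodes")
    if len(df) < 20:
        raise ValueError("redundancy screen needs at least 20 complete rows")
    n = len(df)
    R = correlation_matrix(df)
    rows = []
    flagged = []
    p = len(labels)
    for a in range(p):
        for b in range(a + 1, p):
            if abs(R[a, b]) < r_min:
                continue
            n_sig = 0
            others = [k for k in range(p) if k not in (a, b)]
            for k in others:
                z = _steiger_z(R[a, k], R[b, k], R[a, b], n)
                if 2 * stats.norm.sf(abs(z)) < alpha:
                    n_sig += 1
            prop = n_sig / len(others)
            rows.append((labels[a], labels[b], float(R[a, b]), prop))
            if prop < prop_threshold:
                flagged.append((labels[a], labels[b]))
    candidates = pd.DataFrame(
        rows, columns=["node_a", "node_b", "zero_order_r", "prop_significant"]
    )
    return RedundancyReport(candidates, flagged, r_min, alpha, prop_threshold)
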