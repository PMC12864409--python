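"""Synthetic two-wave symptom panels with known ground truth.

The generator emulates a 10-node substance-use-disorder panel: three craving
subscales (D1-D3, Likert sums), three compulsive-seeking subscales (O1-O3),
three impulsivity subscales (B1-B3) and one stop-signal reaction time node
(SSRT, milliseconds).  Baseline scores arise from a latent Gaussian graphical
model with a sparse precision matrix; the second wave follows a linear
autoregressive + cross-lagged model on the standardized latent scale, with
attrition applied completely at random.  Because the precision matrix and
the lagged coefficient matrix are known, every downstream estimator can be
checked by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

NODE_LABELS = ["D1", "D2", "D3", "O1", "O2", "O3", "B1", "B2", "B3", "SSRT"]
WAVE_LABELS = ("T0", "T1")


@dataclass(frozen=True)
class MarginalSpec:
    """Monotone transform from the standardized latent scale to a score scale.

    kind="likert": y = low + (high-low) * Phi(z)**skew, optionally rounded to
    integers — emulates bounded, possibly skewed questionnaire subscale sums
    (skew > 1 pushes mass toward the lower bound, i.e. right skew).
    kind="linear": y = mean + sd*z (clipped below at ``low`` if given) — for
    quasi-continuous reaction-time scores.
    kind="identity": y = z, used by recovery tests.
    """

    kind: str = "identity"
    low: float = 0.0
    high: float = 1.0
    skew: float = 1.0
    integer: bool = False
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if self.kind not in ("identity", "likert", "linear"):
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        if self.kind == "likert" and not self.low < self.high:
            raise ValueError("marginal range requires low < high")
        if self.kind == "linear" and self.sd <= 0:
            raise ValueError("linear marginal requires sd > 0")


def ordinalize(values: np.ndarray, spec: MarginalSpec) -> np.ndarray:
    """Apply a monotone marginal transform to standardized values.

    Rank order is preserved before any integer rounding; outputs of a
    "likert" spec always lie within [low, high].
    """
    z = np.asarray(values, dtype=float)
    if spec.kind == "identity":
        return z.copy()
    if spec.kind == "linear":
        y = spec.mean + spec.sd * z
        if spec.low is not None:
            y = np.maximum(y, spec.low)
        return np.round(y) if spec.integer else y
    # likert
    u = norm.cdf(z) ** spec.skew
    y = spec.low + (spec.high - spec.low) * u
    if spec.integer:
        y = np.round(y)
    return np.clip(y, spec.low, spec.high)


@dataclass
class SimulationTruth:
    """Ground truth for a two-wave panel simulation.

    Omega is the baseline precision matrix (its implied partial correlations
    are the true undirected network); Bmat holds lagged coefficients on the
    standardized latent scale with rows = wave-1 predictor, columns = wave-2
    outcome, diagonal = autoregressive effects.
    """

    node_labels: list[str]
    Omega: np.ndarray
    Bmat: np.ndarray
    noise_sd: np.ndarray
    marginals: dict[str, MarginalSpec]
    n0: int = 361
    retention: float = 209 / 361
    seed: int = 0

    def __post_init__(self):
        self.Omega = np.asarray(self.Omega, dtype=float)
        self.Bmat = np.asarray(self.Bmat, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        p = len(self.node_labels)
        if self.Omega.shape != (p, p) or self.Bmat.shape != (p, p):
            raise ValueError("Omega and Bmat must be p x p")
        if not np.allclose(self.Omega, self.Omega.T, atol=1e-12):
            raise ValueError("Omega must be symmetric")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")

    @property
    def partial_correlations(self) -> np.ndarray:
        """True partial-correlation matrix implied by Omega (zero diagonal)."""
        d = np.sqrt(np.diag(self.Omega))
        R = -self.Omega / np.outer(d, d)
        np.fill_diagonal(R, 0.0)
        return R

    def wave1_correlation(self) -> np.ndarray:
        """Correlation of the standardized wave-1 latent scores."""
        Sigma = np.linalg.inv(self.Omega)
        d = np.sqrt(np.diag(Sigma))
        return Sigma / np.outer(d, d)

    def wave2_latent_sd(self) -> np.ndarray:
        """Model-implied SD of each wave-2 latent score before transforms."""
        R = self.wave1_correlation()
        var = np.einsum("ik,jk,ij->k", self.Bmat, self.Bmat, R) + self.noise_sd**2
        return np.sqrt(var)

    def standardized_lagged_matrix(self) -> np.ndarray:
        """Lagged coefficients after standardizing the wave-2 outcomes.

        These are the population values a node-wise regression on z-scored
        data estimates; equals Bmat when each wave-2 latent variance is 1.
        """
        return self.Bmat / self.wave2_latent_sd()[None, :]

    # ---- persistence -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "node_labels": self.node_labels,
            "Omega": self.Omega.tolist(),
            "Bmat": self.Bmat.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "marginals": {k: asdict(v) for k, v in self.marginals.items()},
            "n0": self.n0,
            "retention": self.retention,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            node_labels=obj["node_labels"],
            Omega=np.array(obj["Omega"]),
            Bmat=np.array(obj["Bmat"]),
            noise_sd=np.array(obj["noise_sd"]),
            marginals={k: MarginalSpec(**v) for k, v in obj["marginals"].items()},
            n0=obj["n0"],
            retention=obj["retention"],
            seed=obj["seed"],
        )


@dataclass
class SymptomPanel:
    """Two-wave score table with an attrition mask.

    scores has shape (n_subjects, n_nodes, 2); unobserved wave-2 entries are
    NaN and flagged in ``observed``.
    """

    subject_ids: np.ndarray
    scores: np.ndarray
    observed: np.ndarray
    node_labels: list[str] = field(default_factory=lambda: list(NODE_LABELS))
    wave_labels: tuple[str, str] = WAVE_LABELS

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        if len(np.unique(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject IDs")
        n, p, w = self.scores.shape
        if w != 2 or p != len(self.node_labels):
            raise ValueError("scores must be (n, nodes, 2)")
        if not self.observed[:, 0].all():
            raise ValueError("every subject must be observed at wave 1")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def wave_frame(self, wave: str) -> pd.DataFrame:
        """Complete-case score table for one wave (subjects as index)."""
        if wave not in self.wave_labels:
            raise ValueError(f"unknown wave {wave!r}")
        w = self.wave_labels.index(wave)
        mask = self.observed[:, w]
        return pd.DataFrame(
            self.scores[mask, :, w],
            index=pd.Index(self.subject_ids[mask], name="subject_id"),
            columns=self.node_labels,
        )

    def completers(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Wave-1 and wave-2 score tables restricted to both-wave completers."""
        mask = self.observed.all(axis=1)
        idx = pd.Index(self.subject_ids[mask], name="subject_id")
        x0 = pd.DataFrame(self.scores[mask, :, 0], index=idx, columns=self.node_labels)
        x1 = pd.DataFrame(self.scores[mask, :, 1], index=idx, columns=self.node_labels)
        return x0, x1

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for w, wave in enumerate(self.wave_labels):
            mask = self.observed[:, w]
            df = pd.DataFrame(self.scores[mask, :, w], columns=self.node_labels)
            df.insert(0, "wave", wave)
            df.insert(0, "subject_id", self.subject_ids[mask])
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _default_partial_correlations() -> np.ndarray:
    """Sparse baseline partial-correlation pattern.

    Strong within-instrument edges (craving D1-D2, obsessive thinking O1-O2,
    impulsivity B1-B3) and a handful of cross-instrument links; 10 of 45
    possible edges are nonzero.
    """
    p = len(NODE_LABELS)
    idx = {lbl: i for i, lbl in enumerate(NODE_LABELS)}
    edges = {
        ("D1", "D2"): 0.45,
        ("O1", "O2"): 0.45,
        ("B1", "B3"): 0.40,
        ("O1", "O3"): 0.35,
        ("D1", "O2"): 0.32,
        ("D3", "O3"): 0.30,
        ("B1", "B2"): 0.20,
        ("D2", "D3"): 0.15,
        ("O2", "B1"): -0.15,
        ("B2", "SSRT"): 0.15,
    }
    R = np.zeros((p, p))
    for (a, b), r in edges.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


def _default_lagged_matrix() -> np.ndarray:
    """Lagged coefficients: dominant autoregressive diagonal plus sparse
    cross-lagged effects, including protective (negative) paths from
    resistance to thoughts (O3) onto impulsivity."""
    p = len(NODE_LABELS)
    idx = {lbl: i for i, lbl in enumerate(NODE_LABELS)}
    B = np.zeros((p, p))
    diag = [0.50, 0.45, 0.40, 0.50, 0.45, 0.40, 0.50, 0.45, 0.40, 0.35]
    np.fill_diagonal(B, diag)
    cross = {
        ("D2", "D1"): 0.25,
        ("O3", "B1"): -0.20,
        ("O3", "B3"): -0.18,
        ("O1", "B1"): 0.18,
    }
    for (src, dst), b in cross.items():
        B[idx[src], idx[dst]] = b
    return B


def default_marginals() -> dict[str, MarginalSpec]:
    """Instrument-scale defaults.

    Craving subscales (7-point Likert items: D1 seven items, D2 four, D3 two)
    are right-skewed integer sums; obsessive-seeking subscales (5-point items:
    O1 six, O2 four, O3 three) mildly skewed; impulsivity subscales (ten
    4-point items each) approximately symmetric; SSRT a normal reaction time
    (mean 260 ms, sd 40 ms).
    """
    lik = lambda lo, hi, sk: MarginalSpec("likert", low=lo, high=hi, skew=sk, integer=True)
    return {
        "D1": lik(7, 49, 2.2),
        "D2": lik(4, 28, 2.2),
        "D3": lik(2, 14, 1.8),
        "O1": lik(6, 30, 1.3),
        "O2": lik(4, 20, 1.3),
        "O3": lik(3, 15, 1.3),
        "B1": lik(10, 40, 1.0),
        "B2": lik(10, 40, 1.0),
        "B3": lik(10, 40, 1.0),
        "SSRT": MarginalSpec("linear", mean=260.0, sd=40.0, low=50.0),
    }


def identity_marginals() -> dict[str, MarginalSpec]:
    """Pass-through marginals (latent scale), used for parameter recovery."""
    return {lbl: MarginalSpec("identity") for lbl in NODE_LABELS}


def make_default_truth(
    seed: int = 0,
    *,
    n0: int = 361,
    retention: float = 209 / 361,
    marginals: dict[str, MarginalSpec] | None = None,
    noise_sd: np.ndarray | float | None = None,
) -> SimulationTruth:
    """Fixed, documented ground truth for the default 10-node panel.

    The baseline network has six edges with |partial r| >= 0.30 and 78%
    structural zeros; the lagged matrix has autoregressive effects in
    [0.35, 0.50] and four cross-lagged effects with |b| >= 0.15 (one block of
    negative, protective paths).  Unless overridden, per-node innovation SDs
    are chosen so each wave-2 latent score has unit variance, making Bmat
    directly comparable to standardized regression estimates.
    """
    R = _default_partial_correlations()
    Omega = np.eye(len(NODE_LABELS)) - R
    B = _default_lagged_matrix()
    Sigma = np.linalg.inv(Omega)
    d = np.sqrt(np.diag(Sigma))
    Rz = Sigma / np.outer(d, d)
    explained = np.einsum("ik,jk,ij->k", B, B, Rz)
    if noise_sd is None:
        ns = np.sqrt(np.maximum(1.0 - explained, 1e-6))
    else:
        ns = np.broadcast_to(np.asarray(noise_sd, float), (len(NODE_LABELS),)).copy()
    return SimulationTruth(
        node_labels=list(NODE_LABELS),
        Omega=Omega,
        Bmat=B,
        noise_sd=ns,
        marginals=default_marginals() if marginals is None else dict(marginals),
        n0=n0,
        retention=retention,
        seed=seed,
    )


def simulate_panel(truth: SimulationTruth, *, dropout: str = "mcar") -> SymptomPanel:
    """Draw a two-wave panel from the generative model.

    Wave-1 latent scores come from N(0, Omega^{-1}); wave-2 latent scores are
    Bmat' applied to the standardized wave-1 scores plus Gaussian innovation,
    then standardized by their model-implied SD.  Marginal transforms are
    applied last.  Attrition retains round(n0*retention) subjects, by default
    completely at random; ``dropout="score_dependent"`` retains subjects with
    probability decreasing in their wave-1 craving score.
    """
    w = np.linalg.eigvalsh(truth.Omega)
    if w.min() <= 0:
        raise ValueError(
            f"Omega is not positive definite (smallest eigenvalue {w.min():.3e})"
        )
    if dropout not in ("mcar", "score_dependent"):
        raise ValueError(f"unknown dropout mechanism {dropout!r}")

    rng = np.random.default_rng(truth.seed)
    p = len(truth.node_labels)
    n0 = truth.n0
    Sigma = np.linalg.inv(truth.Omega)
    L = np.linalg.cholesky(Sigma)
    z1 = rng.standard_normal((n0, p)) @ L.T
    z1_std = z1 / np.sqrt(np.diag(Sigma))

    z2 = z1_std @ truth.Bmat + rng.standard_normal((n0, p)) * truth.noise_sd
    z2_std = z2 / truth.wave2_latent_sd()

    scores = np.empty((n0, p, 2))
    for j, lbl in enumerate(truth.node_labels):
        spec = truth.marginals[lbl]
        scores[:, j, 0] = ordinalize(z1_std[:, j], spec)
        scores[:, j, 1] = ordinalize(z2_std[:, j], spec)

    n_keep = int(round(n0 * truth.retention))
    if dropout == "mcar":
        keep = rng.choice(n0, size=n_keep, replace=False)
    else:
        # higher baseline craving (D1) -> higher dropout probability
        craving = z1_std[:, truth.node_labels.index("D1")]
        wts = np.exp(-0.5 * craving)
        keep = rng.choice(n0, size=n_keep, replace=False, p=wts / wts.sum())
    observed = np.zeros((n0, 2), dtype=bool)
    observed[:, 0] = True
    observed[keep, 1] = True
    scores[~observed[:, 1], :, 1] = np.nan

    return SymptomPanel(
        subject_ids=np.array([f"S{i:04d}" for i in range(n0)]),
        scores=scores,
        observed=observed,
        node_labels=list(truth.node_labels),
        wave_labels=WAVE_LABELS,
    )
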