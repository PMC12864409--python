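"""Cross-lagged panel network (CLPN) estimation.

Each wave-2 node is regressed on all ten wave-1 nodes with LASSO; predictors
and outcome are z-standardized on the completer sample, the penalty is chosen
by 10-fold cross-validated mean squared error with a fold assignment shared
across the ten outcome regressions.  The resulting directed coefficient
matrix W has autoregressive effects on its diagonal and cross-lagged effects
off it; reported cross-lagged edges are those exceeding an absolute 0.1
threshold (the threshold filters the reported list only, never W itself).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .simulate import SymptomPanel


@dataclass
class CLPNNetwork:
    """Directed lagged network: W[i, j] = effect of wave-1 node i on wave-2 node j."""

    node_labels: list[str]
    W: np.ndarray
    lambda_per_outcome: dict[str, float]
    n: int
    report_threshold: float = 0.1

    @property
    def autoregressive(self) -> pd.Series:
        return pd.Series(np.diag(self.W), index=self.node_labels, name="autoregressive")

    @property
    def in_ei(self) -> pd.Series:
        off = self.W - np.diag(np.diag(self.W))
        return pd.Series(off.sum(axis=0), index=self.node_labels, name="in_ei")

    @property
    def out_ei(self) -> pd.Series:
        off = self.W - np.diag(np.diag(self.W))
        return pd.Series(off.sum(axis=1), index=self.node_labels, name="out_ei")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "node_labels": self.node_labels,
            "W": self.W.tolist(),
            "lambda_per_outcome": self.lambda_per_outcome,
            "n": self.n,
            "report_threshold": self.report_threshold,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CLPNNetwork":
        obj = json.loads(Path(path).read_text())
        return cls(
            node_labels=obj["node_labels"],
            W=np.array(obj["W"]),
            lambda_per_outcome=obj["lambda_per_outcome"],
            n=obj["n"],
            report_threshold=obj["report_threshold"],
        )


def _zscore_frame(df: pd.DataFrame) -> np.ndarray:
    vals = df.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [str(df.columns[i]) for i in zero]
        raise ValueError(f"zero-variance node(s): {names}")
    return (vals - mu) / sd


def fit_clpn(
    panel: SymptomPanel | tuple[pd.DataFrame, pd.DataFrame],
    *,
    n_folds: int = 10,
    seed: int = 0,
    report_threshold: float = 0.1,
    n_alphas: int = 100,
) -> CLPNNetwork:
    """Fit the directed lagged network on both-wave completers.

    Accepts either a SymptomPanel (completers extracted internally) or an
    already-aligned (wave-1, wave-2) pair of score tables.
    """
    if isinstance(panel, SymptomPanel):
        x0, x1 = panel.completers()
    else:
        x0, x1 = panel
        if list(x0.columns) != list(x1.columns) or len(x0) != len(x1):
            raise ValueError("wave tables must share columns and row count")
    labels = [str(c) for c in x0.columns]
    n = len(x0)
    if n < 50:
        raise ValueError("CLPN needs at least 50 completers")
    if n_folds > n:
        raise ValueError("more folds than completers")

    Z0 = _zscore_frame(x0)
    Z1 = _zscore_frame(x1)

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(Z0))  # shared across the ten outcome regressions

    p = len(labels)
    W = np.zeros((p, p))
    lam: dict[str, float] = {}
    for j, lbl in enumerate(labels):
        model = LassoCV(
            cv=iter(folds), alphas=n_alphas, fit_intercept=False, max_iter=50000
        )
        model.fit(Z0, Z1[:, j])
        W[:, j] = model.coef_
        lam[lbl] = float(model.alpha_)
    return CLPNNetwork(
        node_labels=labels, W=W, lambda_per_outcome=lam, n=n,
        report_threshold=report_threshold,
    )


def reported_edges(model: CLPNNetwork) -> pd.DataFrame:
    """Directed edge list: thresholded cross-lagged edges plus all
    autoregressive effects (unthresholded), with signs."""
    rows = []
    p = len(model.node_labels)
    for i in range(p):
        for j in range(p):
            w = model.W[i, j]
            if i == j:
                rows.append((model.node_labels[i], model.node_labels[j], w, "autoregressive"))
            elif abs(w) > model.report_threshold:
                rows.append((model.node_labels[i], model.node_labels[j], w, "cross_lagged"))
    df = pd.DataFrame(rows, columns=["from", "to", "weight", "type"])
    df["sign"] = np.sign(df["weight"]).astype(int)
    return df


def temporal_ei(model: CLPNNetwork) -> pd.DataFrame:
    """Signed in- and out-expected-influence per node (diagonal excluded)."""
    return pd.DataFrame(
        {"node": model.node_labels, "in_ei": model.in_ei.values, "out_ei": model.out_ei.values}
    )
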