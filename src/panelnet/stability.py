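"""Bootstrap accuracy and case-dropping stability for estimated networks.

Edge-weight accuracy uses a nonparametric bootstrap (rows resampled with
replacement, the full estimation pipeline re-run each time, empirical
2.5/97.5% quantile intervals).  Centrality stability uses the case-dropping
bootstrap: at each drop proportion q, subsamples of size round(n*(1-q)) are
drawn without replacement and the correlation between subsample and
full-sample centralities is recorded; the CS coefficient is the largest q at
which, with the stated confidence, those correlations stay above the
threshold at every proportion up to q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import centrality_table
from .ggm import estimate_network

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))
_MAX_REDRAWS = 1000


@dataclass
class EdgeBootstrapTable:
    """Per-edge bootstrap summary (all node pairs, including zero estimates)."""

    table: pd.DataFrame  # node_a, node_b, estimate, boot_mean, ci_lower, ci_upper
    B: int
    n: int
    redraws: int


@dataclass
class StabilityResult:
    """Case-dropping bootstrap output for one or more centrality indices."""

    drop_grid: tuple[float, ...]
    correlations: dict[str, pd.DataFrame]  # index -> columns (drop, correlation)
    cs: dict[str, float]
    corr_threshold: float = 0.7
    confidence_level: float = 0.95
    dropped_grid_points: tuple[float, ...] = field(default_factory=tuple)


def _estimate(X: pd.DataFrame, estimator_kwargs: dict) -> "np.ndarray":
    return estimate_network(X, **estimator_kwargs).weights


def bootstrap_edges(
    X: pd.DataFrame,
    *,
    B: int = 1000,
    seed: int = 0,
    estimator_kwargs: dict | None = None,
) -> EdgeBootstrapTable:
    """Nonparametric bootstrap of edge weights with full model re-selection.

    Replicates that produce a zero-variance column are redrawn (counted in
    ``redraws``).
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    df = pd.DataFrame(X).dropna(axis=0)
    n = len(df)
    if n < 30:
        raise ValueError("need at least 30 complete rows for the bootstrap")
    estimator_kwargs = estimator_kwargs or {}
    net = estimate_network(df, **estimator_kwargs)
    p = len(net.node_labels)
    ii, jj = np.triu_indices(p, k=1)

    rng = np.random.default_rng(seed)
    vals = df.to_numpy(dtype=float)
    boots = np.empty((B, len(ii)))
    redraws = 0
    b = 0
    while b < B:
        rows = rng.integers(0, n, size=n)
        sub = pd.DataFrame(vals[rows], columns=df.columns)
        try:
            W = _estimate(sub, estimator_kwargs)
        except ValueError:
            redraws += 1
            if redraws > _MAX_REDRAWS:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        boots[b] = W[ii, jj]
        b += 1

    table = pd.DataFrame(
        {
            "node_a": [net.node_labels[i] for i in ii],
            "node_b": [net.node_labels[j] for j in jj],
            "estimate": net.weights[ii, jj],
            "boot_mean": boots.mean(axis=0),
            "ci_lower": np.quantile(boots, 0.025, axis=0),
            "ci_upper": np.quantile(boots, 0.975, axis=0),
        }
    )
    return EdgeBootstrapTable(table=table, B=B, n=n, redraws=redraws)


def _subset_correlation(full: np.ndarray, sub: np.ndarray) -> float:
    """Pearson correlation across nodes; 0 when either vector is constant."""
    if full.std() == 0 or sub.std() == 0:
        return 0.0
    return float(np.corrcoef(full, sub)[0, 1])


def case_dropping_correlations(
    X: pd.DataFrame,
    *,
    indices: tuple[str, ...] = ("strength", "expected_influence"),
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B_per_drop: int = 200,
    seed: int = 0,
    estimator_kwargs: dict | None = None,
) -> tuple[dict[str, pd.DataFrame], tuple[float, ...], tuple[float, ...]]:
    """Subsample-vs-full centrality correlations at each drop proportion.

    Returns (correlations per index, usable grid, dropped grid points).
    """
    df = pd.DataFrame(X).dropna(axis=0)
    n = len(df)
    if n < 50:
        raise ValueError("case-dropping bootstrap needs at least 50 complete rows")
    if any(q <= 0 or q > 0.75 for q in drop_grid):
        raise ValueError("drop proportions must lie in (0, 0.75]")
    estimator_kwargs = estimator_kwargs or {}
    full_net = estimate_network(df, **estimator_kwargs)
    p = len(full_net.node_labels)
    full_tab = centrality_table(full_net)
    full_vals = {idx: full_tab[idx].to_numpy() for idx in indices}

    rng = np.random.default_rng(seed)
    vals = df.to_numpy(dtype=float)
    records: dict[str, list[tuple[float, float]]] = {idx: [] for idx in indices}
    usable, dropped = [], []
    for q in drop_grid:
        m = int(round(n * (1 - q)))
        if m < p + 1:
            warnings.warn(f"drop proportion {q} leaves too few rows; skipped")
            dropped.append(q)
            continue
        usable.append(q)
        done = 0
        redraws = 0
        while done < B_per_drop:
            rows = rng.choice(n, size=m, replace=False)
            sub = pd.DataFrame(vals[rows], columns=df.columns)
            try:
                net = estimate_network(sub, **estimator_kwargs)
            except ValueError:
                redraws += 1
                if redraws > _MAX_REDRAWS:
                    raise RuntimeError("too many degenerate subsamples")
                continue
            with warnings.catch_warnings():
                # empty subsample networks make centralities constant (zero)
                warnings.simplefilter("ignore", UserWarning)
                tab = centrality_table(net)
            for idx in indices:
                records[idx].append(
                    (q, _subset_correlation(full_vals[idx], tab[idx].to_numpy()))
                )
            done += 1
    corr = {
        idx: pd.DataFrame(records[idx], columns=["drop", "correlation"])
        for idx in indices
    }
    return corr, tuple(usable), tuple(dropped)


def cs_from_correlations(
    correlations: pd.DataFrame,
    *,
    corr_threshold: float = 0.7,
    confidence: float = 0.95,
) -> float:
    """CS coefficient from a table of (drop, correlation) records.

    The largest drop proportion q such that at every grid point q' <= q the
    (1-confidence) quantile of the correlations is at least the threshold;
    0.0 when even the smallest proportion fails.
    """
    cs = 0.0
    for q in sorted(correlations["drop"].unique()):
        vals = correlations.loc[correlations["drop"] == q, "correlation"]
        if np.quantile(vals, 1 - confidence) >= corr_threshold:
            cs = float(q)
        else:
            break
    return cs


def cs_coefficient(
    X: pd.DataFrame,
    *,
    index: str = "expected_influence",
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B_per_drop: int = 200,
    corr_threshold: float = 0.7,
    confidence: float = 0.95,
    seed: int = 0,
    estimator_kwargs: dict | None = None,
) -> StabilityResult:
    """Correlation-stability coefficient for one centrality index.

    Field benchmarks: CS below 0.25 indicates an unstable centrality order,
    above 0.5 a stable one.
    """
    corr, usable, dropped = case_dropping_correlations(
        X,
        indices=(index,),
        drop_grid=drop_grid,
        B_per_drop=B_per_drop,
        seed=seed,
        estimator_kwargs=estimator_kwargs,
    )
    cs = cs_from_correlations(
        corr[index], corr_threshold=corr_threshold, confidence=confidence
    )
    return StabilityResult(
        drop_grid=usable,
        correlations=corr,
        cs={index: cs},
        corr_threshold=corr_threshold,
        confidence_level=confidence,
        dropped_grid_points=dropped,
    )


def network_stability(
    X: pd.DataFrame,
    *,
    indices: tuple[str, ...] = ("strength", "expected_influence"),
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B_per_drop: int = 200,
    corr_threshold: float = 0.7,
    confidence: float = 0.95,
    seed: int = 0,
    estimator_kwargs: dict | None = None,
) -> StabilityResult:
    """Case-dropping stability for several indices from one subsample stream."""
    corr, usable, dropped = case_dropping_correlations(
        X,
        indices=indices,
        drop_grid=drop_grid,
        B_per_drop=B_per_drop,
        seed=seed,
        estimator_kwargs=estimator_kwargs,
    )
    cs = {
        idx: cs_from_correlations(
            corr[idx], corr_threshold=corr_threshold, confidence=confidence
        )
        for idx in indices
    }
    return StabilityResult(
        drop_grid=usable,
        correlations=corr,
        cs=cs,
        corr_threshold=corr_threshold,
        confidence_level=confidence,
        dropped_grid_points=dropped,
    )
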