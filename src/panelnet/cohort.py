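"""Descriptive summaries and paired two-wave comparisons.

The comparison of a node between waves uses a paired t-test when the paired
differences pass a Shapiro-Wilk normality check, and the Wilcoxon
signed-rank test otherwise (zero differences dropped, mid-ranks for ties,
continuity-corrected normal approximation above n=25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SymptomPanel


def describe(panel: SymptomPanel, wave: str) -> pd.DataFrame:
    """Per-node summary for one wave: median, quartiles (linear
    interpolation), mean and SD on complete cases."""
    df = panel.wave_frame(wave)
    if df.empty:
        raise ValueError(f"no observations at wave {wave!r}")
    out = pd.DataFrame(
        {
            "node": df.columns,
            "n": len(df),
            "median": df.median().values,
            "q25": df.quantile(0.25).values,
            "q75": df.quantile(0.75).values,
            "mean": df.mean().values,
            "sd": df.std(ddof=1).values,
        }
    )
    return out


@dataclass
class PairedComparison:
    node: str
    n_pairs: int
    summary_t0: dict
    summary_t1: dict
    normality_p: float | None
    test_used: str | None  # "paired_t" | "wilcoxon_signed_rank" | None
    statistic: float | None
    p_value: float | None
    degenerate: bool = False
    # raw signed-rank sums, populated for the Wilcoxon branch
    w_plus: float | None = None
    w_minus: float | None = None


def _summary(x: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "median": float(np.median(x)),
        "q25": float(np.quantile(x, 0.25)),
        "q75": float(np.quantile(x, 0.75)),
    }


def signed_rank_sums(diff: np.ndarray) -> tuple[float, float]:
    """W+ and W- rank sums of the nonzero paired differences (mid-ranks)."""
    d = diff[diff != 0]
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), float(ranks[d < 0].sum())


def paired_compare(
    x0,
    x1,
    *,
    node: str = "",
    alpha_normality: float = 0.05,
) -> PairedComparison:
    """Compare paired measurements between the two waves.

    Differences are taken as wave2 - wave1.  The Shapiro-Wilk p-value on the
    differences selects the branch: paired t when p >= alpha_normality,
    Wilcoxon signed-rank otherwise.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x0.shape != x1.shape or x0.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    ok = ~(np.isnan(x0) | np.isnan(x1))
    x0, x1 = x0[ok], x1[ok]
    n = len(x0)
    if n < 10:
        raise ValueError("need at least 10 complete pairs")
    diff = x1 - x0
    base = dict(node=node, n_pairs=n, summary_t0=_summary(x0), summary_t1=_summary(x1))

    if np.all(diff == 0):
        return PairedComparison(
            **base, normality_p=None, test_used=None, statistic=None,
            p_value=None, degenerate=True,
        )

    norm_p = float(stats.shapiro(diff).pvalue)
    if norm_p >= alpha_normality:
        res = stats.ttest_rel(x1, x0)
        return PairedComparison(
            **base, normality_p=norm_p, test_used="paired_t",
            statistic=float(res.statistic), p_value=float(res.pvalue),
        )

    w_plus, w_minus = signed_rank_sums(diff)
    nz = int((diff != 0).sum())
    method = "exact" if nz <= 25 and len(np.unique(np.abs(diff[diff != 0]))) == nz else "approx"
    res = stats.wilcoxon(
        diff, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return PairedComparison(
        **base, normality_p=norm_p, test_used="wilcoxon_signed_rank",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        w_plus=w_plus, w_minus=w_minus,
    )


def compare_waves(panel: SymptomPanel, *, alpha_normality: float = 0.05) -> pd.DataFrame:
    """Completer-sample paired comparison for every node (wave 2 vs wave 1)."""
    x0, x1 = panel.completers()
    rows = []
    for node in panel.node_labels:
        r = paired_compare(
            x0[node].to_numpy(), x1[node].to_numpy(), node=node,
            alpha_normality=alpha_normality,
        )
        s0, s1 = r.summary_t0, r.summary_t1
        if r.test_used == "paired_t":
            t0s = f"{s0['mean']:.2f} ± {s0['sd']:.2f}"
            t1s = f"{s1['mean']:.2f} ± {s1['sd']:.2f}"
        else:
            t0s = f"{s0['median']:.2f} ({s0['q25']:.2f}, {s0['q75']:.2f})"
            t1s = f"{s1['median']:.2f} ({s1['q25']:.2f}, {s1['q75']:.2f})"
        rows.append(
            (node, r.n_pairs, t0s, t1s, r.test_used, r.statistic, r.p_value, r.degenerate)
        )
    return pd.DataFrame(
        rows,
        columns=["node", "n_pairs", "summary_t0", "summary_t1", "test", "statistic", "p_value", "degenerate"],
    )
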