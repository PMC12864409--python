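"""Node centrality for undirected partial-correlation networks.

Two indices: strength (sum of absolute incident edge weights) and one-step
expected influence (sum of signed incident edge weights).  Standardized
columns are z-scores across the nodes of one network, the convention used
for centrality plots.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ggm import GGMNetwork


def _node_index(network: GGMNetwork, node: str) -> int:
    try:
        return network.node_labels.index(node)
    except ValueError:
        raise KeyError(f"unknown node {node!r}") from None


def strength(network: GGMNetwork, node: str) -> float:
    """Sum of absolute weights of edges incident to ``node``."""
    i = _node_index(network, node)
    return float(np.abs(network.weights[i]).sum() - abs(network.weights[i, i]))


def expected_influence(network: GGMNetwork, node: str) -> float:
    """Sum of signed weights of edges incident to ``node`` (one-step EI)."""
    i = _node_index(network, node)
    return float(network.weights[i].sum() - network.weights[i, i])


def centrality_table(network: GGMNetwork) -> pd.DataFrame:
    """Raw and z-standardized strength and expected influence per node.

    Columns: node, strength, expected_influence, z_strength,
    z_expected_influence.  If an index is constant across nodes its z-column
    is set to zero (with a warning).
    """
    labels = network.node_labels
    if len(labels) < 2:
        raise ValueError("centrality table needs at least 2 nodes")
    s = np.array([strength(network, v) for v in labels])
    ei = np.array([expected_influence(network, v) for v in labels])

    def zscore(x: np.ndarray, name: str) -> np.ndarray:
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn(f"{name} constant across nodes; z-scores set to 0")
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    return pd.DataFrame(
        {
            "node": labels,
            "strength": s,
            "expected_influence": ei,
            "z_strength": zscore(s, "strength"),
            "z_expected_influence": zscore(ei, "expected_influence"),
        }
    )
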