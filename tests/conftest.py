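import numpy as np
import pytest
from hypothesis import settings

import panelnet as pn

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_truth():
    """Study-scale ground truth: n0=361, retention 209/361, instrument marginals."""
    return pn.make_default_truth(1)


@pytest.fixture(scope="session")
def study_panel(default_truth):
    return pn.simulate_panel(default_truth)


@pytest.fixture(scope="session")
def latent_truth():
    """Large identity-marginal truth for parameter-recovery checks."""
    return pn.make_default_truth(2, n0=2000, marginals=pn.identity_marginals())


@pytest.fixture(scope="session")
def latent_panel(latent_truth):
    return pn.simulate_panel(latent_truth)


@pytest.fixture(scope="session")
def latent_network(latent_panel):
    return pn.estimate_network(latent_panel.wave_frame("T0"))


def make_network(edges: dict[tuple[str, str], float], labels: list[str]) -> pn.GGMNetwork:
    """Small helper: a GGMNetwork from an explicit edge dictionary."""
    p = len(labels)
    idx = {v: i for i, v in enumerate(labels)}
    W = np.zeros((p, p))
    for (a, b), w in edges.items():
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return pn.GGMNetwork(
        node_labels=list(labels), weights=W, lambda_selected=0.1,
        ebic_selected=0.0, gamma=0.5, n=100, cor_method="pearson", path=[],
    )
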