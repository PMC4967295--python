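import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from fmodscreen import (SyntheticScenario, WeightedGeneNetwork, generate,
                        threshold_by_quantile)
from fmodscreen.disease import pathway_member_set
from fmodscreen.screen import ScreenConfig


@pytest.fixture
def toy_net():
    """Path A-B-C-D plus an isolated node E."""
    return WeightedGeneNetwork(
        [("A", "B", 0.9), ("B", "C", 0.8), ("C", "D", 0.7)],
        nodes=["A", "B", "C", "D", "E"])


def random_network(rng: np.random.Generator, n_nodes: int = 50,
                   edge_prob: float = 0.15) -> WeightedGeneNetwork:
    genes = [f"g{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((genes[i], genes[j], float(rng.uniform(0.05, 1.0))))
    return WeightedGeneNetwork(edges, nodes=genes)


@pytest.fixture(scope="session")
def bundle():
    """One high-signal synthetic study, shared across tests."""
    return generate(SyntheticScenario(seed=11))


@pytest.fixture(scope="session")
def thresholded(bundle):
    net, thr = threshold_by_quantile(bundle.network, 0.05)
    return net


@pytest.fixture(scope="session")
def pathway_genes(bundle):
    return pathway_member_set(bundle.pathways, 0.05)


def study_config(seed: int, **overrides) -> ScreenConfig:
    """The screen configuration matched to the default synthetic study:
    a coarse m-grid bracketing the planted module size and a k-grid
    matched to the module's neighbor count."""
    kw = dict(m_values=[8, 25, 80], k_step=10, k_floor=10, k_window=15,
              n_reps=1000, n_reps_auc=200, seed=seed)
    kw.update(overrides)
    return ScreenConfig(**kw)
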