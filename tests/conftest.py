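import numpy as np
import pandas as pd
import pytest

from netpsych import (NODE_LABELS, WeightedNetwork, reference_network,
                      sample_reference_scores)


@pytest.fixture(scope="session")
def ref_net() -> WeightedNetwork:
    """The published signed reference network (12 nodes, 2 communities)."""
    return reference_network()


@pytest.fixture(scope="session")
def ref_scores_small() -> pd.DataFrame:
    """Continuous subscale scores at the study's screened sample size."""
    return sample_reference_scores(560, seed=2024)


def make_net(edges, labels=None, communities=None) -> WeightedNetwork:
    """Small network helper: edges as (label_a, label_b, weight)."""
    if labels is None:
        labels = sorted({a for a, _, _ in edges} | {b for _, b, _ in edges})
    if communities is None:
        communities = {lab: "all2" if i % 2 else "all1"
                       for i, lab in enumerate(labels)}
    idx = {lab: i for i, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    for a, b, val in edges:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = val
    return WeightedNetwork(labels=list(labels), weights=w,
                           communities=communities)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
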