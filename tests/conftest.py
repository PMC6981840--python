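import numpy as np
import pandas as pd
import pytest

from coexrewire import simdata, preprocess
from coexrewire.coexnet import SignedNetwork
from coexrewire.containers import LabeledDataset

import networkx as nx


def make_network(nodes, edges, sign="positive", threshold=0.1, state="NC"):
    """A SignedNetwork from explicit (u, v[, weight]) tuples."""
    g = nx.Graph(sign=sign, threshold=threshold, state=state)
    g.add_nodes_from(nodes)
    for e in edges:
        u, v = e[0], e[1]
        w = e[2] if len(e) > 2 else (0.5 if sign == "positive" else -0.5)
        g.add_edge(u, v, weight=w)
    return SignedNetwork(g, sign=sign, threshold=threshold, state=state)


def labeled_dataset(config: simdata.SimConfig):
    """Simulate, merge diagnoses, and de-log: the standard pipeline entry."""
    matrix, diagnoses, truth = simdata.simulate_expression(config)
    meta = preprocess.sample_meta_from_ids(matrix.samples)
    labels = preprocess.assign_diagnosis(meta, diagnoses)
    dataset = LabeledDataset(preprocess.delog(matrix), labels)
    return dataset, truth


def random_linear_matrix(rng, n_probes=100, n_samples=30):
    """A linear-scale matrix whose probes straddle the filter thresholds."""
    from coexrewire.containers import ExpressionMatrix, LINEAR

    mean_log2 = rng.uniform(4, 10, size=n_probes)
    sd_log2 = rng.uniform(0.3, 2.5, size=n_probes)
    vals = 2.0 ** (
        mean_log2[:, None] + sd_log2[:, None] * rng.standard_normal((n_probes, n_samples))
    )
    probes = [f"P{i:04d}" for i in range(n_probes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    return ExpressionMatrix(
        pd.DataFrame(vals, index=probes, columns=samples), scale=LINEAR
    )


@pytest.fixture(scope="session")
def demo_fixture(tmp_path_factory):
    """On-disk demo fixture (expression + diagnosis + truth), written once."""
    out = tmp_path_factory.mktemp("demo")
    cfg = simdata.demo_scenario(seed=1)
    matrix, diagnoses, truth = simdata.simulate_expression(cfg)
    simdata.write_fixture(out, matrix, diagnoses, truth)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
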