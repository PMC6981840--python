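"""Per-state Pearson correlation matrices and signed, thresholded networks.

For each diagnostic state the pairwise Pearson correlation of the retained
probes is computed over that state's samples, and two signed networks are
cut from it at a nonnegative threshold T: the positive network keeps pairs
with r > T, the negative network pairs with r < -T (both strict).  Every
retained probe stays in the node set even when isolated, so networks of the
different states share one node set and can be compared node-by-node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import LabeledDataset

logger = logging.getLogger("coexrewire")

SIGNS = ("positive", "negative")


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame  # symmetric, unit diagonal, probe x probe
    state: str

    @property
    def probes(self) -> list[str]:
        return [str(p) for p in self.values.index]


@dataclass
class SignedNetwork:
    graph: nx.Graph
    sign: str  # "positive" | "negative"
    threshold: float
    state: str

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]


def correlation_matrix(values: pd.DataFrame, state: str) -> CorrelationMatrix:
    """Pairwise Pearson r between probe rows over one state's samples.

    Zero-variance probes have undefined correlations; their off-diagonal
    entries are set to 0 (flagged), the diagonal stays 1.
    """
    if values.shape[1] < 3:
        raise ValueError(f"state {state} has fewer than 3 samples")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 probes")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(arr)
    if degenerate.any():
        logger.warning(
            "state %s: %d zero-variance probe(s); correlations set to 0",
            state,
            int(degenerate.sum()),
        )
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    frame = pd.DataFrame(corr, index=values.index, columns=values.index)
    return CorrelationMatrix(frame, state)


def threshold_network(corr: CorrelationMatrix, threshold: float, sign: str) -> SignedNetwork:
    """Cut a signed network out of a correlation matrix at a strict threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if sign not in SIGNS:
        raise ValueError(f"sign must be one of {SIGNS}")
    graph = nx.Graph(sign=sign, threshold=threshold, state=corr.state)
    probes = corr.probes
    graph.add_nodes_from(probes)
    arr = corr.values.to_numpy()
    if sign == "positive":
        ii, jj = np.nonzero(np.triu(arr > threshold, k=1))
    else:
        ii, jj = np.nonzero(np.triu(arr < -threshold, k=1))
    graph.add_weighted_edges_from(
        (probes[i], probes[j], float(arr[i, j])) for i, j in zip(ii, jj)
    )
    return SignedNetwork(graph, sign=sign, threshold=threshold, state=corr.state)


def state_correlations(dataset: LabeledDataset) -> dict[str, CorrelationMatrix]:
    """One correlation matrix per diagnostic state present in the dataset."""
    out = {}
    for state in dataset.states_present():
        cols = dataset.samples_for(state)
        out[state] = correlation_matrix(dataset.matrix.values[cols], state)
    return out


def build_state_networks(
    dataset: LabeledDataset, thresholds=(0.1, 0.3)
) -> dict[float, dict[str, dict[str, SignedNetwork]]]:
    """All signed networks: thresholds -> state -> sign -> SignedNetwork.

    Six networks per threshold (3 states x 2 signs) on a common node set.
    """
    states = dataset.states_present()
    if len(states) < 3:
        raise ValueError(f"expected all three states, found {states}")
    corrs = state_correlations(dataset)
    return {
        float(t): {
            state: {sign: threshold_network(corrs[state], t, sign) for sign in SIGNS}
            for state in states
        }
        for t in thresholds
    }


# ---------------------------------------------------------------------------
# exports


def export_edge_table(network: SignedNetwork, path) -> None:
    """TSV edge table: source, target, weight, sign, state, threshold."""
    rows = [
        {
            "source": min(u, v),
            "target": max(u, v),
            "weight": data["weight"],
            "sign": network.sign,
            "state": network.state,
            "threshold": network.threshold,
        }
        for u, v, data in network.graph.edges(data=True)
    ]
    frame = pd.DataFrame(
        rows, columns=["source", "target", "weight", "sign", "state", "threshold"]
    ).sort_values(["source", "target"])
    try:
        frame.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing edge table {path}: {exc}") from exc


def export_graphml(network: SignedNetwork, path) -> None:
    graph = network.graph.copy()
    for _, _, data in graph.edges(data=True):
        data.setdefault("sign", network.sign)
        data.setdefault("state", network.state)
    try:
        nx.write_graphml(graph, path)
    except OSError as exc:
        raise OSError(f"failed writing GraphML {path}: {exc}") from exc


def import_graphml(path) -> SignedNetwork:
    graph = nx.read_graphml(path)
    meta = graph.graph
    return SignedNetwork(
        graph,
        sign=meta.get("sign", "positive"),
        threshold=float(meta.get("threshold", 0.0)),
        state=meta.get("state", ""),
    )


def export_sif(network: SignedNetwork, path) -> None:
    """Cytoscape SIF: ``source pos|neg target`` per edge, isolated nodes bare."""
    interaction = "pos" if network.sign == "positive" else "neg"
    lines = []
    connected = set()
    for u, v in sorted(network.edges):
        lines.append(f"{u}\t{interaction}\t{v}")
        connected.update((u, v))
    for node in sorted(network.nodes - connected):
        lines.append(node)
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    except OSError as exc:
        raise OSError(f"failed writing SIF {path}: {exc}") from exc
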