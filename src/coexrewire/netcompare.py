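"""Comparing the per-state networks: node rewiring and consensus edges.

Two complementary comparisons are implemented.

**Rewiring score.**  For node v with adjacency vector a_s(v) in state s
(entries 0/1 in binary mode, |r| in weighted mode) and centroid
c(v) = mean_s a_s(v), the raw score is

    score(v) = sum_s || a_s(v) - c(v) ||^2

i.e. the total variance of the node's connectivity around its cross-state
centroid.  It is zero iff the node's neighbourhood is identical in every
state, invariant under permutation of the states, and in binary mode it
decomposes additively over neighbour slots (a slot that differs in exactly
one or exactly two of three states contributes 2/3).  A degree-corrected
variant divides by the node's mean degree, and a non-squared distance
variant is available; the raw score is the default.

**Consensus differential network.**  Against a single reference state,
an edge is *gained* when absent from the reference but present in every
condition network, and *lost* when present in the reference but absent from
every condition network.  Edges changing in only some conditions appear in
neither set.  The comparison is run separately per sign class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .coexnet import SignedNetwork

logger = logging.getLogger("coexrewire")

SCORE_MODES = ("raw", "degree_corrected", "distance")


def _common_nodes(networks: list[SignedNetwork]) -> list[str]:
    node_sets = [net.nodes for net in networks]
    if any(ns != node_sets[0] for ns in node_sets[1:]):
        raise ValueError("rewiring/consensus comparisons require identical node sets")
    return sorted(node_sets[0])


def _adjacency(net: SignedNetwork, nodes: list[str], weighted: bool) -> np.ndarray:
    idx = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v, data in net.graph.edges(data=True):
        w = abs(data.get("weight", 1.0)) if weighted else 1.0
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = w
    return a


def rewiring_scores(
    networks: dict[str, SignedNetwork],
    mode: str = "binary",
    score: str = "raw",
) -> pd.DataFrame:
    """Per-node rewiring score across the per-state networks.

    Parameters
    ----------
    networks
        Mapping state label -> network; all on one node set.
    mode
        ``binary`` (edge presence) or ``weighted`` (|r| as adjacency entry).
    score
        ``raw`` (sum of squared distances to the centroid, default),
        ``degree_corrected`` (raw divided by the node's mean degree), or
        ``distance`` (distances not squared).

    Returns a DataFrame indexed by node with the score, per-state degree,
    and dense rank (descending score, ties broken by node ID).
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    if score not in SCORE_MODES:
        raise ValueError(f"unknown score variant {score!r}")
    if len(networks) < 2:
        logger.warning("rewiring over a single network: all scores are 0")
    states = list(networks)
    nodes = _common_nodes(list(networks.values()))
    stack = np.stack(
        [_adjacency(networks[s], nodes, weighted=(mode == "weighted")) for s in states]
    )  # (n_states, n, n)
    centroid = stack.mean(axis=0)
    dev = stack - centroid[None, :, :]
    if score == "distance":
        vals = np.sqrt((dev**2).sum(axis=2)).sum(axis=0)
    else:
        vals = (dev**2).sum(axis=(0, 2))
    degrees = {s: stack[i].astype(bool).sum(axis=1) for i, s in enumerate(states)}
    if score == "degree_corrected":
        mean_deg = np.stack(list(degrees.values())).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(mean_deg > 0, vals / mean_deg, 0.0)
    table = pd.DataFrame({"score": vals}, index=pd.Index(nodes, name="node"))
    for s in states:
        table[f"degree_{s}"] = degrees[s]
    order = table.sort_values("score", ascending=False, kind="mergesort")
    # stable sort on a lexicographically sorted index -> deterministic ties
    table["rank"] = pd.Series(range(1, len(order) + 1), index=order.index)
    return table


def top_rewired(table: pd.DataFrame, cutoff: float = 5.0) -> pd.DataFrame:
    """Nodes with score >= cutoff, descending; ties broken by node ID."""
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    sub = table[table["score"] >= cutoff]
    return sub.sort_values("score", ascending=False, kind="mergesort")


def rewiring_report(
    positive: pd.DataFrame, negative: pd.DataFrame, cutoff: float = 5.0
) -> dict[str, pd.DataFrame]:
    """Top-rewired tables for the positive and negative network families."""
    return {
        "positive": top_rewired(positive, cutoff),
        "negative": top_rewired(negative, cutoff),
    }


@dataclass
class DifferentialNetwork:
    reference_state: str
    condition_states: list[str]
    sign: str
    threshold: float
    nodes: set[str] = field(repr=False)
    gained: set[tuple[str, str]] = field(repr=False)
    lost: set[tuple[str, str]] = field(repr=False)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(
            reference=self.reference_state,
            conditions=",".join(self.condition_states),
            sign=self.sign,
            threshold=self.threshold,
        )
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from((u, v, {"change": "gained"}) for u, v in sorted(self.gained))
        g.add_edges_from((u, v, {"change": "lost"}) for u, v in sorted(self.lost))
        return g


def consensus_differential(
    reference: SignedNetwork, conditions: list[SignedNetwork]
) -> DifferentialNetwork:
    """Edges gained/lost in ALL condition networks relative to the reference."""
    if not conditions:
        raise ValueError("need at least one condition network")
    nets = [reference, *conditions]
    if len({net.sign for net in nets}) != 1:
        raise ValueError("all networks must share one sign class")
    if len({net.threshold for net in nets}) != 1:
        raise ValueError("all networks must share one threshold")
    nodes = set(_common_nodes(nets))
    ref_edges = reference.edges
    cond_edges = [c.edges for c in conditions]
    in_all = set.intersection(*cond_edges)
    in_any = set.union(*cond_edges)
    return DifferentialNetwork(
        reference_state=reference.state,
        condition_states=[c.state for c in conditions],
        sign=reference.sign,
        threshold=reference.threshold,
        nodes=nodes,
        gained=in_all - ref_edges,
        lost=ref_edges - in_any,
    )


def export_differential_graphml(diff: DifferentialNetwork, path) -> None:
    nx.write_graphml(diff.to_graph(), path)


def export_differential_sif(diff: DifferentialNetwork, path) -> None:
    lines = [f"{u}\tgained\t{v}" for u, v in sorted(diff.gained)]
    lines += [f"{u}\tlost\t{v}" for u, v in sorted(diff.lost)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def write_rewiring_table(table: pd.DataFrame, path) -> None:
    cols = ["score", "rank"] + [c for c in table.columns if c.startswith("degree_")]
    table[cols].to_csv(path, sep="\t", index_label="node")
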