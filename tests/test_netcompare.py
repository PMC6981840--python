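"""Rewiring scores and consensus differential inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import labeled_dataset, make_network
from coexrewire import netcompare, simdata
from coexrewire.netcompare import consensus_differential, rewiring_scores, top_rewired


def naive_rewiring(networks, weighted=False):
    """Per-node centroid-distance loop over explicit adjacency dicts."""
    states = list(networks)
    nodes = sorted(networks[states[0]].nodes)
    scores = {}
    for v in nodes:
        vecs = []
        for s in states:
            g = networks[s].graph
            vec = []
            for u in nodes:
                if g.has_edge(v, u):
                    vec.append(abs(g.edges[v, u]["weight"]) if weighted else 1.0)
                else:
                    vec.append(0.0)
            vecs.append(np.array(vec))
        centroid = sum(vecs) / len(vecs)
        scores[v] = sum(((vec - centroid) ** 2).sum() for vec in vecs)
    return scores


def random_triple(rng, n_nodes=8, p=0.3, sign="positive"):
    nodes = [f"n{i}" for i in range(n_nodes)]
    nets = {}
    for state in ("NC", "MCI", "AD"):
        edges = [
            (u, v, rng.uniform(0.1, 1.0) * (1 if sign == "positive" else -1))
            for u, v in itertools.combinations(nodes, 2)
            if rng.random() < p
        ]
        nets[state] = make_network(nodes, edges, sign=sign, state=state)
    return nets


class TestRewiringScores:
    def test_identical_networks_score_zero(self):
        nodes = list("abcd")
        edges = [("a", "b"), ("c", "d")]
        nets = {s: make_network(nodes, edges, state=s) for s in ("NC", "MCI", "AD")}
        table = rewiring_scores(nets)
        assert (table["score"] == 0).all()

    def test_single_edge_in_one_of_three_states(self):
        nodes = list("abc")
        nets = {
            "NC": make_network(nodes, [("a", "b")], state="NC"),
            "MCI": make_network(nodes, [], state="MCI"),
            "AD": make_network(nodes, [], state="AD"),
        }
        table = rewiring_scores(nets)
        # per endpoint: (2/3)^2 + (1/3)^2 + (1/3)^2 = 2/3
        assert table.loc["a", "score"] == pytest.approx(2 / 3)
        assert table.loc["b", "score"] == pytest.approx(2 / 3)
        assert table.loc["c", "score"] == 0

    def test_additivity_over_slots(self):
        # hub x with 5 neighbours, each edge present in exactly one state
        nodes = ["x"] + [f"n{i}" for i in range(5)]
        per_state = {"NC": [0, 1], "MCI": [2, 3], "AD": [4]}
        nets = {
            s: make_network(nodes, [("x", f"n{i}") for i in per_state[s]], state=s)
            for s in ("NC", "MCI", "AD")
        }
        table = rewiring_scores(nets)
        assert table.loc["x", "score"] == pytest.approx(5 * 2 / 3)

    def test_two_of_three_slot_contributes_two_thirds(self):
        nodes = list("ab")
        nets = {
            "NC": make_network(nodes, [("a", "b")], state="NC"),
            "MCI": make_network(nodes, [("a", "b")], state="MCI"),
            "AD": make_network(nodes, [], state="AD"),
        }
        table = rewiring_scores(nets)
        assert table.loc["a", "score"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nets = random_triple(rng)
        table = rewiring_scores(nets)
        expected = naive_rewiring(nets)
        for node, exp in expected.items():
            assert table.loc[node, "score"] == pytest.approx(exp, abs=1e-12)

    def test_weighted_mode_matches_naive_oracle(self, rng):
        nets = random_triple(rng, sign="negative")
        table = rewiring_scores(nets, mode="weighted")
        expected = naive_rewiring(nets, weighted=True)
        for node, exp in expected.items():
            assert table.loc[node, "score"] == pytest.approx(exp, abs=1e-12)

    def test_permutation_invariance(self, rng):
        nets = random_triple(rng)
        t1 = rewiring_scores(nets)
        shuffled = {s: nets[s] for s in ("AD", "NC", "MCI")}
        t2 = rewiring_scores(shuffled)
        pd.testing.assert_series_equal(t1["score"], t2["score"])

    def test_degree_corrected_divides_by_mean_degree(self):
        nodes = list("abc")
        nets = {
            "NC": make_network(nodes, [("a", "b")], state="NC"),
            "MCI": make_network(nodes, [], state="MCI"),
            "AD": make_network(nodes, [], state="AD"),
        }
        raw = rewiring_scores(nets, score="raw")
        corr = rewiring_scores(nets, score="degree_corrected")
        assert corr.loc["a", "score"] == pytest.approx(raw.loc["a", "score"] / (1 / 3))
        assert corr.loc["c", "score"] == 0

    def test_distance_variant_square_roots_per_state(self):
        nodes = list("ab")
        nets = {
            "NC": make_network(nodes, [("a", "b")], state="NC"),
            "MCI": make_network(nodes, [], state="MCI"),
            "AD": make_network(nodes, [], state="AD"),
        }
        table = rewiring_scores(nets, score="distance")
        assert table.loc["a", "score"] == pytest.approx(2 / 3 + 1 / 3 + 1 / 3)

    def test_mismatched_node_sets_rejected(self):
        nets = {
            "NC": make_network(list("ab"), [], state="NC"),
            "MCI": make_network(list("abc"), [], state="MCI"),
        }
        with pytest.raises(ValueError, match="identical node sets"):
            rewiring_scores(nets)


class TestTopRewired:
    def make_table(self, scores):
        t = pd.DataFrame({"score": pd.Series(scores)})
        t.index.name = "node"
        return t

    def test_cutoff_keeps_scores_at_or_above(self):
        table = self.make_table({"a": 8.33, "b": 5.67, "c": 4.0})
        top = top_rewired(table, cutoff=5)
        assert list(top.index) == ["a", "b"]

    def test_all_zero_scores_empty_at_cutoff_five(self):
        table = self.make_table({"a": 0.0, "b": 0.0})
        assert top_rewired(table, cutoff=5).empty

    def test_zero_cutoff_returns_all_descending(self):
        table = self.make_table({"a": 1.0, "b": 3.0, "c": 2.0})
        assert list(top_rewired(table, cutoff=0).index) == ["b", "c", "a"]

    def test_ties_break_lexicographically(self):
        table = self.make_table({"b": 5.0, "a": 5.0, "c": 7.0})
        assert list(top_rewired(table.sort_index(), cutoff=5).index) == ["c", "a", "b"]

    def test_report_row_counts(self):
        pos = self.make_table({"a": 6.0, "b": 2.0})
        neg = self.make_table({"a": 1.0, "b": 0.0})
        report = netcompare.rewiring_report(pos, neg, cutoff=5)
        assert len(report["positive"]) == 1 and len(report["negative"]) == 0


def brute_force_consensus(ref_edges, cond_edge_sets):
    all_pairs = set(ref_edges).union(*cond_edge_sets)
    gained = {
        e for e in all_pairs
        if e not in ref_edges and all(e in c for c in cond_edge_sets)
    }
    lost = {
        e for e in ref_edges
        if all(e not in c for c in cond_edge_sets)
    }
    return gained, lost


class TestConsensusDifferential:
    def test_edge_in_both_conditions_only_is_gained(self):
        nodes = list("ab")
        ref = make_network(nodes, [], state="NC")
        mci = make_network(nodes, [("a", "b")], state="MCI")
        ad = make_network(nodes, [("a", "b")], state="AD")
        diff = consensus_differential(ref, [mci, ad])
        assert diff.gained == {("a", "b")} and diff.lost == set()

    def test_partial_condition_change_is_neither(self):
        nodes = list("ab")
        ref = make_network(nodes, [("a", "b")], state="NC")
        mci = make_network(nodes, [], state="MCI")
        ad = make_network(nodes, [("a", "b")], state="AD")
        diff = consensus_differential(ref, [mci, ad])
        assert diff.gained == set() and diff.lost == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        nets = random_triple(rng, n_nodes=8, p=0.4)
        diff = consensus_differential(nets["NC"], [nets["MCI"], nets["AD"]])
        gained, lost = brute_force_consensus(
            nets["NC"].edges, [nets["MCI"].edges, nets["AD"].edges]
        )
        assert diff.gained == gained and diff.lost == lost
        assert diff.gained.isdisjoint(diff.lost)
        assert diff.gained.isdisjoint(nets["NC"].edges)
        assert diff.lost <= nets["NC"].edges

    def test_condition_order_invariance(self, rng):
        nets = random_triple(rng)
        d1 = consensus_differential(nets["NC"], [nets["MCI"], nets["AD"]])
        d2 = consensus_differential(nets["NC"], [nets["AD"], nets["MCI"]])
        assert d1.gained == d2.gained and d1.lost == d2.lost

    def test_empty_condition_list_rejected(self):
        ref = make_network(list("ab"), [])
        with pytest.raises(ValueError):
            consensus_differential(ref, [])

    def test_mixed_sign_classes_rejected(self):
        ref = make_network(list("ab"), [], sign="positive")
        cond = make_network(list("ab"), [], sign="negative")
        with pytest.raises(ValueError, match="sign"):
            consensus_differential(ref, [cond])

    def test_graphml_and_sif_exports(self, tmp_path):
        nodes = list("abc")
        ref = make_network(nodes, [("a", "c")], state="NC")
        mci = make_network(nodes, [("a", "b")], state="MCI")
        ad = make_network(nodes, [("a", "b")], state="AD")
        diff = consensus_differential(ref, [mci, ad])
        netcompare.export_differential_graphml(diff, tmp_path / "d.graphml")
        netcompare.export_differential_sif(diff, tmp_path / "d.sif")
        import networkx as nx

        g = nx.read_graphml(tmp_path / "d.graphml")
        changes = {(u, v): d["change"] for u, v, d in g.edges(data=True)}
        assert changes == {("a", "b"): "gained", ("a", "c"): "lost"}
        assert (tmp_path / "d.sif").read_text() == "a\tgained\tb\na\tlost\tc\n"


class TestParameterRecovery:
    def test_planted_fully_rewired_node_ranks_first(self):
        from coexrewire import coexnet

        cfg = simdata.rewiring_scenario(seed=0)
        dataset, truth = labeled_dataset(cfg)
        nets = coexnet.build_state_networks(dataset, thresholds=(0.1,))[0.1]
        table = rewiring_scores({s: nets[s]["positive"] for s in nets})
        assert table["score"].idxmax() == truth.rewired_nodes[0]
        report = netcompare.rewiring_report(table, table, cutoff=5)
        assert report["positive"].index[0] == truth.rewired_nodes[0]

    def test_planted_consensus_edges_recovered(self):
        from coexrewire import coexnet

        cfg = simdata.consensus_scenario(seed=0)
        dataset, truth = labeled_dataset(cfg)
        nets = coexnet.build_state_networks(dataset, thresholds=(0.1,))[0.1]
        diff = consensus_differential(
            nets["NC"]["positive"], [nets["MCI"]["positive"], nets["AD"]["positive"]]
        )
        precision, recall = simdata.score_consensus_recovery(
            truth, diff.gained, diff.lost, sign="positive"
        )
        assert precision >= 0.9 and recall >= 0.9
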