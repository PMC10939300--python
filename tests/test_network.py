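"""Pathway connectivity/overlap statistics, degree-aware nulls, DPN assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eabench.containers import FunctionalNetwork, GeneSetCollection, ValidationError
from eabench.network import (
    assemble,
    combine_fisher,
    direct_links,
    ipc,
    jaccard,
    make_degree_bins,
    pairwise_stats,
    sample_matched,
    shared_neighbors,
    subsample_pvalue,
)

from conftest import random_toy_network


def brute_direct_links(A, B, net):
    return sum(1 for u, v, _ in net.edges() if (u in A and v in B) or (u in B and v in A))


def brute_shared_neighbors(A, B, net):
    count = 0
    for g in net.nodes - set(A) - set(B):
        nbrs = net.neighbors(g)
        if nbrs & set(A) and nbrs & set(B):
            count += 1
    return count


class TestConnectivityCounts:
    def test_direct_links_toy(self, toy_net):
        assert direct_links({"a1", "a2"}, {"b1", "b2"}, toy_net) == 2

    def test_direct_links_disconnected(self, toy_net):
        assert direct_links({"x"}, {"a1"}, toy_net) == 0

    def test_direct_links_clique_self_comparison(self):
        net = FunctionalNetwork()
        for i in range(4):
            for j in range(i + 1, 4):
                net.add_edge(f"k{i}", f"k{j}")
        clique = {f"k{i}" for i in range(4)}
        assert direct_links(clique, clique, net) == 6

    def test_shared_neighbors_star(self, toy_net):
        # c is outside both sets and touches a1 and b1
        assert shared_neighbors({"a1"}, {"b1", "b2"}, toy_net) == 1

    def test_shared_neighbor_inside_union_not_counted(self, toy_net):
        assert shared_neighbors({"a1", "c"}, {"b1", "c"}, toy_net) == 0

    def test_ipc_sums_and_vacuous_cases(self, toy_net):
        assert ipc({"a1", "a2"}, {"b1", "b2"}, toy_net) == 3  # DL=2, SN=1 (c)
        assert ipc(set(), {"b1"}, toy_net) == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            net, names = random_toy_network(rng, n_nodes=14, p=0.25)
            A = set(rng.choice(names, size=4, replace=False))
            B = set(rng.choice(names, size=5, replace=False))
            assert direct_links(A, B, net) == brute_direct_links(A, B, net)
            assert shared_neighbors(A, B, net) == brute_shared_neighbors(A, B, net)
            assert ipc(A, B, net) == ipc(B, A, net)


class TestJaccard:
    def test_examples(self):
        assert jaccard({1, 2, 3}, {3, 4}) == 0.25
        assert jaccard({1, 2}, {1, 2}) == 1.0
        assert jaccard({1}, {2}) == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            jaccard(set(), set())


class TestDegreeBins:
    def test_bin_sizes_partition_sorted_universe(self, small_study):
        net, _, _ = small_study
        universe = {f"u{i}" for i in range(250)}
        bins = make_degree_bins(net, universe, bin_size=100)
        assert [len(b) for b in bins.members] == [100, 100, 50]

    def test_single_bin_when_bin_size_exceeds_universe(self, small_study):
        net, _, _ = small_study
        bins = make_degree_bins(net, {"a", "b"}, bin_size=10)
        assert bins.n_bins == 1

    def test_order_is_degree_sorted_with_id_tiebreak(self, toy_net):
        bins = make_degree_bins(toy_net, toy_net.nodes, bin_size=2)
        degrees = [toy_net.degree(g) for g in bins.order]
        assert degrees == sorted(degrees)
        for d in set(degrees):
            tied = [g for g in bins.order if toy_net.degree(g) == d]
            assert tied == sorted(tied)


class TestSampleMatched:
    def test_cardinality_and_distinctness(self, small_study):
        net, collection, _ = small_study
        bins = make_degree_bins(net, net.nodes, bin_size=50)
        rng = np.random.default_rng(0)
        B = set(list(collection[collection.ids[0]])[:10])
        sample = sample_matched(B, bins, rng)
        assert len(sample) == len(B)

    def test_singleton_bins_force_identity(self, toy_net):
        bins = make_degree_bins(toy_net, toy_net.nodes, bin_size=1)
        B = {"a1", "c"}
        assert sample_matched(B, bins, np.random.default_rng(0)) == B

    def test_mean_degree_preserved_over_draws(self, small_spec):
        from eabench.synthetic import make_network

        net = make_network(small_spec)
        genes = np.array(sorted(net.nodes), dtype=object)
        bins = make_degree_bins(net, net.nodes, bin_size=50)
        rng = np.random.default_rng(1)
        B = set(rng.choice(genes, 30, replace=False).tolist())
        target = np.mean([net.degree(g) for g in B])
        means = [
            np.mean([net.degree(g) for g in sample_matched(B, bins, rng)])
            for _ in range(1000)
        ]
        assert np.mean(means) == pytest.approx(target, rel=0.05)

    def test_gene_outside_universe_rejected(self, toy_net):
        bins = make_degree_bins(toy_net, {"a1", "b1"}, bin_size=1)
        with pytest.raises(ValidationError):
            sample_matched({"nope"}, bins, np.random.default_rng(0))


class TestSubsamplePvalue:
    def test_observed_above_all_null_draws(self, small_study):
        net, _, _ = small_study
        # wiring a fresh dense biclique makes the observed IPC unreachable by
        # degree-matched draws, so p hits (or nears) the 1/(n+1) floor
        net_copy = net.copy()
        members = sorted(net.nodes)[:8]
        for u in members[:4]:
            for v in members[4:8]:
                net_copy.add_edge(u, v)
        bins = make_degree_bins(net_copy, net_copy.nodes, bin_size=50)
        p_ipc = subsample_pvalue(
            set(members[:4]), set(members[4:8]), "ipc", net_copy, bins,
            n=50, rng=np.random.default_rng(2),
        )
        assert p_ipc <= 5 / 51

    def test_observed_below_all_null_draws_gives_one(self, small_study):
        net, _, _ = small_study
        bins = make_degree_bins(net, net.nodes, bin_size=50)
        rng = np.random.default_rng(3)
        nodes = sorted(net.nodes)
        # empty overlap: every null draw ties or beats a Jaccard of 0
        p = subsample_pvalue(set(nodes[:20]), set(nodes[20:40]), "jaccard", net, bins, n=30, rng=rng)
        assert p == 1.0

    def test_null_pvalues_uniform_under_matched_null(self, small_study):
        """Degree-matched random pairs give a uniform p-value grid (KS alpha=0.01)."""
        net, _, _ = small_study
        genes = np.array(sorted(net.nodes), dtype=object)
        bins = make_degree_bins(net, net.nodes, bin_size=50)
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(300):
            A = set(rng.choice(genes, 60, replace=False).tolist())
            B = sample_matched(set(rng.choice(genes, 60, replace=False).tolist()), bins, rng)
            ps.append(subsample_pvalue(A, B, "ipc", net, bins, n=99, rng=rng))
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_relabeling_invariance_under_order_preserving_map(self, small_study):
        net, collection, _ = small_study
        relabel = lambda g: "zz_" + g  # preserves lexicographic order
        mapped = FunctionalNetwork(
            (relabel(u), relabel(v), w) for u, v, w in net.edges()
        )
        bins = make_degree_bins(net, net.nodes, bin_size=50)
        bins_m = make_degree_bins(mapped, mapped.nodes, bin_size=50)
        A = set(collection[collection.ids[0]])
        B = set(collection[collection.ids[1]])
        p1 = subsample_pvalue(A, B, "ipc", net, bins, n=60, rng=np.random.default_rng(9))
        p2 = subsample_pvalue(
            {relabel(g) for g in A}, {relabel(g) for g in B}, "ipc",
            mapped, bins_m, n=60, rng=np.random.default_rng(9),
        )
        assert p1 == p2


class TestCombineFisher:
    def test_unit_pvalues_combine_to_one(self):
        assert combine_fisher(1.0, 1.0) == pytest.approx(1.0)

    def test_hand_example(self):
        assert combine_fisher(0.05, 0.05) == pytest.approx(0.01748, abs=2e-4)

    def test_commutative(self):
        assert combine_fisher(0.3, 0.04) == combine_fisher(0.04, 0.3)

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValidationError):
            combine_fisher(0.0, 0.5)


@pytest.fixture(scope="module")
def small_pairwise(small_study):
    net, collection, truth = small_study
    table = pairwise_stats(collection, net, n_samples=150, seed=17, universe=net.nodes)
    return net, collection, truth, table


class TestPairwiseStats:
    def test_row_count_is_pair_count(self, small_pairwise):
        _, collection, _, table = small_pairwise
        n = len(collection)
        assert len(table) == n * (n - 1) // 2

    def test_planted_pairs_significant(self, small_pairwise):
        _, _, truth, table = small_pairwise
        indexed = table.set_index(["pathway_a", "pathway_b"])
        for a, b in truth:
            key = (a, b) if (a, b) in indexed.index else (b, a)
            row = indexed.loc[key]
            assert row["q_conn"] < 0.05
            assert row["q_olap"] < 0.05

    def test_ipc_column_is_dl_plus_sn(self, small_pairwise):
        _, _, _, table = small_pairwise
        assert (table["IPC"] == table["DL"] + table["SN"]).all()

    def test_deterministic_under_seed_and_order_independent(self, small_study):
        net, collection, _ = small_study
        sub = GeneSetCollection(
            {pid: collection[pid] for pid in collection.ids[:4]}
        )
        reordered = GeneSetCollection(
            {pid: collection[pid] for pid in reversed(collection.ids[:4])}
        )
        t1 = pairwise_stats(sub, net, n_samples=40, seed=5, universe=net.nodes)
        t2 = pairwise_stats(reordered, net, n_samples=40, seed=5, universe=net.nodes)
        def as_dict(t):
            return {
                frozenset((r.pathway_a, r.pathway_b)): (r.p_conn, r.p_olap)
                for r in t.itertuples()
            }
        assert as_dict(t1) == as_dict(t2)


def make_stats_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_a", "pathway_b", "DL", "SN", "IPC", "J",
            "p_conn_ab", "p_conn_ba", "p_conn", "p_olap_ab", "p_olap_ba",
            "p_olap", "q_conn", "q_olap",
        ],
    )


def synthetic_accepted_table(n_neighbors, q=0.01):
    rows = []
    for i in range(n_neighbors):
        rows.append(
            ("T", f"N{i:02d}", 1, 1, 2, 0.2, q, q, q, q, q, q, q, q)
        )
    return make_stats_table(rows)


class TestAssemble:
    def test_top_k_pruning(self):
        table = synthetic_accepted_table(25)
        sim = {("N%02d" % i): 1 - i * 0.01 for i in range(25)}
        dpn = assemble(table, ["T"], lambda a, b: sim[b if a == "T" else a], k=20)
        assert len(dpn.related["T"]) == 20
        # highest-similarity neighbours kept
        assert dpn.related["T"][0] == "N00"

    def test_no_accepted_edges_leaves_targets_isolated(self):
        table = synthetic_accepted_table(5, q=0.5)
        dpn = assemble(table, ["T"], lambda a, b: 1.0, alpha=0.05)
        assert dpn.edges == {}
        assert dpn.related["T"] == []

    def test_gate_disabled_accepts_every_pair(self):
        table = synthetic_accepted_table(5, q=0.9)
        dpn = assemble(table, ["T"], lambda a, b: 1.0, alpha=1.0, k=10**6)
        assert len(dpn.edges) == 5

    def test_monotone_in_alpha(self, small_pairwise):
        _, collection, _, table = small_pairwise
        targets = collection.ids[:2]
        sim = lambda a, b: 1.0
        edges = [
            set(assemble(table, targets, sim, alpha=a).edges) for a in (0.01, 0.05, 0.5, 1.0)
        ]
        for smaller, larger in zip(edges, edges[1:]):
            assert smaller <= larger

    def test_missing_similarity_pair_named_in_error(self):
        table = synthetic_accepted_table(2)
        with pytest.raises(ValidationError, match="N00"):
            assemble(table, ["T"], pd.DataFrame())

    def test_unknown_target_rejected(self):
        table = synthetic_accepted_table(2)
        with pytest.raises(ValidationError, match="ghost"):
            assemble(table, ["ghost"], lambda a, b: 1.0)
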