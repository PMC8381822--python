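"""Network reconstruction, centrality indices, hubs and scale-free test."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy import stats

from mnqtl.descriptors import descriptor_tensor
from mnqtl.network import (
    MicrobialNetwork,
    build_network,
    centralities,
    detect_hubs,
    per_host_network,
    powerlaw_test,
    shortest_paths,
)


def _net_from_edges(edges, nodes, directed=False, itype=None):
    itype = itype or ("aggression" if directed else "mutualism")
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n), dtype=int)
    for u, v in edges:
        A[idx[u], idx[v]] = 1
        if not directed:
            A[idx[v], idx[u]] = 1
    W = np.where(A, 1.0, np.nan)
    return MicrobialNetwork(itype, list(nodes), A, W, directed)


def _from_nx(g, directed):
    nodes = sorted(g.nodes())
    return _net_from_edges(g.edges(), nodes, directed=directed)


class TestBuildNetwork:
    def test_strong_pair_retained(self, rng):
        # one near-tied pair (explosive Z_mu) against well-separated others
        hosts = [f"h{i}" for i in range(8)]
        taxa = list("ABCDE")
        base = np.array([100.0, 99.0, 1.0, 10.0, 1000.0])
        ab = pd.DataFrame(
            base * rng.lognormal(0, 0.02, (8, 5)), index=hosts, columns=taxa
        )
        tensor = descriptor_tensor(ab)
        net = build_network(tensor, "mutualism", alpha=0.05, n_perm=200, seed=1)
        edges = set(map(tuple, net.edge_list()[["u", "v"]].to_numpy()))
        assert ("A", "B") in edges

    def test_exchangeable_null_controls_fdr(self, rng):
        frac = []
        for rep in range(100):
            ab = pd.DataFrame(
                rng.lognormal(0, 1, (6, 6)),
                index=[f"h{i}" for i in range(6)],
                columns=list("ABCDEF"),
            )
            tensor = descriptor_tensor(ab)
            with pytest.warns(UserWarning):
                net = build_network(tensor, "aggression", alpha=0.05, n_perm=99,
                                    seed=rep)
            frac.append(net.n_edges / tensor.n_pairs)
        se = np.std(frac) / np.sqrt(len(frac))
        assert np.mean(frac) <= 0.05 + 2 * se + 1e-9

    def test_single_pair_indeterminate(self, rng):
        ab = pd.DataFrame(
            np.tile([4.0, 2.0], (5, 1)), index=[f"h{i}" for i in range(5)],
            columns=["A", "B"],
        )
        tensor = descriptor_tensor(ab)
        with pytest.warns(UserWarning, match="indeterminate"):
            net = build_network(tensor, "mutualism", n_perm=99)
        assert net.indeterminate and net.n_edges == 0

    def test_directed_network_has_no_two_cycles(self, rng):
        ab = pd.DataFrame(
            rng.lognormal(0, 1, (10, 5)), index=[f"h{i}" for i in range(10)],
            columns=list("ABCDE"),
        )
        tensor = descriptor_tensor(ab)
        net = per_host_network(tensor, "h0", "aggression", quantile=0.0)
        assert net.directed
        assert not np.any((net.adjacency == 1) & (net.adjacency.T == 1))

    def test_undirected_symmetry_enforced(self):
        A = np.array([[0, 1], [0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            MicrobialNetwork("mutualism", ["a", "b"], A, A.astype(float), False)


class TestShortestPaths:
    def test_path_graph_by_inspection(self):
        net = _net_from_edges([("u", "v"), ("v", "w")], ["u", "v", "w"])
        dm = shortest_paths(net)
        assert dm.D[0, 2] == 2 and dm.sigma[0, 2] == 1
        assert dm.path_count_through(1)[0, 2] == 1

    def test_complete_graph(self):
        nodes = list("abcd")
        net = _net_from_edges([(u, v) for i, u in enumerate(nodes)
                               for v in nodes[i + 1:]], nodes)
        dm = shortest_paths(net)
        off = ~np.eye(4, dtype=bool)
        assert np.all(dm.D[off] == 1)
        for u in range(4):
            assert dm.path_count_through(u).sum() == 0

    def test_matches_bfs_brute_force(self, rng):
        g = nx.gnp_random_graph(10, 0.35, seed=5)
        net = _from_nx(g, directed=False)
        dm = shortest_paths(net)
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        for i in range(10):
            for j in range(10):
                expect = lengths[i].get(j, np.inf)
                assert dm.D[i, j] == expect


def _random_connected(rng, directed):
    while True:
        n = int(rng.integers(8, 31))
        p = 0.35 if directed else 0.25
        g = (nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)), directed=True)
             if directed else
             nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30))))
        ok = nx.is_strongly_connected(g) if directed else nx.is_connected(g)
        if ok:
            return g


class TestCentralities:
    def test_path_graph_hand_values(self):
        net = _net_from_edges([("u", "v"), ("v", "w")], ["u", "v", "w"])
        prof = centralities(net)
        t = prof.table
        assert t.loc["v", "closeness"] == pytest.approx(1 / 2)
        assert t.loc["u", "closeness"] == pytest.approx(1 / 3)
        assert t.loc["v", "eccentricity"] == pytest.approx(1.0)
        assert t.loc["u", "eccentricity"] == pytest.approx(1 / 2)
        assert t.loc["v", "betweenness"] == pytest.approx(1.0)
        assert t.loc["u", "betweenness"] == pytest.approx(0.0)

    def test_path_graph_eigenpair(self):
        net = _net_from_edges([("u", "v"), ("v", "w")], ["u", "v", "w"])
        prof = centralities(net)
        expect = np.array([1.0, np.sqrt(2), 1.0])
        expect /= np.linalg.norm(expect)
        np.testing.assert_allclose(prof.table["eigenvector"], expect, atol=1e-10)
        assert prof.eigenvalue == pytest.approx(np.sqrt(2), abs=1e-10)

    def test_pagerank_satisfies_printed_recursion(self, rng):
        g = _random_connected(rng, directed=True)
        net = _from_nx(g, directed=True)
        prof = centralities(net, damping=0.85, pagerank_variant="as_printed")
        P = prof.table["pagerank"].to_numpy()
        A = net.adjacency
        K = A.sum(axis=1)
        resub = np.empty_like(P)
        for u in range(len(P)):
            acc = 0.0
            for v in range(len(P)):
                if A[v, u]:
                    acc += P[v] / K[v]
            resub[u] = 0.15 + 0.85 * acc
        np.testing.assert_allclose(P, resub, atol=1e-10)

    def test_pagerank_agrees_with_power_iteration_oracle(self, rng):
        g = _random_connected(rng, directed=True)
        net = _from_nx(g, directed=True)
        P = centralities(net, pagerank_variant="normalized").table["pagerank"].to_numpy()
        n = net.n_nodes
        A = net.adjacency.astype(float)
        K = A.sum(axis=1)
        x = np.full(n, 1 / n)
        for _ in range(5000):
            nxt = np.full(n, 0.15 / n)
            for v in range(n):
                share = x[v] / K[v] if K[v] else x[v] / n
                targets = np.nonzero(A[v])[0] if K[v] else np.arange(n)
                nxt[targets] += 0.85 * share
            if np.abs(nxt - x).max() < 1e-14:
                x = nxt
                break
            x = nxt
        np.testing.assert_allclose(P, x, atol=1e-10)

    @pytest.mark.parametrize("directed", [False, True])
    def test_indices_match_networkx_oracle(self, rng, directed):
        for _ in range(10):
            g = _random_connected(rng, directed)
            net = _from_nx(g, directed)
            prof = centralities(net, pagerank_variant="normalized")
            t = prof.table
            n = net.n_nodes
            oriented = g.reverse() if directed else g
            close = nx.closeness_centrality(oriented)
            ecc = nx.eccentricity(g)
            btw = nx.betweenness_centrality(g, normalized=False)
            eig = nx.eigenvector_centrality(oriented, max_iter=5000, tol=1e-12)
            pr = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=1000)
            nodes = list(t.index)
            np.testing.assert_allclose(
                t["closeness"], [close[v] / (n - 1) for v in nodes], atol=1e-12)
            np.testing.assert_allclose(
                t["eccentricity"], [1 / ecc[v] for v in nodes], atol=1e-12)
            np.testing.assert_allclose(
                t["betweenness"], [btw[v] for v in nodes], atol=1e-9)
            ev = np.array([eig[v] for v in nodes])
            ev /= np.linalg.norm(ev)
            np.testing.assert_allclose(t["eigenvector"], ev, atol=1e-8)
            np.testing.assert_allclose(t["pagerank"], [pr[v] for v in nodes], atol=1e-8)
            deg = dict(g.degree()) if not directed else {
                v: g.in_degree(v) + g.out_degree(v) for v in nodes}
            assert prof.connectivity == pytest.approx(np.mean([deg[v] for v in nodes]))

    def test_disconnected_reachability_reported(self):
        net = _net_from_edges([("a", "b")], ["a", "b", "c"])
        prof = centralities(net)
        assert np.isnan(prof.table.loc["c", "closeness"])
        assert prof.reachable_fraction["a"] == pytest.approx(0.5)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            centralities(MicrobialNetwork("mutualism", [], np.zeros((0, 0)),
                                          np.zeros((0, 0)), False))


class TestHubs:
    def test_star_graph_center_is_hub(self):
        nodes = ["c"] + [f"l{i}" for i in range(9)]
        net = _net_from_edges([("c", l) for l in nodes[1:]], nodes)
        ab = pd.Series(1.0, index=nodes)
        rep = detect_hubs(net, ab)
        assert rep.hubs == ["c"]

    def test_aggression_role_partition(self):
        net = _net_from_edges([("a", "b"), ("a", "c"), ("c", "b")],
                              ["a", "b", "c"], directed=True, itype="aggression")
        roles = detect_hubs(net, pd.Series(1.0, index=["a", "b", "c"])).roles
        assert roles["a"] == "hawk" and roles["b"] == "dove" and roles["c"] == "hawk-dove"

    def test_hub_abundance_contrast(self, rng):
        # 4 fully connected hubs + 16 leaves; hubs far more abundant
        hubs = [f"hub{i}" for i in range(4)]
        leaves = [f"leaf{i}" for i in range(16)]
        edges = [(h, x) for h in hubs for x in hubs + leaves if h < x]
        net = _net_from_edges(edges, hubs + leaves)
        ab = pd.Series(
            np.r_[rng.normal(10, 1, 4), rng.normal(1, 1, 16)], index=hubs + leaves)
        rep = detect_hubs(net, ab)
        assert set(rep.hubs) == set(hubs)
        assert rep.p_value < 0.001

    def test_equal_degrees_empty_hub_set(self):
        net = _net_from_edges([("a", "b"), ("b", "c"), ("c", "a")], ["a", "b", "c"])
        with pytest.warns(UserWarning, match="all degrees equal"):
            rep = detect_hubs(net, pd.Series(1.0, index=["a", "b", "c"]))
        assert rep.hubs == []


class TestPowerlaw:
    def test_exponent_recovered_from_zipf_sample(self, rng):
        degrees = stats.zipf.rvs(2.5, size=500, random_state=1234)
        res = powerlaw_test(degrees, n_boot=30, seed=0)
        assert 2.2 <= res.exponent <= 2.8

    def test_regular_degrees_rejected(self):
        res = powerlaw_test(np.full(60, 4), n_boot=99, seed=0)
        assert res.p_value < 0.05

    def test_too_small_flagged_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = powerlaw_test(np.array([1, 2, 3, 2, 1]))
        assert not res.defined and np.isnan(res.exponent)
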