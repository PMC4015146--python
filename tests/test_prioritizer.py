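"""Path enumeration, correlation scoring and ranking tests."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from netprio import (
    NetworkPath,
    PropagationParams,
    StateVector,
    ValidationError,
    build_global_graph,
    enumerate_paths,
    init_state,
    normalize_prior,
    prioritize,
    propagate_along_path,
    propagate_within,
    score_correlation,
)
from netprio.prioritize import PathResult, _pearson


def graph_from_meta(meta_edges, domain_ids):
    """Global graph with one node per domain, relations per meta edge."""
    domain_specs = [(d, [f"{d}_x"], []) for d in domain_ids]
    relation_specs = [
        (a, b, [(f"{a}_x", f"{b}_x", 1.0)]) for a, b in meta_edges
    ]
    return build_global_graph(domain_specs, relation_specs)


class TestEnumeratePaths:
    def test_chain_plus_direct_gives_two_paths(self):
        g = graph_from_meta([("Q", "A"), ("A", "T"), ("Q", "T")],
                            ["Q", "A", "T"])
        paths = enumerate_paths(g, "Q", "T")
        assert [p.sequence for p in paths] == [("Q", "A", "T"), ("Q", "T")]

    def test_single_edge_single_path(self):
        g = graph_from_meta([("Q", "T")], ["Q", "T"])
        assert [p.sequence for p in enumerate_paths(g, "Q", "T")] == [("Q", "T")]

    def test_five_domain_topology_with_three_paths(self):
        # direct, via A, via B-C: exactly three routes query -> target
        g = graph_from_meta(
            [("Q", "T"), ("Q", "A"), ("A", "T"), ("Q", "B"), ("B", "C"),
             ("C", "T")],
            ["Q", "A", "B", "C", "T"],
        )
        assert len(enumerate_paths(g, "Q", "T")) == 3

    def test_disconnected_networks_raise(self):
        g = graph_from_meta([("Q", "A")], ["Q", "A", "T"])
        with pytest.raises(ValidationError, match="disconnected"):
            enumerate_paths(g, "Q", "T")

    def test_matches_networkx_all_simple_paths(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 7))
            ids = [f"D{i}" for i in range(n)]
            edges = [
                (ids[i], ids[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.5
            ]
            g = graph_from_meta(edges, ids)
            oracle = sorted(
                tuple(p)
                for p in nx.all_simple_paths(g.meta_graph, ids[0], ids[-1])
            )
            if not oracle:
                with pytest.raises(ValidationError):
                    enumerate_paths(g, ids[0], ids[-1])
            else:
                got = [p.sequence for p in enumerate_paths(g, ids[0], ids[-1])]
                assert got == oracle


class TestPropagateAlongPath:
    def test_direct_path_projects_query_state(self, triangle_graph):
        params = PropagationParams(gamma=0.5)
        q_net = triangle_graph.domains["q"]
        x_q = propagate_within(
            q_net, normalize_prior(init_state(q_net, {"q0"})), params
        )
        res = propagate_along_path(
            triangle_graph, NetworkPath(("q", "t")), x_q, params
        )
        np.testing.assert_array_equal(res.penultimate_state.values, x_q.values)
        S = triangle_graph.relation_between("q", "t").norm_toward("t")
        np.testing.assert_allclose(res.projected, S @ x_q.values)

    def test_signal_free_intermediate_carries_zeros(self):
        g = build_global_graph(
            [("q", ["q0", "q1"], [("q0", "q1", 1.0)]),
             ("m", ["m0", "m1"], [("m0", "m1", 1.0)]),
             ("t", ["t0"], [])],
            [("q", "m", [("q1", "m0", 0.0)]),  # zero-weight: no adjacency
             ("m", "t", [("m0", "t0", 1.0)])],
        )
        params = PropagationParams(gamma=1.0)
        q_net = g.domains["q"]
        x_q = propagate_within(
            q_net, normalize_prior(init_state(q_net, {"q0"})), params
        )
        res = propagate_along_path(g, NetworkPath(("q", "m", "t")), x_q, params)
        assert res.penultimate_state.values.sum() == 0
        assert res.projected.sum() == 0

    def test_matches_scalar_loop_oracle_on_three_chain(self, triangle_graph):
        params = PropagationParams(alpha=0.7, gamma=0.67)
        g = triangle_graph
        q_net, m_net, t_net = (g.domains[d] for d in "qmt")
        x_q = propagate_within(
            q_net, normalize_prior(init_state(q_net, {"q0", "q1"})), params
        )
        res = propagate_along_path(g, NetworkPath(("q", "m", "t")), x_q, params)

        # independent scalar recomputation: mean -> threshold -> prior ->
        # dense closed form -> projection
        rel_qm = g.relation_between("q", "m")
        adj = rel_qm.adjacency_toward("m").toarray()
        mid = np.zeros(m_net.n_nodes)
        for i in range(m_net.n_nodes):
            neigh = [j for j in range(q_net.n_nodes) if adj[i, j]]
            if neigh:
                mid[i] = sum(x_q.values[j] for j in neigh) / len(neigh)
        n_zero = math.ceil(m_net.n_nodes * (1 - params.gamma))
        for i in sorted(range(len(mid)), key=lambda k: (mid[k], k))[:n_zero]:
            mid[i] = 0.0
        mid = mid / mid.sum()
        M = m_net.norm_adjacency.toarray()
        x_m = (1 - params.alpha) * np.linalg.solve(
            np.eye(m_net.n_nodes) - params.alpha * M, mid
        )
        S = g.relation_between("m", "t").norm_toward("t").toarray()
        np.testing.assert_allclose(res.projected, S @ x_m, atol=1e-10)


class TestScoreCorrelation:
    def test_proportional_vectors_score_one(self):
        pr = PathResult(
            NetworkPath(("q", "t")), StateVector("q", [1.0]),
            np.array([0.2, 0.4, 0.8]),
        )
        t_hat = StateVector("t", [0.1, 0.2, 0.4])
        assert score_correlation([pr], t_hat) == pytest.approx(1.0)

    def test_zero_projection_scores_zero(self):
        pr = PathResult(
            NetworkPath(("q", "t")), StateVector("q", [1.0]), np.zeros(3)
        )
        assert score_correlation([pr], StateVector("t", [0.1, 0.5, 0.2])) == 0.0

    def test_two_path_concatenation_frozen_value(self):
        # x = (0,1,2,0,2,4) vs t = (0,1,2) repeated: r = 36 / sqrt(1656),
        # from the textbook sum formula evaluated by hand
        prs = [
            PathResult(NetworkPath(("q", "t")), StateVector("q", [1.0]),
                       np.array([0.0, 1.0, 2.0])),
            PathResult(NetworkPath(("q", "m", "t")), StateVector("m", [1.0]),
                       np.array([0.0, 2.0, 4.0])),
        ]
        t_hat = StateVector("t", [0.0, 1.0, 2.0])
        expected = 36.0 / math.sqrt(1656.0)
        got = score_correlation(prs, t_hat)
        assert got == pytest.approx(expected, abs=1e-12)
        # second route: scipy on the concatenated vectors
        scipy_r = stats.pearsonr([0, 1, 2, 0, 2, 4], [0, 1, 2, 0, 1, 2])[0]
        assert got == pytest.approx(scipy_r, abs=1e-12)

    def test_pearson_zero_variance_convention(self):
        assert _pearson(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0])) == 0.0


class TestPrioritize:
    def test_ranking_is_complete(self, triangle_graph):
        ranking = prioritize(
            triangle_graph, {"q0"}, "q", "t", PropagationParams(gamma=0.5)
        )
        assert [r for _, _, r in ranking.entries] == [1, 2, 3, 4]
        scores = [s for _, s, _ in ranking.entries]
        assert scores == sorted(scores, reverse=True)
        assert all(-1 - 1e-12 <= s <= 1 + 1e-12 for s in scores)

    def test_automorphic_targets_tie_by_node_index(self):
        # t1 and t2 are mirror images w.r.t. the query's relation arcs
        g = build_global_graph(
            [("q", ["q0"], []),
             ("t", ["t0", "t1", "t2"], [("t0", "t1", 1.0), ("t0", "t2", 1.0)])],
            [("q", "t", [("q0", "t1", 1.0), ("q0", "t2", 1.0)])],
        )
        ranking = prioritize(g, {"q0"}, "q", "t", PropagationParams())
        scores = ranking.scores()
        assert scores["t1"] == pytest.approx(scores["t2"], abs=1e-12)
        assert ranking.rank_of("t1") < ranking.rank_of("t2")

    def test_empty_query_set_rejected(self, triangle_graph):
        with pytest.raises(ValidationError, match="query set"):
            prioritize(triangle_graph, set(), "q", "t")

    def test_node_permutation_leaves_scores_unchanged(self, rng):
        from conftest import tiny_triangle_graph

        g1 = tiny_triangle_graph()
        params = PropagationParams(gamma=0.5)
        s1 = prioritize(g1, {"q0"}, "q", "t", params).scores()
        # rebuild with the target network's node order reversed
        domain_specs = [
            ("q", ["q0", "q1", "q2", "q3"],
             [("q0", "q1", 1.0), ("q1", "q2", 0.5), ("q2", "q3", 0.8)]),
            ("m", ["m0", "m1", "m2"], [("m0", "m1", 1.0), ("m1", "m2", 0.4)]),
            ("t", ["t3", "t2", "t1", "t0"],
             [("t0", "t1", 0.6), ("t2", "t3", 0.9)]),
        ]
        relation_specs = [
            ("q", "m", [("q0", "m0", 1.0), ("q1", "m1", 0.7)]),
            ("m", "t", [("m0", "t0", 1.0), ("m2", "t2", 0.5)]),
            ("q", "t", [("q0", "t0", 1.0), ("q3", "t3", 0.3)]),
        ]
        g2 = build_global_graph(domain_specs, relation_specs)
        s2 = prioritize(g2, {"q0"}, "q", "t", params).scores()
        for node in s1:
            assert s1[node] == pytest.approx(s2[node], abs=1e-10)


def two_network_reference(Wq, Wt, R, query_idx, alpha):
    """Independent dense implementation of the two-network base case.

    Normalizes with explicit loops, solves both diffusions with
    numpy.linalg, projects through the relation and correlates — no shared
    code with the package internals.
    """
    def norm(N):
        N = np.asarray(N, dtype=float)
        out = np.zeros_like(N)
        rs, cs = N.sum(axis=1), N.sum(axis=0)
        for j in range(N.shape[0]):
            for k in range(N.shape[1]):
                if rs[j] > 0 and cs[k] > 0:
                    out[j, k] = N[j, k] / np.sqrt(rs[j] * cs[k])
        return out

    Mq, Mt, S = norm(Wq), norm(Wt), norm(R)  # S rows = query side
    nq, nt = Wq.shape[0], Wt.shape[0]
    x0 = np.zeros(nq)
    x0[list(query_idx)] = 1.0 / len(query_idx)
    xq = (1 - alpha) * np.linalg.solve(np.eye(nq) - alpha * Mq, x0)
    x_bar = S.T @ xq  # one value per target node
    inv_t = (1 - alpha) * np.linalg.inv(np.eye(nt) - alpha * Mt)
    scores = np.zeros(nt)
    for e in range(nt):
        t_bar = inv_t[:, e]
        xd, td = x_bar - x_bar.mean(), t_bar - t_bar.mean()
        den = np.sqrt((xd ** 2).sum() * (td ** 2).sum())
        scores[e] = (xd * td).sum() / den if den > 0 else 0.0
    order = np.lexsort((np.arange(nt), -scores))
    return scores, list(order)


class TestTwoNetworkReduction:
    def test_general_pipeline_equals_special_case(self, rng):
        alpha = 0.9
        for _ in range(10):
            nq, nt = int(rng.integers(6, 15)), int(rng.integers(6, 15))
            Wq = np.triu(rng.random((nq, nq)) * (rng.random((nq, nq)) < 0.4), 1)
            Wq = Wq + Wq.T
            Wt = np.triu(rng.random((nt, nt)) * (rng.random((nt, nt)) < 0.4), 1)
            Wt = Wt + Wt.T
            R = rng.random((nq, nt)) * (rng.random((nq, nt)) < 0.4)
            q_nodes = [f"g{i}" for i in range(nq)]
            t_nodes = [f"p{i}" for i in range(nt)]
            g = build_global_graph(
                [("gene", q_nodes,
                  [(q_nodes[i], q_nodes[j], Wq[i, j])
                   for i in range(nq) for j in range(i + 1, nq) if Wq[i, j]]),
                 ("disease", t_nodes,
                  [(t_nodes[i], t_nodes[j], Wt[i, j])
                   for i in range(nt) for j in range(i + 1, nt) if Wt[i, j]])],
                [("gene", "disease",
                  [(q_nodes[i], t_nodes[j], R[i, j])
                   for i in range(nq) for j in range(nt) if R[i, j]])],
            )
            query_idx = sorted(
                rng.choice(nq, size=int(rng.integers(1, 4)), replace=False)
            )
            ranking = prioritize(
                g, {q_nodes[i] for i in query_idx}, "gene", "disease",
                PropagationParams(alpha=alpha),
            )
            ref_scores, ref_order = two_network_reference(
                Wq, Wt, R, query_idx, alpha
            )
            got = ranking.scores()
            for e in range(nt):
                assert got[t_nodes[e]] == pytest.approx(
                    ref_scores[e], abs=1e-8
                )
            assert [name for name, _, _ in ranking.entries] == [
                t_nodes[i] for i in ref_order
            ]
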