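import numpy as np
import pytest

from infoflow import (
    build_hypergraph,
    compute_flow,
    edge_flow,
    restrict,
    stationary_distribution,
    transition_matrix,
)
from conftest import ev
from oracles import dense_stationary, digraph_transition, simulate_edge_flow


class TestBuild:
    def test_single_cascade(self):
        events = [ev("t0", "A", 0), ev("t1", "B", 0, root="t0"), ev("t2", "C", 0, root="t0")]
        H = build_hypergraph(events)
        (c,) = H.cascades
        assert c.tail == "A" and c.head == {"B", "C"} and c.head_size == 2

    def test_two_tweets_distinct_from_one_tweet_twice(self):
        # A posts twice, B retweets each: two size-1 hyper-edges,
        # not one size-2 edge -- the cascade structure is preserved.
        events = [
            ev("t0", "A", 0),
            ev("t1", "B", 0, root="t0"),
            ev("t2", "A", 1),
            ev("t3", "B", 1, root="t2"),
        ]
        H = build_hypergraph(events)
        assert H.n_edges == 2
        assert all(c.head_size == 1 for c in H.cascades)

    def test_unretweeted_original_contributes_node_only(self):
        H = build_hypergraph([ev("t0", "A", 0)])
        assert H.n_edges == 0 and H.nodes == ["A"]

    def test_duplicate_retweets_collapse(self):
        events = [
            ev("t0", "A", 0),
            ev("t1", "B", 0, root="t0"),
            ev("t2", "B", 1, root="t0"),
        ]
        H = build_hypergraph(events)
        assert H.n_edges == 1 and H.cascades[0].head == {"B"}

    def test_self_retweet_dropped(self):
        events = [ev("t0", "A", 0), ev("t1", "A", 0, root="t0"), ev("t2", "B", 0, root="t0")]
        H = build_hypergraph(events)
        assert H.cascades[0].head == {"B"}

    def test_orphan_root_gets_synthetic_tail(self):
        H = build_hypergraph([ev("t1", "B", 0, root="t_missing")])
        assert "B" in H.nodes
        assert any(n.startswith("unknown:") for n in H.nodes)
        assert H.n_edges == 1


class TestTransition:
    def test_two_hyperedge_hand_values(self, star_events):
        # edges <A,{B,C}> and <A,{B}>: T[A->B] = (1/2 + 1)/2, T[A->C] = (1/2)/2
        H = build_hypergraph(star_events)
        T, dangling = transition_matrix(H)
        i = H.node_index
        assert T[i["A"], i["B"]] == pytest.approx(0.75)
        assert T[i["A"], i["C"]] == pytest.approx(0.25)
        assert dangling[i["B"]] and dangling[i["C"]] and not dangling[i["A"]]

    def test_single_edge_unit_probability(self):
        H = build_hypergraph([ev("t0", "A", 0), ev("t1", "B", 0, root="t0")])
        T, _ = transition_matrix(H)
        assert T[H.node_index["A"], H.node_index["B"]] == 1.0

    def test_rows_stochastic_on_generated_stream(self, planted_sim_small):
        H = build_hypergraph(planted_sim_small.events)
        T, dangling = transition_matrix(H)
        sums = np.asarray(T.sum(axis=1)).ravel()
        assert np.allclose(sums[~dangling], 1.0, atol=1e-12)
        assert np.allclose(sums[dangling], 0.0)

    def test_unit_heads_equal_row_normalized_digraph(self, planted_sim_small):
        # with every head of size 1 the hypergraph walk degenerates to the
        # ordinary weighted retweet digraph
        events = [e for e in planted_sim_small.events]
        # keep only one retweet per root to force unit head sizes
        seen = set()
        filtered = []
        for e in events:
            if e.is_retweet:
                if e.root_tweet_id in seen:
                    continue
                seen.add(e.root_tweet_id)
            filtered.append(e)
        H = build_hypergraph(filtered)
        T, _ = transition_matrix(H)
        T_ref = digraph_transition(filtered, H.nodes)
        assert abs(T - T_ref).max() < 1e-12


class TestStationary:
    def test_symmetric_two_cycle(self, two_cycle_events):
        H = build_hypergraph(two_cycle_events)
        T, _ = transition_matrix(H)
        p = stationary_distribution(T, damping=1.0)
        assert np.allclose(p, [0.5, 0.5])

    def test_matches_dense_eigen_oracle(self, two_clique_events):
        H = build_hypergraph(two_clique_events)
        T, _ = transition_matrix(H)
        p = stationary_distribution(T, damping=0.85)
        assert np.allclose(p, dense_stationary(T, 0.85), atol=1e-9)
        assert p.sum() == pytest.approx(1.0)

    def test_chain_with_teleport_matches_oracle(self):
        events = [
            ev("t0", "A", 0),
            ev("t1", "B", 0, root="t0"),
            ev("t2", "B", 1),
            ev("t3", "C", 1, root="t2"),
        ]
        H = build_hypergraph(events)
        T, _ = transition_matrix(H)
        p = stationary_distribution(T, damping=0.85)
        assert np.allclose(p, dense_stationary(T, 0.85), atol=1e-9)

    def test_label_permutation_equivariance(self, star_events):
        H = build_hypergraph(star_events)
        T, _ = transition_matrix(H)
        p = stationary_distribution(T)
        renamed = [
            ev(e.tweet_id, {"A": "Z", "B": "B", "C": "C"}[e.user_id], e.day,
               root=e.root_tweet_id if e.is_retweet else None)
            for e in star_events
        ]
        H2 = build_hypergraph(renamed)
        T2, _ = transition_matrix(H2)
        p2 = stationary_distribution(T2)
        for old, new in [("A", "Z"), ("B", "B"), ("C", "C")]:
            assert p[H.node_index[old]] == pytest.approx(p2[H2.node_index[new]])

    def test_nonconvergence_raises(self, two_cycle_events):
        H = build_hypergraph(two_cycle_events)
        T, _ = transition_matrix(H)
        with pytest.raises(RuntimeError, match="converge"):
            stationary_distribution(T, damping=1.0, tol=0.0, max_iter=3)

    def test_empty_hypergraph_refused(self):
        H = build_hypergraph([ev("t0", "A", 0)])
        with pytest.raises(ValueError):
            transition_matrix(H)


class TestEdgeFlow:
    def test_two_cycle_half_half(self, two_cycle_events):
        H = build_hypergraph(two_cycle_events)
        flow = compute_flow(H, damping=1.0)
        F = flow.to_dense()
        i = H.node_index
        assert F[i["A"], i["B"]] == pytest.approx(0.5)
        assert F[i["B"], i["A"]] == pytest.approx(0.5)

    def test_total_mass_one_and_marginals(self, two_clique_events):
        H = build_hypergraph(two_clique_events)
        flow = compute_flow(H, damping=0.85)
        F = flow.to_dense()
        assert (F >= 0).all()
        assert F.sum() == pytest.approx(1.0)
        assert np.allclose(F.sum(axis=1), flow.p, atol=1e-9)  # sink marginal
        assert np.allclose(F.sum(axis=0), flow.p, atol=1e-9)  # source marginal

    def test_matches_monte_carlo_walk(self, star_events):
        H = build_hypergraph(star_events)
        flow = compute_flow(H, damping=0.85)
        F_hat = simulate_edge_flow(H, damping=0.85, n_steps=200_000, seed=42)
        assert np.abs(flow.to_dense() - F_hat).max() < 0.01

    def test_dimension_mismatch_fatal(self, two_cycle_events):
        H = build_hypergraph(two_cycle_events)
        T, _ = transition_matrix(H)
        with pytest.raises(ValueError):
            edge_flow(T, np.array([1.0]))


class TestRestrict:
    def test_full_subset_identity(self, planted_sim_small):
        H = build_hypergraph(planted_sim_small.events)
        H2 = restrict(H, planted_sim_small.events)
        assert H2.n_edges == H.n_edges
        assert H2.nodes == H.nodes

    def test_single_cascade_subset(self, star_events):
        H = build_hypergraph(star_events)
        subset = [e for e in star_events if e.root_tweet_id == "t0"]
        H2 = restrict(H, subset)
        assert H2.n_edges == 1 and H2.cascades[0].head == {"B", "C"}
        assert set(H2.nodes) >= set(H.nodes)

    def test_disjoint_subset_empty_edges(self, star_events):
        H = build_hypergraph(star_events)
        H2 = restrict(H, [])
        assert H2.n_edges == 0 and set(H2.nodes) == set(H.nodes)
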