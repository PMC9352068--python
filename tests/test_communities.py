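import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from infoflow import (
    build_hypergraph,
    classify_events,
    compute_flow,
    detect_communities,
    edge_flow,
    escape_probability,
    partition_dict,
    partition_quality,
    per_period_flow,
    stationary_distribution,
    visit_probability,
)
from infoflow.synthetic import (
    GeneratorConfig,
    default_catalog,
    planted_partition_config,
    simulate,
)
from conftest import ev
from oracles import best_partition_bruteforce, best_two_partition, digraph_transition


class TestDetect:
    def test_two_cliques_recovered_and_match_bruteforce(self, two_clique_events):
        H = build_hypergraph(two_clique_events)
        flow = compute_flow(H, damping=0.85)
        labels = detect_communities(flow, seed=0)
        planted = [0 if n.startswith("a") else 1 for n in H.nodes]
        assert adjusted_rand_score(planted, labels) == 1.0
        # detected quality is at least the best over all <=2-block splits
        q_best = best_two_partition(flow)
        assert partition_quality(flow, labels) >= q_best - 1e-9

    def test_single_clique_not_split(self):
        # all-to-all retweeting among 5 users: one community is optimal
        events = []
        tid = 0
        for day, poster in enumerate("abcde"):
            root = f"t{tid}"
            events.append(ev(root, poster, day))
            tid += 1
            for other in "abcde":
                if other != poster:
                    events.append(ev(f"t{tid}", other, day, root=root))
                    tid += 1
        H = build_hypergraph(events)
        flow = compute_flow(H, damping=0.85)
        labels = detect_communities(flow, seed=0)
        assert labels.max() == 0
        q_best, best_labels = best_partition_bruteforce(flow)
        assert len(set(best_labels)) == 1

    def test_planted_partition_recovery(self, planted_sim_small):
        H = build_hypergraph(planted_sim_small.events)
        flow = compute_flow(H)
        labels = detect_communities(flow, seed=0)
        truth = planted_sim_small.truth.partition()
        planted = [truth.get(u, -1) for u in H.nodes]
        assert adjusted_rand_score(planted, labels) >= 0.9

    def test_deterministic_given_seed(self, planted_sim_small):
        H = build_hypergraph(planted_sim_small.events)
        flow = compute_flow(H)
        a = detect_communities(flow, seed=3)
        b = detect_communities(flow, seed=3)
        assert (a == b).all()

    def test_labels_ordered_by_size(self, planted_sim_small):
        H = build_hypergraph(planted_sim_small.events)
        labels = detect_communities(compute_flow(H), seed=0)
        sizes = np.bincount(labels)
        assert (np.diff(sizes) <= 0).all()
        assert set(labels) == set(range(labels.max() + 1))

    def test_quality_beats_trivial_partitions(self, two_clique_events):
        H = build_hypergraph(two_clique_events)
        flow = compute_flow(H, damping=0.85)
        labels = detect_communities(flow, seed=0)
        n = flow.n
        q = partition_quality(flow, labels)
        assert q >= partition_quality(flow, np.zeros(n, dtype=int)) - 1e-12
        assert q >= partition_quality(flow, np.arange(n)) - 1e-12

    def test_unit_heads_match_digraph_oracle(self, planted_sim_small):
        # with unit head sizes, flow clustering on the hypergraph equals
        # clustering of the row-normalized retweet digraph
        seen, filtered = set(), []
        for e in planted_sim_small.events:
            if e.is_retweet:
                if e.root_tweet_id in seen:
                    continue
                seen.add(e.root_tweet_id)
            filtered.append(e)
        H = build_hypergraph(filtered)
        flow = compute_flow(H)
        labels = detect_communities(flow, seed=0)
        T_ref = digraph_transition(filtered, H.nodes)
        p_ref = stationary_distribution(T_ref, damping=0.85)
        flow_ref = edge_flow(T_ref, p_ref, damping=0.85)
        labels_ref = detect_communities(flow_ref, seed=0)
        assert adjusted_rand_score(labels, labels_ref) == 1.0


class TestDiagnostics:
    def test_uniform_visit_probability(self):
        p = np.full(10, 0.1)
        labels = np.array([0] * 4 + [1] * 6)
        assert np.allclose(visit_probability(labels, p), 0.1)

    def test_singleton_visit_is_node_mass(self):
        p = np.array([0.5, 0.3, 0.2])
        labels = np.array([0, 1, 2])
        assert np.allclose(visit_probability(labels, p), p)

    def test_three_node_hand_computed(self):
        p = np.array([0.5, 0.3, 0.2])
        labels = np.array([0, 0, 1])
        assert np.allclose(visit_probability(labels, p), [0.4, 0.2])

    def test_escape_zero_for_whole_graph_community(self, two_clique_events):
        H = build_hypergraph(two_clique_events)
        flow = compute_flow(H, damping=0.85)
        esc = escape_probability(np.zeros(flow.n, dtype=int), flow)
        assert esc[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_cycle_singletons_escape_one(self, two_cycle_events):
        H = build_hypergraph(two_cycle_events)
        flow = compute_flow(H, damping=1.0)
        esc = escape_probability(np.array([0, 1]), flow)
        assert np.allclose(esc, 1.0)

    def test_escape_within_unit_interval(self, planted_sim_small):
        H = build_hypergraph(planted_sim_small.events)
        flow = compute_flow(H)
        labels = detect_communities(flow, seed=0)
        esc = escape_probability(labels, flow)
        assert np.all((esc >= 0) & (esc <= 1))

    def test_visit_mass_sums_to_one(self, planted_sim_small):
        H = build_hypergraph(planted_sim_small.events)
        flow = compute_flow(H)
        labels = detect_communities(flow, seed=0)
        sizes = np.bincount(labels)
        assert float((visit_probability(labels, flow.p) * sizes).sum()) == pytest.approx(1.0)


class TestEchoChamber:
    def test_echo_block_escapes_less_on_category_subgraph(self, echo_sim_small):
        cfg, result = echo_sim_small
        catalog = default_catalog(cfg)
        partition = result.truth.partition()
        nodes = sorted(partition)

        def block_stats(category):
            selected = classify_events(result.events, catalog, category)
            H = build_hypergraph(selected, keep_nodes=nodes)
            flow = compute_flow(H)
            labels = np.array([partition.get(u, -1) for u in H.nodes])
            esc, vis = {}, {}
            for b in (0, 1):
                mask = labels == b
                mass = flow.p[mask].sum()
                esc[b] = 1.0 - flow.block_flow(mask, mask) / mass
                vis[b] = mass / mask.sum()
            return esc, vis

        esc_cat, vis_cat = block_stats("vaccine_critical")
        assert esc_cat[0] < esc_cat[1]  # echo chamber leaks less
        assert vis_cat[0] > vis_cat[1]  # and is visited more per capita
        esc_media, _ = block_stats("media")
        assert esc_media[0] >= esc_media[1]  # ordering reverses on media


class TestPerPeriod:
    def test_single_period_equals_global(self, echo_sim_small):
        cfg, result = echo_sim_small
        catalog = default_catalog(cfg)
        partition = result.truth.partition()
        table = per_period_flow(result.events, [], partition, catalog, subgraphs=("all",))
        assert table["period"].nunique() == 1
        nodes = sorted(partition)
        H = build_hypergraph(result.events, keep_nodes=nodes)
        flow = compute_flow(H)
        labels = np.array([partition.get(u, -1) for u in H.nodes])
        for b in sorted(set(partition.values())):
            mask = labels == b
            expected = flow.p[mask].sum() / mask.sum()
            got = table[(table["community"] == b)]["avg_visit"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-9)

    def test_outward_mixing_shift_raises_escape(self):
        # block 0 doubles its outward mixing in period 2
        m1 = ((0.9, 0.1), (0.1, 0.9))
        m2 = ((0.6, 0.4), (0.1, 0.9))
        cfg = GeneratorConfig(
            n_users=200, block_sizes=(100, 100), tweet_rate=0.3, media_url_prob=1.0,
            alpha=0.0, n_seed_engaged=0, n_days=40, seed=2,
            period_breaks=(20,), period_mixing=(m1, m2), mixing=m1,
        )
        result = simulate(cfg)
        catalog = default_catalog(cfg)
        partition = result.truth.partition()
        table = per_period_flow(result.events, [20], partition, catalog, subgraphs=("all",))
        esc = table[table["community"] == 0].set_index("period")["escape"]
        assert esc[1] > esc[0]

    def test_empty_period_marked(self, echo_sim_small):
        cfg, result = echo_sim_small
        catalog = default_catalog(cfg)
        partition = result.truth.partition()
        hi = max(e.day for e in result.events)
        table = per_period_flow(
            result.events, [hi], partition, catalog, subgraphs=("vaccine_critical",)
        )
        assert set(table["period"]) == {0, 1}
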