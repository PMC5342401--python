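"""Scoring, filtering, expansion, clustering and leader identification."""

import numpy as np
import pytest

from leadnet import (InteractionNetwork, LeaderGeneModel, ValidationError,
                     class_separation_test, cluster_scores, compute_tis,
                     compute_wnl, expand_seed, filter_by_confidence,
                     identify_leaders)
from leadnet.simulate import planted_leader_inputs

from conftest import random_network


def brute_force_scores(net):
    """Independent double-loop oracle for WNL and TIS."""
    wnl = {n: 0.0 for n in net.nodes}
    tis = {n: 0 for n in net.nodes}
    for node in net.nodes:
        for a, b, s in net.edges():
            if node in (a, b):
                wnl[node] += s
                t = int(np.floor(1000 * s + 0.5))
                tis[node] += t
    return wnl, tis


class TestScores:
    def test_triangle_hand_values(self, triangle):
        assert compute_wnl(triangle) == pytest.approx(
            {"A": 1.85, "B": 1.89, "C": 1.94})
        assert compute_tis(triangle) == {"A": 1850, "B": 1890, "C": 1940}

    def test_isolated_node_scores_zero(self):
        net = InteractionNetwork(nodes=["Z"])
        assert compute_wnl(net) == {"Z": 0.0}
        assert compute_tis(net) == {"Z": 0}

    def test_unit_score_edge(self):
        net = InteractionNetwork([("A", "B", 1.0)])
        assert compute_wnl(net) == {"A": 1.0, "B": 1.0}

    def test_tis_rounds_half_away_from_zero(self):
        net = InteractionNetwork([("A", "B", 0.8505)])
        assert compute_tis(net) == {"A": 851, "B": 851}

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            net = random_network(rng, max_nodes=20)
            wnl_oracle, tis_oracle = brute_force_scores(net)
            assert compute_wnl(net) == pytest.approx(wnl_oracle, abs=0)
            assert compute_tis(net) == tis_oracle

    def test_adding_edge_never_decreases_scores(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, max_nodes=12)
        before = compute_wnl(net)
        nodes = sorted(net.nodes)
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                 if not net.has_edge(a, b)]
        if pairs:
            a, b = pairs[0]
            net.add_edge(a, b, 0.5)
            after = compute_wnl(net)
            assert all(after[n] >= before[n] for n in before)


class TestConfidenceFilter:
    def test_inclusive_band_keeps_boundary_scores(self, banded_net):
        kept = filter_by_confidence(banded_net, 0.90, 0.99)
        assert sorted(s for _, _, s in kept.edges()) == [0.90, 0.95, 0.99]
        assert kept.nodes == banded_net.nodes  # isolated nodes retained

    def test_identity_band_keeps_everything(self, banded_net):
        assert filter_by_confidence(banded_net, 1e-4, 1.0).equals(banded_net)

    def test_empty_band_isolates_all_nodes(self):
        net = InteractionNetwork([("A", "B", 0.9), ("B", "C", 0.9)])
        out = filter_by_confidence(net, 0.999, 0.999)
        assert out.n_edges == 0 and out.nodes == {"A", "B", "C"}

    def test_inverted_band_rejected(self, banded_net):
        with pytest.raises(ValidationError):
            filter_by_confidence(banded_net, 0.99, 0.9)

    def test_nested_bands_give_nested_edge_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = random_network(rng, max_nodes=15)
            inner = {e[:2] for e in filter_by_confidence(net, 0.4, 0.6).edges()}
            outer = {e[:2] for e in filter_by_confidence(net, 0.2, 0.8).edges()}
            assert inner <= outer


class TestSeedExpansion:
    @pytest.fixture
    def filtered(self):
        # B-D at 0.85 falls outside the band and is pre-filtered away
        net = InteractionNetwork(
            [("A", "C", 0.95), ("B", "D", 0.85), ("C", "E", 0.92)])
        return filter_by_confidence(net, 0.9, 0.99)

    def test_one_step_reaches_direct_partners(self, filtered, caplog):
        with caplog.at_level("WARNING", logger="leadnet"):
            sub = expand_seed(filtered, ["A", "B"], steps=1)
        assert sub.nodes == {"A", "B", "C"}
        assert [e[:2] for e in sub.edges()] == [("A", "C")]

    def test_two_steps_reach_second_shell(self, filtered):
        sub = expand_seed(filtered, ["A", "B"], steps=2)
        assert sub.nodes == {"A", "B", "C", "E"}
        assert [e[:2] for e in sub.edges()] == [("A", "C"), ("C", "E")]

    def test_zero_steps_returns_seed_induced_subgraph(self, filtered):
        sub = expand_seed(filtered, ["A", "B"], steps=0)
        assert sub.nodes == {"A", "B"} and sub.n_edges == 0

    def test_missing_seed_kept_isolated_with_warning(self, filtered, caplog):
        with caplog.at_level("WARNING", logger="leadnet"):
            sub = expand_seed(filtered, ["A", "ZZZ9"], steps=1)
        assert "ZZZ9" in sub.nodes and sub.degree("ZZZ9") == 0
        assert any("ZZZ9" in r.message for r in caplog.records)

    def test_empty_seed_list_rejected(self, filtered):
        with pytest.raises(ValidationError):
            expand_seed(filtered, [], steps=1)

    def test_node_set_monotone_in_steps(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = random_network(rng, max_nodes=20)
            seeds = sorted(net.nodes)[:2]
            prev = set()
            for steps in range(5):
                cur = expand_seed(net, seeds, steps).nodes
                assert prev <= cur
                prev = cur
            # beyond the diameter the closure equals the seed components
            import networkx as nx
            comp = set(seeds)
            for s in seeds:
                comp |= nx.node_connected_component(net.graph, s)
            assert expand_seed(net, seeds, 100).nodes == comp


class TestClustering:
    def test_two_class_split_of_bimodal_scores(self):
        scores = {"A": 10, "B": 11, "C": 9, "D": 0.5, "E": 0.4}
        part = cluster_scores(scores, n_classes=2)
        assert part.classes[0] == ["A", "B", "C"]
        assert part.classes[1] == ["D", "E"]
        assert part.class_means == pytest.approx([10.0, 0.45])

    def test_single_class_degenerate(self):
        part = cluster_scores({"A": 1, "B": 2}, n_classes=1)
        assert part.classes == [["A", "B"]]

    def test_indistinguishable_scores_rejected(self):
        with pytest.raises(ValidationError):
            cluster_scores({"A": 5, "B": 5, "C": 5}, n_classes=2)

    def test_class_means_strictly_decreasing(self):
        rng = np.random.default_rng(2)
        scores = {f"G{i}": float(v) for i, v in enumerate(rng.uniform(0, 10, 30))}
        part = cluster_scores(scores, n_classes=4)
        assert all(a > b for a, b in zip(part.class_means, part.class_means[1:]))


class TestClassSeparation:
    def test_hand_computed_f_and_p(self):
        scores = {"A": 1, "B": 2, "C": 3, "D": 11, "E": 12, "F": 13}
        part = cluster_scores(scores, n_classes=2)
        sep = class_separation_test(part, scores)
        assert sep.anova.f_statistic == pytest.approx(150.0)
        assert sep.anova_p == pytest.approx(0.00026, abs=2e-5)
        assert sep.anova_p < 0.001

    def test_identical_class_values_give_f_zero_p_one(self):
        from leadnet.leader import ClassPartition
        part = ClassPartition(classes=[["A", "B"], ["C", "D"]],
                              class_means=[5.0, 5.0])
        sep = class_separation_test(part, {"A": 5, "B": 5, "C": 5, "D": 5})
        assert sep.anova.f_statistic == 0.0 and sep.anova_p == 1.0

    def test_singleton_classes_excluded_with_warning(self, caplog):
        from leadnet.leader import ClassPartition
        part = ClassPartition(classes=[["A"], ["B", "C"], ["D", "E"]],
                              class_means=[9.0, 5.0, 1.0])
        scores = {"A": 9, "B": 5, "C": 5.1, "D": 1, "E": 1.2}
        with caplog.at_level("WARNING", logger="leadnet"):
            sep = class_separation_test(part, scores)
        assert sep.excluded_classes == [1]

    def test_too_few_usable_classes_rejected(self):
        from leadnet.leader import ClassPartition
        part = ClassPartition(classes=[["A"], ["B", "C"]], class_means=[9, 1])
        with pytest.raises(ValidationError):
            class_separation_test(part, {"A": 9, "B": 1, "C": 1.1})


class TestLeaders:
    def test_top_wnl_class_are_leaders(self):
        scores = {"A": 10, "B": 11, "C": 9, "D": 0.5, "E": 0.4}
        part = cluster_scores(scores, n_classes=2)
        tis = {g: int(1000 * v) for g, v in scores.items()}
        res = identify_leaders(part, scores, tis)
        assert res.leaders == {"A", "B", "C"} and res.leader_class == 1

    def test_tp53_hub_is_sole_leader(self):
        # TP53 with strictly maximal WNL and TIS in a small hub network
        net = InteractionNetwork(
            [("TP53", "CASP3", 0.95), ("TP53", "MDM2", 0.99),
             ("TP53", "CDKN1A", 0.93), ("TP53", "BAX", 0.97),
             ("CASP3", "BAX", 0.91)])
        model = LeaderGeneModel(net, min_score=0.9, max_score=0.99, n_classes=2)
        res = model.fit()
        assert res.leaders.leaders == {"TP53"}

    def test_single_class_means_everyone_leads(self):
        part = cluster_scores({"A": 1, "B": 2}, n_classes=1)
        res = identify_leaders(part, {"A": 1, "B": 2}, {"A": 1000, "B": 2000})
        assert res.leaders == {"A", "B"}

    def test_wnl_tis_discordance_warns(self):
        from leadnet.leader import ClassPartition
        part = ClassPartition(classes=[["A"], ["B"]], class_means=[2.0, 1.0])
        res = identify_leaders(part, {"A": 2, "B": 1}, {"A": 1000, "B": 5000})
        assert res.leaders == {"A"}
        assert any("discordance" in w for w in res.warnings)


class TestModelResults:
    def test_planted_module_recovered_end_to_end(self):
        net, planted, seeds = planted_leader_inputs(11)
        res = LeaderGeneModel(net, seeds=seeds).fit()
        assert res.leaders.leaders == planted
        assert res.separation.anova_p < 0.001

    def test_summary_names_leaders_and_classes(self):
        net, planted, seeds = planted_leader_inputs(4)
        res = LeaderGeneModel(net, seeds=seeds).fit()
        text = res.summary()
        assert "Leader-gene analysis" in text
        for gene in sorted(planted):
            assert gene in text

    def test_scores_table_consistent_with_partition(self):
        net, _, seeds = planted_leader_inputs(8)
        res = LeaderGeneModel(net, seeds=seeds).fit()
        labels = res.partition.label_of()
        assert all(labels[g] == c for g, c in
                   zip(res.scores["gene"], res.scores["class_label"]))
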