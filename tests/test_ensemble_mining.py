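"""Ensemble aggregation: rankings, pair extraction, and networks."""

import itertools
from collections import Counter

import networkx as nx
import pytest

from conftest import random_rulesets, separable_matrix
from proteorules import (
    LearnerConfig,
    build_network,
    extract_pairs,
    most_connected,
    rank_proteins,
    run_ensemble,
)
from proteorules.ensemble_mining import MiningError, PairNetwork
from proteorules.rule_learner import parse_ruleset, serialize_ruleset


def brute_force_counts(rulesets):
    """Independent recomputation of rankings and pairs from the serialized
    text of each rule set (the mining oracle)."""
    feature_counts: dict[str, Counter] = {}
    pair_counts: dict[str, Counter] = {}
    for rs in rulesets:
        reparsed = parse_ruleset(serialize_ruleset(rs))
        for rule in reparsed.rules:
            feats = sorted({c.feature for c in rule.conditions})
            feature_counts.setdefault(rule.predicted_class, Counter()).update(feats)
            for pair in itertools.combinations(feats, 2):
                pair_counts.setdefault(rule.predicted_class, Counter())[pair] += 1
    return feature_counts, pair_counts


class TestRanking:
    def test_printed_ruleset_counts(self, printed_ruleset_text):
        rs = parse_ruleset(printed_ruleset_text)
        ranking = rank_proteins([rs])
        il1b = dict((f, c) for f, c, _ in ranking.per_class["IL-1β"])
        assert il1b == {"TPIS": 1, "MMP-3": 1, "UBIB": 1}
        carprofen = dict((f, c) for f, c, _ in ranking.per_class["carprofen"])
        assert carprofen == {"MGP": 1, "A1AT": 1}

    def test_default_class_never_ranked(self):
        rulesets = random_rulesets(30, seed=1)
        ranking = rank_proteins(rulesets)
        assert "control" not in ranking.per_class

    def test_duplicating_rulesets_doubles_counts_keeps_shares(self):
        rulesets = random_rulesets(10, seed=2)
        once = rank_proteins(rulesets)
        twice = rank_proteins(rulesets + rulesets)
        for cls in once.per_class:
            c1 = {f: (c, s) for f, c, s in once.per_class[cls]}
            c2 = {f: (c, s) for f, c, s in twice.per_class[cls]}
            assert set(c1) == set(c2)
            for f in c1:
                assert c2[f][0] == 2 * c1[f][0]
                assert c2[f][1] == pytest.approx(c1[f][1])

    def test_zero_rule_sets_rank_empty(self):
        rulesets = random_rulesets(5, seed=99)
        empty = [rs for rs in rulesets if len(rs) == 0]
        if not empty:  # force one
            from proteorules.rule_learner import RuleSet
            empty = [RuleSet((), "control")]
        assert rank_proteins(empty).per_class == {}

    def test_ranking_matches_bruteforce_oracle(self):
        rulesets = random_rulesets(60, seed=5)
        ranking = rank_proteins(rulesets)
        oracle_feats, _ = brute_force_counts(rulesets)
        assert set(ranking.per_class) == set(oracle_feats)
        for cls, rows in ranking.per_class.items():
            assert dict((f, c) for f, c, _ in rows) == dict(oracle_feats[cls])
            total = sum(oracle_feats[cls].values())
            for f, c, share in rows:
                assert share == pytest.approx(100.0 * c / total)
            # sorted by count desc, ties lexicographic
            assert rows == sorted(rows, key=lambda r: (-r[1], r[0]))

    def test_monotone_in_runs(self):
        rulesets = random_rulesets(40, seed=6)
        small = rank_proteins(rulesets[:20])
        large = rank_proteins(rulesets)
        for cls, rows in small.per_class.items():
            small_feats = {f for f, _, _ in rows}
            large_feats = {f for f, _, _ in large.per_class[cls]}
            assert small_feats <= large_feats


class TestPairs:
    def test_printed_rules_give_the_two_pairs(self, printed_ruleset_text):
        rs = parse_ruleset(printed_ruleset_text)
        pairs = extract_pairs([rs])
        assert pairs["IL-1β"] == Counter({("MMP-3", "UBIB"): 1})
        assert pairs["carprofen"] == Counter({("A1AT", "MGP"): 1})
        assert "IL-1β+carprofen" not in pairs  # single-feature rules only

    def test_three_feature_rule_gives_three_pairs(self):
        text = "IF A > 1 AND B > 2 AND C > 3 THEN x\nDEFAULT c\n"
        pairs = extract_pairs([parse_ruleset(text)])
        assert pairs["x"] == Counter({("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1})

    def test_pairs_match_bruteforce_oracle(self):
        rulesets = random_rulesets(60, seed=8)
        pairs = extract_pairs(rulesets)
        _, oracle_pairs = brute_force_counts(rulesets)
        assert {c: dict(p) for c, p in pairs.items()} == \
            {c: dict(p) for c, p in oracle_pairs.items()}


class TestNetwork:
    def test_top_k_retained_per_class(self):
        counts = {"x": Counter({(f"A{i}", f"B{i}"): i + 1 for i in range(7)})}
        net = build_network(counts, k=3)
        assert len(net.edges) == 3
        kept = {(a, b) for a, b, _, _ in net.edges}
        assert kept == {("A6", "B6"), ("A5", "B5"), ("A4", "B4")}

    def test_class_with_fewer_pairs_keeps_all(self):
        counts = {"x": Counter({("A", "B"): 2, ("A", "C"): 1})}
        net = build_network(counts, k=100)
        assert len(net.edges) == 2

    def test_k1_deterministic_tie_break(self):
        counts = {"x": Counter({("B", "C"): 2, ("A", "D"): 2})}
        net = build_network(counts, k=1)
        assert net.edges == [("A", "D", "x", 2)]

    def test_edge_budget_bounded_by_k_times_classes(self):
        rulesets = random_rulesets(80, seed=12)
        pairs = extract_pairs(rulesets)
        net = build_network(pairs, k=5)
        assert len(net.edges) <= 5 * len(pairs)
        per_class = Counter(cls for _, _, cls, _ in net.edges)
        assert all(v <= 5 for v in per_class.values())

    def test_no_self_loops_and_sorted_endpoints(self):
        rulesets = random_rulesets(50, seed=13)
        net = build_network(extract_pairs(rulesets), k=100)
        for a, b, _, _ in net.edges:
            assert a < b

    def test_most_connected_star(self):
        edges = [("H", leaf, "x", 1) for leaf in ["a", "b", "c", "d", "e"]]
        edges = [(min(a, b), max(a, b), c, n) for a, b, c, n in edges]
        net = PairNetwork(nodes={"H", "a", "b", "c", "d", "e"}, edges=edges, k=10)
        ranked = most_connected(net, top_n=3)
        assert ranked[0] == ("H", 5)
        assert all(deg == 1 for _, deg in ranked[1:])

    def test_top_n_capped_at_node_count(self):
        net = PairNetwork(nodes={"a", "b"}, edges=[("a", "b", "x", 1)], k=1)
        assert len(most_connected(net, top_n=10)) == 2

    def test_planted_hub_ranks_among_most_connected(self):
        """A feature that co-occurs with many partners in two-condition
        rules ends up in the network's top-connected nodes, across seeds."""
        from proteorules.rule_learner import Condition, Rule, RuleSet
        import numpy as np
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rules = []
            for _ in range(60):
                if rng.random() < 0.5:  # hub rule: HUB paired with a random partner
                    partner = f"P{int(rng.integers(12)):02d}"
                    rules.append(Rule((Condition("HUB", ">", 0.1),
                                       Condition(partner, "<", 0.5)), "x"))
                else:  # background pair between two random partners
                    a, b = rng.choice(12, size=2, replace=False)
                    rules.append(Rule((Condition(f"P{a:02d}", ">", 0.1),
                                       Condition(f"P{b:02d}", ">", 0.2)), "y"))
            net = build_network(extract_pairs([RuleSet(tuple(rules), "control")]), k=100)
            top3 = [n for n, _ in most_connected(net, top_n=3)]
            hits += "HUB" in top3
        assert hits >= 9

    def test_empty_network_rejected(self):
        with pytest.raises(MiningError):
            most_connected(PairNetwork(nodes=set(), edges=[], k=1), 3)

    def test_networkx_export_carries_attributes(self):
        counts = {"IL-1β": Counter({("A", "B"): 3}),
                  "carprofen": Counter({("A", "B"): 2})}
        g = build_network(counts, k=10).to_networkx()
        assert isinstance(g, nx.MultiGraph)
        assert g.number_of_edges() == 2  # one parallel edge per class
        data = g.get_edge_data("A", "B")
        assert data["IL-1β"]["colour"] == "#0000ff"
        assert data["carprofen"]["colour"] == "#ff0000"
        assert data["IL-1β"]["count"] == 3


class TestEnsemble:
    def test_ensemble_reproducible_and_seeded_consecutively(self, separable,
                                                            quick_learner):
        a = run_ensemble(separable, quick_learner, n_runs=3, base_seed=10)
        b = run_ensemble(separable, quick_learner, n_runs=3, base_seed=10)
        assert [serialize_ruleset(x) for x in a] == [serialize_ruleset(x) for x in b]
        assert [rs.training_seed for rs in a] == [10, 11, 12]

    def test_all_runs_use_the_unique_separator(self, quick_learner):
        """On a toy where planted proteins are the only separators, every
        ensemble run builds its rules on them."""
        m = separable_matrix(n_per_class=4, seed=3)
        rulesets = run_ensemble(m, quick_learner, n_runs=30, base_seed=0)
        for rs in rulesets:
            feats = {c.feature for r in rs.rules for c in r.conditions}
            assert feats & {"A|empai", "B|empai"}
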