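"""Mining ensembles of rule sets for protein rankings and pair networks.

Because the rule learner is stochastic, a single run is only one sample
of the models that explain the data. Running it many times (10,000 in the
original analysis) and counting how often each protein feature appears in
rules for each treatment class yields a per-class biomarker ranking;
counting how often two features co-occur in the same multi-condition rule
yields a per-class weighted protein-pair network.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .quantify import SampleQuantMatrix
from .rule_learner import LearnerConfig, RuleSet, learn_ruleset

logger = logging.getLogger(__name__)

# Edge colours per treatment class, matching the published network figures;
# other class names fall back to a small qualitative palette.
CLASS_COLOURS = {
    "IL-1β": "#0000ff",            # blue
    "carprofen": "#ff0000",        # red
    "IL-1β+carprofen": "#00aa00",  # green
}
_FALLBACK_COLOURS = ("#9467bd", "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf")


class MiningError(ValueError):
    pass


@dataclass
class ProteinRanking:
    """Per-class feature usage across an ensemble of rule sets.

    ``per_class`` maps each non-default class to ``(feature, count, share)``
    triples sorted by count descending (ties lexicographic); ``share`` is
    the percentage of that class's total feature-appearances. The default
    class never appears: it has no rules.
    """

    per_class: dict[str, list[tuple[str, int, float]]]
    n_runs: int
    n_rules_per_class: dict[str, int] = field(default_factory=dict)

    def top(self, cls: str, n: int) -> list[str]:
        return [feat for feat, _, _ in self.per_class.get(cls, [])[:n]]


@dataclass
class PairNetwork:
    """Per-class weighted protein-pair graph.

    Edges are ``(feature_a, feature_b, class, count)`` with the endpoints
    in lexicographic order; at most ``k`` edges are retained per class.
    """

    nodes: set[str]
    edges: list[tuple[str, str, str, int]]
    k: int

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(sorted(self.nodes))
        classes = sorted({cls for _, _, cls, _ in self.edges})
        colours = dict(CLASS_COLOURS)
        fallback = itertools.cycle(_FALLBACK_COLOURS)
        for cls in classes:
            colours.setdefault(cls, next(fallback))
        for a, b, cls, count in self.edges:
            g.add_edge(a, b, key=cls, treatment_class=cls, count=count,
                       colour=colours[cls])
        return g


# ---------------------------------------------------------------------------
# ensemble


def run_ensemble(m: SampleQuantMatrix, config: LearnerConfig, n_runs: int,
                 base_seed: int, log_every: int = 1000) -> list[RuleSet]:
    """Train ``n_runs`` rule sets on the full matrix with consecutive seeds
    ``base_seed .. base_seed + n_runs - 1``."""
    if n_runs < 1:
        raise MiningError(f"n_runs must be >= 1, got {n_runs}")
    rulesets = []
    for i in range(n_runs):
        try:
            rulesets.append(
                learn_ruleset(m, dataclasses.replace(config, seed=base_seed + i)))
        except Exception as exc:
            raise MiningError(f"learner failed on ensemble run {i}: {exc}") from exc
        if log_every and (i + 1) % log_every == 0:
            logger.info("ensemble: %d/%d runs complete", i + 1, n_runs)
    return rulesets


# ---------------------------------------------------------------------------
# mining


def rank_proteins(rulesets: list[RuleSet]) -> ProteinRanking:
    """Count, per non-default class, how many rules each feature appears in.

    A feature is counted once per rule however many of the rule's
    conditions use it, and is attributed to the rule's predicted class.
    ``share`` is ``100 * count / total feature-appearances in that class``.
    """
    if not rulesets:
        raise MiningError("need at least one rule set")
    counts: dict[str, Counter] = {}
    n_rules: Counter = Counter()
    for rs in rulesets:
        for rule in rs.rules:
            cls = rule.predicted_class
            n_rules[cls] += 1
            bucket = counts.setdefault(cls, Counter())
            for feat in rule.features:
                bucket[feat] += 1
    per_class = {}
    for cls, bucket in counts.items():
        total = sum(bucket.values())
        ranked = sorted(bucket.items(), key=lambda kv: (-kv[1], kv[0]))
        per_class[cls] = [(feat, cnt, 100.0 * cnt / total) for feat, cnt in ranked]
    return ProteinRanking(per_class=per_class, n_runs=len(rulesets),
                          n_rules_per_class=dict(n_rules))


def extract_pairs(rulesets: list[RuleSet]) -> dict[str, Counter]:
    """Per-class counts of unordered feature pairs co-occurring in a rule.

    Every rule using >= 2 distinct features contributes one count for each
    of its 2-subsets to the rule's class; single-feature rules contribute
    nothing.
    """
    if not rulesets:
        raise MiningError("need at least one rule set")
    pairs: dict[str, Counter] = {}
    for rs in rulesets:
        for rule in rs.rules:
            feats = rule.features  # distinct, sorted
            if len(feats) < 2:
                continue
            bucket = pairs.setdefault(rule.predicted_class, Counter())
            for a, b in itertools.combinations(feats, 2):
                bucket[(a, b)] += 1
    return pairs


def build_network(pair_counts: dict[str, Counter], k: int = 100) -> PairNetwork:
    """Retain the ``k`` most frequent pairs per class and merge them into
    one graph; classes with fewer than ``k`` distinct pairs keep them all.
    Ties are broken lexicographically for reproducibility."""
    if k < 1:
        raise MiningError(f"k must be >= 1, got {k}")
    edges: list[tuple[str, str, str, int]] = []
    nodes: set[str] = set()
    for cls in sorted(pair_counts):
        ranked = sorted(pair_counts[cls].items(), key=lambda kv: (-kv[1], kv[0]))
        for (a, b), count in ranked[:k]:
            edges.append((a, b, cls, count))
            nodes.update((a, b))
    return PairNetwork(nodes=nodes, edges=edges, k=k)


def most_connected(net: PairNetwork, top_n: int = 5) -> list[tuple[str, int]]:
    """Nodes by degree — the number of distinct neighbours across all
    classes — descending, ties lexicographic."""
    if not net.nodes:
        raise MiningError("network is empty")
    neighbours: dict[str, set[str]] = {n: set() for n in net.nodes}
    for a, b, _, _ in net.edges:
        neighbours[a].add(b)
        neighbours[b].add(a)
    ranked = sorted(((n, len(s)) for n, s in neighbours.items()),
                    key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]
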