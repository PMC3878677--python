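"""Stochastic iterative learner of ordered threshold-rule sets.

Learns classifiers in the style of evolutionary learning classifier
systems: a sequential-covering loop repeatedly evolves one conjunctive
threshold rule with a seeded genetic search, appends it to an ordered
rule set, and removes the training samples it covers. A sample is
classified by the first rule it matches; samples matching no rule fall to
an explicit default class (the untreated control group when present), for
which no rules are ever emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .quantify import SampleQuantMatrix

GREATER_THAN = ">"
LESS_THAN = "<"
_OPS = (GREATER_THAN, LESS_THAN)


class RuleError(ValueError):
    """Raised for invalid rules, rule sets, or learner configurations."""


class RuleParseError(RuleError):
    """Raised when rule-set text cannot be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


# ---------------------------------------------------------------------------
# rule model


@dataclass(frozen=True)
class Condition:
    """One threshold test on a feature, with strict inequality."""

    feature: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise RuleError(f"operator must be '>' or '<', got {self.op!r}")
        if not np.isfinite(self.threshold):
            raise RuleError(f"threshold must be finite, got {self.threshold}")

    def holds(self, value: float) -> bool:
        if self.op == GREATER_THAN:
            return value > self.threshold
        return value < self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {_format_threshold(self.threshold)}"


@dataclass(frozen=True)
class Rule:
    """A conjunction of conditions predicting one non-default class."""

    conditions: tuple[Condition, ...]
    predicted_class: str

    def __post_init__(self) -> None:
        if not self.conditions:
            raise RuleError("a rule needs at least one condition")
        object.__setattr__(self, "conditions", tuple(self.conditions))
        keys = [(c.feature, c.op) for c in self.conditions]
        if len(set(keys)) != len(keys):
            raise RuleError(f"duplicate (feature, op) conditions in rule: {keys}")

    @property
    def features(self) -> list[str]:
        """Distinct features used, each counted once however often it appears."""
        return sorted({c.feature for c in self.conditions})

    def __str__(self) -> str:
        conj = " AND ".join(str(c) for c in self.conditions)
        return f"IF {conj} THEN {self.predicted_class}"


@dataclass(frozen=True)
class RuleSet:
    """An ordered rule list with an explicit default class.

    Order is significant: prediction takes the class of the first matching
    rule. No rule may predict the default class.
    """

    rules: tuple[Rule, ...]
    default_class: str
    training_seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        for rule in self.rules:
            if rule.predicted_class == self.default_class:
                raise RuleError(
                    f"rule predicts the default class {self.default_class!r}: {rule}"
                )

    @property
    def classes_used(self) -> set[str]:
        return {r.predicted_class for r in self.rules}

    def __len__(self) -> int:
        return len(self.rules)


def matches(rule: Rule, sample: Mapping[str, float]) -> bool:
    """True iff every condition of the rule holds for the sample.

    Features absent from the sample score 0 (an undetected protein).
    Inequalities are strict, so e.g. ``MMP-3 > 0`` fails at exactly 0.
    """
    return all(c.holds(sample.get(c.feature, 0.0)) for c in rule.conditions)


def predict(rs: RuleSet, sample: Mapping[str, float]) -> str:
    """Class of the first matching rule, or the default class if none match."""
    for rule in rs.rules:
        if matches(rule, sample):
            return rule.predicted_class
    return rs.default_class


# ---------------------------------------------------------------------------
# serialization

_DEFAULT_PREFIX = "DEFAULT"
_SEED_PREFIX = "# training_seed:"


def _format_threshold(t: float) -> str:
    # repr round-trips doubles exactly; trim the trailing ".0" of integers
    text = repr(float(t))
    return text[:-2] if text.endswith(".0") else text


def serialize_ruleset(rs: RuleSet) -> str:
    """Human-readable text form, one ``IF ... THEN <class>`` line per rule
    and a final ``DEFAULT <class>`` line."""
    lines = []
    if rs.training_seed is not None:
        lines.append(f"{_SEED_PREFIX} {rs.training_seed}")
    lines.extend(str(rule) for rule in rs.rules)
    lines.append(f"{_DEFAULT_PREFIX} {rs.default_class}")
    return "\n".join(lines) + "\n"


def parse_ruleset(text: str) -> RuleSet:
    """Inverse of :func:`serialize_ruleset`; raises :class:`RuleParseError`
    with the offending line number on malformed input."""
    rules: list[Rule] = []
    default_class: str | None = None
    training_seed: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(_SEED_PREFIX):
            try:
                training_seed = int(line[len(_SEED_PREFIX):].strip())
            except ValueError:
                raise RuleParseError(f"bad training seed in {line!r}", lineno)
            continue
        if line.startswith("#"):
            continue
        if line.startswith(_DEFAULT_PREFIX + " ") or line.startswith("default:"):
            if default_class is not None:
                raise RuleParseError("duplicate DEFAULT line", lineno)
            default_class = line.split(None, 1)[1].strip()
            continue
        rules.append(_parse_rule_line(line, lineno))
    if default_class is None:
        raise RuleParseError("missing DEFAULT line", len(text.splitlines()) or 1)
    try:
        return RuleSet(rules=tuple(rules), default_class=default_class,
                       training_seed=training_seed)
    except RuleError as exc:
        raise RuleParseError(str(exc), 1)


def _parse_rule_line(line: str, lineno: int) -> Rule:
    tokens = line.split()
    if not tokens or tokens[0] != "IF":
        raise RuleParseError(f"expected 'IF ...', got {line!r}", lineno)
    try:
        then_at = tokens.index("THEN")
    except ValueError:
        raise RuleParseError("missing THEN", lineno)
    predicted = " ".join(tokens[then_at + 1:])
    if not predicted:
        raise RuleParseError("missing class after THEN", lineno)
    body = tokens[1:then_at]
    conditions: list[Condition] = []
    i = 0
    while i < len(body):
        if i + 2 >= len(body):
            raise RuleParseError(f"incomplete condition near {' '.join(body[i:])!r}", lineno)
        feature, op, value = body[i], body[i + 1], body[i + 2]
        if op not in _OPS:
            raise RuleParseError(f"bad operator {op!r}", lineno)
        try:
            threshold = float(value)
        except ValueError:
            raise RuleParseError(f"bad threshold {value!r}", lineno)
        conditions.append(Condition(feature, op, threshold))
        i += 3
        if i < len(body):
            if body[i] != "AND":
                raise RuleParseError(f"expected AND, got {body[i]!r}", lineno)
            i += 1
    if not conditions:
        raise RuleParseError("rule has no conditions", lineno)
    try:
        return Rule(conditions=tuple(conditions), predicted_class=predicted)
    except RuleError as exc:
        raise RuleParseError(str(exc), lineno)


# ---------------------------------------------------------------------------
# learner


@dataclass(frozen=True)
class LearnerConfig:
    """Settings of the seeded genetic rule search.

    ``coverage_breakpoint`` is the fraction of the remaining training
    samples a rule should cover before its fitness stops being penalised;
    ``min_rule_accuracy`` is the admission bar for appending the best rule
    found in an iteration.
    """

    seed: int = 0
    generations: int = 30
    population_size: int = 50
    max_conditions: int = 3
    coverage_breakpoint: float = 0.25
    min_rule_accuracy: float = 0.7
    max_rules: int = 10

    def __post_init__(self) -> None:
        for name in ("generations", "population_size", "max_conditions", "max_rules"):
            if getattr(self, name) < 1:
                raise RuleError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0.0 < self.coverage_breakpoint <= 1.0):
            raise RuleError(
                f"coverage_breakpoint must be in (0, 1], got {self.coverage_breakpoint}"
            )
        if not (0.0 <= self.min_rule_accuracy <= 1.0):
            raise RuleError(
                f"min_rule_accuracy must be in [0, 1], got {self.min_rule_accuracy}"
            )


# A candidate in the genetic search: canonically-sorted condition tuples so
# that equal rule bodies compare equal and tie-breaks are reproducible.
_Genome = tuple[tuple[int, str, float], ...]


def _candidate_thresholds(X: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Midpoints between consecutive distinct observed values per feature,
    plus each midpoint's gap width as a fraction of the feature's range.

    Thresholds therefore always separate observed scores rather than
    sitting on them, so learned rules generalise past exact training
    values; the gap fractions feed the margin term of the fitness.
    Features with a single distinct value get no thresholds and are
    unusable.
    """
    thresholds, gaps = [], []
    for row in X:
        vals = np.unique(row)
        if len(vals) > 1:
            thresholds.append((vals[:-1] + vals[1:]) / 2.0)
            # gap width as a saturating log-fold-change: a threshold inside
            # a 10x abundance jump scores near 1, one squeezed between
            # near-identical noise values scores near 0. The offset keeps
            # zeros (undetected proteins) finite.
            eps = 0.5 * float(np.median(vals[vals > 0])) if (vals > 0).any() else 1.0
            log_gap = np.log((vals[1:] + eps) / (vals[:-1] + eps))
            gaps.append(log_gap / (log_gap + np.log(2.0)))
        else:
            thresholds.append(np.empty(0))
            gaps.append(np.empty(0))
    return thresholds, gaps


class _RuleSearch:
    """One genetic search for the best single rule on the remaining samples."""

    def __init__(self, X: np.ndarray, y: np.ndarray, default_code: int,
                 n_classes: int, thresholds: list[np.ndarray],
                 gaps: list[np.ndarray], config: LearnerConfig,
                 rng: np.random.Generator):
        self.X = X
        self.y = y
        self.default_code = default_code
        self.n_classes = n_classes
        self.thresholds = thresholds
        self.gaps = gaps
        self.usable = [i for i, t in enumerate(thresholds) if len(t) > 0]
        self.config = config
        self.rng = rng
        self._mask_cache: dict[tuple[int, str, float], np.ndarray] = {}
        self._need = config.coverage_breakpoint * X.shape[1]
        # admissibility floor: covering a fixed fraction of the breakpoint
        # keeps rules that chase one or two leftover samples out of the set
        self._min_cov = max(1, int(np.ceil(0.5 * self._need)))

    def _margin(self, genome: _Genome) -> float:
        """Smallest normalised value gap any condition's threshold sits in.

        Thresholds centred in wide gaps between observed scores separate
        classes robustly; thresholds squeezed between near-identical noise
        values are symptoms of overfitting, so the fitness discounts them.
        """
        worst = 1.0
        for fi, _, t in genome:
            ts = self.thresholds[fi]
            idx = min(int(np.searchsorted(ts, t)), len(ts) - 1)
            worst = min(worst, float(self.gaps[fi][idx]))
        return worst

    def _condition_mask(self, cond: tuple[int, str, float]) -> np.ndarray:
        """Full-sample boolean mask for one condition, memoised because the
        search revisits the same conditions many times."""
        cached = self._mask_cache.get(cond)
        if cached is None:
            fi, op, t = cond
            col = self.X[fi]
            cached = (col > t) if op == GREATER_THAN else (col < t)
            self._mask_cache[cond] = cached
        return cached

    def evaluate(self, genome: _Genome, remaining: np.ndarray):
        """Fitness = accuracy x coverage penalty; also returns the majority
        non-default class among covered samples and the cover mask."""
        mask = self._condition_mask(genome[0])[remaining]
        for cond in genome[1:]:
            mask = mask & self._condition_mask(cond)[remaining]
        cov = int(mask.sum())
        if cov == 0:
            return 0.0, -1, 0.0, mask
        counts = np.bincount(self.y[remaining[mask]], minlength=self.n_classes)
        counts[self.default_code] = 0
        cls = int(np.argmax(counts))
        if counts[cls] == 0:
            return 0.0, -1, 0.0, mask
        acc = counts[cls] / cov
        # coverage measured against the full training set, not the shrinking
        # remainder: late rules covering a couple of samples stay penalised
        fitness = acc * min(1.0, cov / self._need) if self._need > 0 else acc
        # margin and parsimony pressure: narrow-gap thresholds and stacked
        # conditions fit noise, so both are discounted
        fitness *= self._margin(genome) * 0.5 ** (len(genome) - 1)
        return fitness, cls, acc, mask

    # -- genome construction ---------------------------------------------

    def _random_condition(self, sample_idx: int | None) -> tuple[int, str, float] | None:
        if not self.usable:
            return None
        rng = self.rng
        fi = self.usable[int(rng.integers(len(self.usable)))]
        ts = self.thresholds[fi]
        op = GREATER_THAN if rng.random() < 0.5 else LESS_THAN
        if sample_idx is not None:
            # bias the condition to cover a chosen seed sample
            v = self.X[fi, sample_idx]
            split = int(np.searchsorted(ts, v))
            lo, hi = (0, split) if op == GREATER_THAN else (split, len(ts))
            if lo == hi:
                op = LESS_THAN if op == GREATER_THAN else GREATER_THAN
                lo, hi = (split, len(ts)) if op == LESS_THAN else (0, split)
            if lo == hi:
                return None
            return fi, op, float(ts[lo + int(rng.integers(hi - lo))])
        return fi, op, float(ts[int(rng.integers(len(ts)))])

    def _single_condition_table(self, remaining: np.ndarray,
                                class_onehot: np.ndarray) -> list[tuple]:
        """Best single threshold condition per (feature, direction) on the
        remaining samples, sorted by fitness descending.

        This is the covering operator: the population is seeded from the
        top of this table, so informative features surface immediately even
        in wide matrices, while the genetic search explores refinements and
        conjunctions around them.
        """
        entries: list[tuple] = []
        Xr = self.X[:, remaining]
        for fi in self.usable:
            ts, gp = self.thresholds[fi], self.gaps[fi]
            vals = Xr[fi]
            for op in (GREATER_THAN, LESS_THAN):
                if op == GREATER_THAN:
                    mask = vals[None, :] > ts[:, None]
                else:
                    mask = vals[None, :] < ts[:, None]
                cov = mask.sum(axis=1)
                counts = mask.astype(np.float64) @ class_onehot
                best_cnt = counts.max(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    acc = np.where(cov > 0, best_cnt / np.maximum(cov, 1), 0.0)
                    fit = acc * np.minimum(1.0, cov / self._need) * gp
                fit = np.where(best_cnt > 0, fit, 0.0)
                # prefer wider coverage among near-equal candidates
                fit = fit + 1e-6 * np.where(fit > 0, cov, 0)
                j = int(np.argmax(fit))
                if fit[j] > 0:
                    entries.append((float(fit[j]), fi, op, float(ts[j])))
        entries.sort(key=lambda e: (-e[0], e[1], e[2]))
        return entries

    def _seed_genome(self, table: list[tuple], rank: int,
                     top_m: int = 10) -> _Genome:
        """Covering-style initialization from the single-condition table:
        the first individual takes the table optimum, the rest draw from
        the ``top_m`` best candidates, keeping run-to-run variety."""
        if not table:
            c = self._random_condition(None)
            return () if c is None else (c,)
        if rank == 0:
            pick = 0
        else:
            pick = int(self.rng.integers(min(top_m, len(table))))
        _, fi, op, threshold = table[pick]
        conds = {(fi, op): (fi, op, threshold)}
        if self.rng.random() < 0.3:
            c = self._random_condition(None)
            if c is not None:
                conds.setdefault((c[0], c[1]), c)
        return tuple(sorted(conds.values()))

    def _mutate(self, genome: _Genome, remaining: np.ndarray) -> _Genome:
        conds = {(fi, op): (fi, op, t) for fi, op, t in genome}
        r = self.rng.random()
        if r < 0.3 and len(conds) < self.config.max_conditions:
            c = self._random_condition(None)
            if c is not None:
                conds[(c[0], c[1])] = c
        elif r < 0.5 and len(conds) > 1:
            key = tuple(sorted(conds))[int(self.rng.integers(len(conds)))]
            del conds[key]
        elif conds:
            # perturb one threshold: usually an adjacent candidate value,
            # sometimes a fresh uniform draw to escape local plateaus
            key = tuple(sorted(conds))[int(self.rng.integers(len(conds)))]
            fi, op, t = conds[key]
            ts = self.thresholds[fi]
            if self.rng.random() < 0.5:
                pos = int(np.searchsorted(ts, t))
                step = 1 if self.rng.random() < 0.5 else -1
                pos = min(max(pos + step, 0), len(ts) - 1)
            else:
                pos = int(self.rng.integers(len(ts)))
            conds[key] = (fi, op, float(ts[pos]))
        return tuple(sorted(conds.values()))

    def _crossover(self, a: _Genome, b: _Genome) -> _Genome:
        merged: dict[tuple[int, str], tuple[int, str, float]] = {}
        for key in sorted({(fi, op) for fi, op, _ in a} | {(fi, op) for fi, op, _ in b}):
            ca = next((c for c in a if (c[0], c[1]) == key), None)
            cb = next((c for c in b if (c[0], c[1]) == key), None)
            pick = ca if cb is None else cb if ca is None else (
                ca if self.rng.random() < 0.5 else cb)
            if self.rng.random() < 0.7:
                merged[key] = pick
        if not merged:
            source = a if self.rng.random() < 0.5 else b
            if source:
                c = source[int(self.rng.integers(len(source)))]
                merged[(c[0], c[1])] = c
        while len(merged) > self.config.max_conditions:
            key = tuple(sorted(merged))[int(self.rng.integers(len(merged)))]
            del merged[key]
        return tuple(sorted(merged.values()))

    # -- evolution --------------------------------------------------------

    def run(self, remaining: np.ndarray):
        """Evolve for ``generations``; returns (genome, class code, accuracy,
        cover mask) of the best rule, or None when no rule covers anything."""
        cfg = self.config
        onehot = np.zeros((len(remaining), self.n_classes))
        onehot[np.arange(len(remaining)), self.y[remaining]] = 1.0
        onehot[:, self.default_code] = 0.0
        table = self._single_condition_table(remaining, onehot)
        population = [self._seed_genome(table, rank)
                      for rank in range(cfg.population_size)]
        population = [g for g in population if g]
        if not population:
            return None
        # best admissible rule: accurate enough and covering enough samples;
        # inadmissible genomes still compete in selection so the search can
        # move through them toward admissible ones
        best = None  # (fitness, coverage, -len, genome, cls, acc, mask)

        def consider(genome: _Genome):
            nonlocal best
            fitness, cls, acc, mask = self.evaluate(genome, remaining)
            if cls < 0:
                return fitness
            cov = int(mask.sum())
            if acc >= self.config.min_rule_accuracy and cov >= self._min_cov:
                entry = (fitness, cov, -len(genome), genome, cls, acc, mask)
                if (best is None or entry[:3] > best[:3]
                        or (entry[:3] == best[:3] and genome < best[3])):
                    best = entry
            # selection pressure: equal-fitness rules with wider coverage win
            return fitness + 1e-6 * cov

        fits = [consider(g) for g in population]
        for _ in range(cfg.generations):
            order = np.argsort(fits)[::-1]
            elite = population[int(order[0])]
            new_pop = [elite]
            while len(new_pop) < cfg.population_size:
                i, j = self.rng.integers(len(population), size=2)
                p1 = population[i] if fits[i] >= fits[j] else population[j]
                i, j = self.rng.integers(len(population), size=2)
                p2 = population[i] if fits[i] >= fits[j] else population[j]
                child = self._crossover(p1, p2) if self.rng.random() < 0.6 else p1
                if self.rng.random() < 0.6:
                    child = self._mutate(child, remaining)
                if child:
                    new_pop.append(child)
            population = new_pop
            fits = [consider(g) for g in population]
        return None if best is None else best[3:]


def learn_ruleset(train: SampleQuantMatrix, config: LearnerConfig) -> RuleSet:
    """Learn an ordered threshold-rule set from a labelled score matrix.

    Sequential covering: evolve the best single rule on the samples not yet
    covered, append it, drop the samples it covers, and repeat until the
    remainder is all default-class, ``max_rules`` is reached, or the best
    candidate's accuracy falls below ``min_rule_accuracy``. The same seed
    on the same data reproduces the rule set exactly.
    """
    classes = train.classes
    if len(classes) < 2:
        raise RuleError(f"need >= 2 classes to learn rules, got {classes}")
    if train.n_features == 0 or train.n_samples == 0:
        raise RuleError("empty training matrix")

    default_class = _default_class(train)
    class_to_code = {c: i for i, c in enumerate(classes)}
    default_code = class_to_code[default_class]
    y = train.labels.map(class_to_code).to_numpy()
    if (y == default_code).all():
        raise RuleError("no non-default-class training samples")
    X = train.scores.to_numpy()
    features = train.features
    thresholds, gaps = _candidate_thresholds(X)

    rng = np.random.default_rng(config.seed)
    search = _RuleSearch(X, y, default_code, len(classes), thresholds, gaps, config, rng)

    remaining = np.arange(train.n_samples)
    rules: list[Rule] = []
    while len(rules) < config.max_rules:
        if (y[remaining] == default_code).all():
            break
        found = search.run(remaining)
        if found is None:
            break
        genome, cls, acc, mask = found
        rules.append(Rule(
            conditions=tuple(Condition(features[fi], op, t) for fi, op, t in genome),
            predicted_class=classes[cls],
        ))
        remaining = remaining[~mask]
        if len(remaining) == 0:
            break
    return RuleSet(rules=tuple(rules), default_class=default_class,
                   training_seed=config.seed)


def _default_class(train: SampleQuantMatrix) -> str:
    """The control group when present, else the majority class."""
    if "control" in train.classes or any(c.lower() == "control" for c in train.classes):
        for c in train.classes:
            if c.lower() == "control":
                return c
    sizes = train.class_sizes()
    return max(train.classes, key=lambda c: (sizes[c], -train.classes.index(c)))
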