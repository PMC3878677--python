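import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from proteorules import (
    GeneratorConfig,
    LearnerConfig,
    MarkerSpec,
    SampleQuantMatrix,
    generate_design,
)
from proteorules.rule_learner import Condition, Rule, RuleSet

# The example rule set printed in the analysis write-up: five threshold
# rules over three treated classes with the untreated control as default.
PRINTED_RULESET_TEXT = """\
IF TPIS > 0.01 THEN IL-1β
IF IL-8 > 0.02 THEN IL-1β+carprofen
IF MMP-3 > 0 AND UBIB < 0.2 THEN IL-1β
IF MGP > 0 AND A1AT < 0.9 THEN carprofen
IF ALBU > 0.01 THEN IL-1β+carprofen
DEFAULT control
"""


@pytest.fixture
def printed_ruleset_text() -> str:
    return PRINTED_RULESET_TEXT


@pytest.fixture
def paper_design():
    return generate_design(paper_defaults=True)


@pytest.fixture
def tiny_matrix() -> SampleQuantMatrix:
    """A hand-built 3-protein x 4-sample matrix over two classes."""
    scores = pd.DataFrame(
        {
            "s1": [0.5, 0.0, 0.1],
            "s2": [0.6, 0.0, 0.2],
            "s3": [0.0, 0.3, 0.1],
            "s4": [0.0, 0.4, 0.2],
        },
        index=["A|empai", "B|empai", "C|empai"],
    )
    labels = pd.Series(
        {"s1": "treated", "s2": "treated", "s3": "control", "s4": "control"})
    return SampleQuantMatrix(scores=scores, labels=labels, provenance="fixture")


def separable_matrix(n_per_class: int = 4, seed: int = 0) -> SampleQuantMatrix:
    """Perfectly threshold-separable toy: protein A is positive exactly in
    class X, protein B exactly in class Y; control is all background."""
    rng = np.random.default_rng(seed)
    classes = (["control"] * n_per_class + ["X"] * n_per_class
               + ["Y"] * n_per_class)
    n = len(classes)
    a = np.where(np.array(classes) == "X", rng.uniform(0.5, 1.0, n), 0.0)
    b = np.where(np.array(classes) == "Y", rng.uniform(0.5, 1.0, n), 0.0)
    noise = rng.uniform(0.0, 0.2, (3, n))
    samples = [f"s{i:02d}" for i in range(n)]
    scores = pd.DataFrame(
        np.vstack([a, b, noise]),
        index=["A|empai", "B|empai", "N1|empai", "N2|empai", "N3|empai"],
        columns=samples,
    )
    labels = pd.Series(classes, index=samples)
    return SampleQuantMatrix(scores=scores, labels=labels, provenance="separable toy")


@pytest.fixture
def separable() -> SampleQuantMatrix:
    return separable_matrix()


def random_rulesets(n: int, seed: int, classes=("IL-1β", "carprofen", "IL-1β+carprofen"),
                    features=None, default_class: str = "control") -> list[RuleSet]:
    """Random rule-set fixtures for mining tests (not learner output)."""
    rng = np.random.default_rng(seed)
    if features is None:
        features = [f"P{i:02d}" for i in range(12)]
    out = []
    for _ in range(n):
        rules = []
        for _ in range(int(rng.integers(0, 5))):
            k = int(rng.integers(1, 4))
            feats = rng.choice(features, size=k, replace=False)
            conds = []
            for f in feats:
                op = ">" if rng.random() < 0.7 else "<"
                conds.append(Condition(str(f), op, round(float(rng.uniform(0, 1)), 3)))
            rules.append(Rule(tuple(conds),
                              str(rng.choice(list(classes)))))
        out.append(RuleSet(tuple(rules), default_class=default_class))
    return out


@pytest.fixture
def quick_learner() -> LearnerConfig:
    return LearnerConfig(seed=0, generations=6, population_size=20)


def null_generator_config(seed: int, n_proteins: int = 30) -> GeneratorConfig:
    """No planted markers: labels carry no information about scores."""
    return GeneratorConfig(seed=seed, n_background_proteins=n_proteins,
                           markers=(), dropout_prob=0.1, noise_cv=0.3)
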