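"""Leave-one-out cross-validation and permutation significance testing.

With only ~23 samples across four treatment classes, the study evaluates
classifiers by LOOCV (one model per held-out sample) and assesses the
significance of the observed accuracy against accuracies obtained on
datasets whose class labels were randomly reassigned while keeping the
class sizes fixed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import SampleQuantMatrix
from .rule_learner import LearnerConfig, RuleSet, learn_ruleset, predict

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# results


@dataclass
class ConfusionMatrix:
    """True-class by predicted-class counts."""

    classes: list[str]
    counts: np.ndarray  # rows = true, columns = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise EvaluationError(
                f"counts must be {k}x{k}, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise EvaluationError("confusion counts must be nonnegative")

    @classmethod
    def from_predictions(cls, true: list[str], predicted: list[str],
                         classes: list[str]) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true, predicted, strict=True):
            counts[index[t], index[p]] += 1
        return cls(classes=list(classes), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.total

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class LoocvResult:
    confusion: ConfusionMatrix
    accuracy: float
    predictions: pd.DataFrame  # sample_id, true_class, predicted_class, split_seed
    rulesets: list[RuleSet] | None = None


@dataclass
class PermutationResult:
    observed_accuracy: float
    permuted_accuracies: list[float]
    p_empirical: float
    p_gaussian: float
    n_permutations: int


def accuracy_percent(n_correct: int, n_total: int) -> float:
    """Accuracy as a percentage rounded to one decimal place, the way the
    study reports it (18/23 -> 78.3)."""
    if n_total < 1:
        raise EvaluationError("n_total must be >= 1")
    return round(100.0 * n_correct / n_total, 1)


# ---------------------------------------------------------------------------
# LOOCV


def loocv_splits(m: SampleQuantMatrix) -> list[tuple[list[str], str]]:
    """One (train ids, test id) split per sample: each sample is held out
    exactly once with all others as the training set."""
    samples = m.samples
    if len(samples) < 2:
        raise EvaluationError(f"LOOCV needs >= 2 samples, got {len(samples)}")
    return [([s for s in samples if s != test], test) for test in samples]


def split_seed(base_seed: int, index: int) -> int:
    """Deterministic per-split (or per-permutation/run) seed derived by
    hashing the base seed with the index, decoupling the streams."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2 ** 31))


def run_loocv(m: SampleQuantMatrix, config: LearnerConfig,
              keep_rulesets: bool = False) -> LoocvResult:
    """Learn one rule set per LOOCV split and score the held-out samples.

    Each split trains with its own derived seed, so the whole evaluation is
    reproducible from ``config.seed`` alone.
    """
    splits = loocv_splits(m)
    classes = m.classes
    if len(classes) < 2:
        raise EvaluationError(f"need >= 2 classes, got {classes}")
    rows = []
    rulesets = [] if keep_rulesets else None
    for i, (train_ids, test_id) in enumerate(splits):
        seed_i = split_seed(config.seed, i)
        try:
            rs = learn_ruleset(m.subset_samples(train_ids),
                               dataclasses.replace(config, seed=seed_i))
        except Exception as exc:
            raise EvaluationError(
                f"learner failed on split {i} (test sample {test_id!r}): {exc}"
            ) from exc
        pred = predict(rs, m.sample_scores(test_id))
        rows.append({"sample_id": test_id, "true_class": m.labels[test_id],
                     "predicted_class": pred, "split_seed": seed_i})
        if keep_rulesets:
            rulesets.append(rs)
    predictions = pd.DataFrame(rows)
    confusion = ConfusionMatrix.from_predictions(
        predictions["true_class"].tolist(),
        predictions["predicted_class"].tolist(), classes)
    return LoocvResult(confusion=confusion, accuracy=confusion.accuracy,
                       predictions=predictions, rulesets=rulesets)


# ---------------------------------------------------------------------------
# permutation testing


def permute_labels(m: SampleQuantMatrix, seed: int) -> SampleQuantMatrix:
    """Randomly reassign class labels among samples, preserving the class
    sizes exactly; the score matrix is untouched."""
    rng = np.random.default_rng(seed)
    values = m.labels.to_numpy()
    permuted = values[rng.permutation(len(values))]
    labels = pd.Series(permuted, index=m.labels.index, name="class")
    return m.with_labels(labels, provenance=f"{m.provenance} [labels permuted]")


def empirical_p(observed: float, permuted: list[float]) -> float:
    """One-tailed empirical p-value ``(r + 1) / (n + 1)`` with ``r`` the
    number of permuted accuracies at or above the observed one; never 0."""
    r = sum(1 for a in permuted if a >= observed)
    return (r + 1) / (len(permuted) + 1)


def gaussian_tail_p(observed: float, permuted: list[float]) -> float:
    """Upper-tail normal probability of the observed accuracy under a
    Gaussian fitted to the permuted accuracies. Reported alongside the
    empirical p because a 50-permutation null cannot resolve probabilities
    below 1/51."""
    mean = float(np.mean(permuted))
    sd = float(np.std(permuted, ddof=1)) if len(permuted) > 1 else 0.0
    if sd == 0.0:
        warnings.warn("permuted accuracies have zero variance; "
                      "Gaussian tail p degenerates to 0 or 1", stacklevel=2)
        return 0.0 if observed > mean else 1.0
    return float(stats.norm.sf((observed - mean) / sd))


def permutation_test(m: SampleQuantMatrix, config: LearnerConfig,
                     n_permutations: int = 50, seed: int = 0) -> PermutationResult:
    """LOOCV accuracy on the true labels versus on label-permuted datasets.

    Each permutation preserves the class-size multiset and re-runs the full
    LOOCV evaluation.
    """
    if n_permutations < 1:
        raise EvaluationError(f"n_permutations must be >= 1, got {n_permutations}")
    observed = run_loocv(m, config).accuracy
    logger.info("permutation test: observed accuracy %.3f, %d permutations",
                observed, n_permutations)
    permuted = []
    for i in range(n_permutations):
        pm = permute_labels(m, seed=split_seed(seed, i))
        permuted.append(run_loocv(pm, config).accuracy)
    return PermutationResult(
        observed_accuracy=observed,
        permuted_accuracies=permuted,
        p_empirical=empirical_p(observed, permuted),
        p_gaussian=gaussian_tail_p(observed, permuted),
        n_permutations=n_permutations,
    )
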