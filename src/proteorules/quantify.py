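"""Label-free protein quantification and score-matrix assembly.

Turns peptide-level identification tables into per-sample protein score
matrices using the exponentially modified protein abundance index (emPAI)
or a peptide-evidence probability score, combines score blocks into a
single feature matrix, and filters samples with anomalously few
identified proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SCORE_TYPES = ("empai", "probability")


class QuantifyError(ValueError):
    """Raised for invalid quantification inputs."""


# ---------------------------------------------------------------------------
# scores


def compute_pai(observed_peptides: int, observable_peptides: int,
                protein_id: str | None = None) -> float:
    """Protein abundance index: observed peptides / theoretically observable
    tryptic peptides.

    Parameters
    ----------
    observed_peptides
        Number of peptides identified for the protein in one sample.
    observable_peptides
        Number of theoretically observable tryptic peptides (>= 1).
    protein_id
        Optional accession used in error messages.
    """
    if observed_peptides < 0:
        raise QuantifyError(f"observed_peptides must be >= 0, got {observed_peptides}")
    if observable_peptides < 1:
        who = f" for protein {protein_id!r}" if protein_id else ""
        raise QuantifyError(
            f"observable_peptides must be >= 1{who}, got {observable_peptides}"
        )
    return observed_peptides / observable_peptides


def compute_empai(pai: float) -> float:
    """Exponentially modified PAI: ``10**PAI - 1``.

    Zero when no peptides were observed and strictly increasing in PAI, so
    it can be used directly as a quasi-absolute abundance estimate.
    """
    if pai < 0:
        raise QuantifyError(f"pai must be >= 0, got {pai}")
    return 10.0 ** pai - 1.0


def protein_probability_standin(peptide_probs: Sequence[float]) -> float:
    """Probability that a protein identification is correct, combined from
    independent peptide-level probabilities as ``1 - prod(1 - p_i)``.

    A simplified closed-form protein-probability score: a single certain
    peptide makes the protein certain, and adding evidence never lowers
    the score.
    """
    probs = list(peptide_probs)
    if not probs:
        raise QuantifyError("peptide_probs must be nonempty")
    for p in probs:
        if not (0.0 <= p <= 1.0):
            raise QuantifyError(f"peptide probability out of [0, 1]: {p}")
    prod = 1.0
    for p in probs:
        prod *= 1.0 - p
    return 1.0 - prod


# ---------------------------------------------------------------------------
# matrix container


@dataclass
class SampleQuantMatrix:
    """Proteins-by-samples nonnegative score matrix with class labels.

    ``scores`` is indexed by feature id ``"<accession>|<score_type>"`` so a
    combined matrix can carry the same accession once per score block.
    ``labels`` maps sample id -> treatment class, aligned with the score
    columns.
    """

    scores: pd.DataFrame
    labels: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        if (self.scores.to_numpy() < 0).any():
            raise QuantifyError("scores must be nonnegative")
        if not self.scores.index.is_unique:
            dup = self.scores.index[self.scores.index.duplicated()].tolist()
            raise QuantifyError(f"duplicate feature ids: {dup}")
        missing = [s for s in self.scores.columns if s not in self.labels.index]
        if missing:
            raise QuantifyError(f"samples without a class label: {missing}")
        self.labels = self.labels.reindex(self.scores.columns)
        for feat in self.scores.index:
            st = feature_score_type(feat)
            if st not in SCORE_TYPES:
                raise QuantifyError(f"unknown score type {st!r} in feature {feat!r}")
        prob_feats = [f for f in self.scores.index
                      if feature_score_type(f) == "probability"]
        if prob_feats and (self.scores.loc[prob_feats].to_numpy() > 1.0).any():
            raise QuantifyError("probability-type scores must be <= 1")

    # -- views ------------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.scores.index)

    @property
    def proteins(self) -> list[str]:
        return [feature_accession(f) for f in self.scores.index]

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_samples(self) -> int:
        return self.scores.shape[1]

    @property
    def n_features(self) -> int:
        return self.scores.shape[0]

    @property
    def classes(self) -> list[str]:
        """Class names in order of first appearance along the sample axis."""
        return list(dict.fromkeys(self.labels.tolist()))

    def class_sizes(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in self.classes}

    def sample_scores(self, sample_id: str) -> dict[str, float]:
        """Feature -> score mapping for one sample (zeros included)."""
        return self.scores[sample_id].to_dict()

    def subset_samples(self, sample_ids: Sequence[str]) -> "SampleQuantMatrix":
        keep = list(sample_ids)
        return SampleQuantMatrix(
            scores=self.scores[keep].copy(),
            labels=self.labels.loc[keep].copy(),
            provenance=self.provenance,
        )

    def with_labels(self, labels: pd.Series, provenance: str | None = None) -> "SampleQuantMatrix":
        return SampleQuantMatrix(
            scores=self.scores.copy(),
            labels=labels.reindex(self.scores.columns),
            provenance=self.provenance if provenance is None else provenance,
        )


def feature_id(accession: str, score_type: str) -> str:
    return f"{accession}|{score_type}"


def feature_accession(feature: str) -> str:
    return feature.rsplit("|", 1)[0]


def feature_score_type(feature: str) -> str:
    if "|" not in feature:
        raise QuantifyError(f"feature id {feature!r} lacks a score-type tag")
    return feature.rsplit("|", 1)[1]


# ---------------------------------------------------------------------------
# assembly


def assemble_matrix(records: pd.DataFrame, labels: Mapping[str, str],
                    score_type: str = "empai",
                    provenance: str = "") -> SampleQuantMatrix:
    """Assemble a wide score matrix from a long peptide or score table.

    ``records`` is either a peptide table (columns ``protein_id, sample_id,
    observed_peptides, observable_peptides``), from which emPAI scores are
    computed, or a pre-scored table (columns ``protein_id, sample_id,
    score``). Proteins are the union over samples; a protein not reported
    in a sample scores 0 there (an explicitly absent protein, not a missing
    value). Protein and sample orderings are lexicographic.
    """
    if score_type not in SCORE_TYPES:
        raise QuantifyError(f"score_type must be one of {SCORE_TYPES}, got {score_type!r}")
    if len(records) == 0:
        raise QuantifyError("records table is empty: no proteins to assemble")

    records = records.copy()
    dup = records.duplicated(subset=["protein_id", "sample_id"])
    if dup.any():
        pairs = records.loc[dup, ["protein_id", "sample_id"]].itertuples(index=False)
        raise QuantifyError(
            "duplicate (protein, sample) rows: " + ", ".join(map(str, map(tuple, pairs)))
        )

    sample_ids = sorted(records["sample_id"].unique())
    unlabeled = [s for s in sample_ids if s not in labels]
    if unlabeled:
        raise QuantifyError(f"samples without a class label: {unlabeled}")

    if "score" in records.columns:
        records["_value"] = records["score"].astype(float)
    else:
        obs = records["observed_peptides"].to_numpy()
        obl = records["observable_peptides"].to_numpy()
        bad = obl < 1
        if bad.any():
            offender = records.loc[bad, "protein_id"].iloc[0]
            raise QuantifyError(
                f"observable_peptides must be >= 1 for protein {offender!r}"
            )
        if score_type != "empai":
            raise QuantifyError(
                "peptide tables can only be assembled into empai scores"
            )
        records["_value"] = 10.0 ** (obs / obl) - 1.0

    wide = records.pivot(index="protein_id", columns="sample_id", values="_value")
    wide = wide.reindex(sorted(wide.index), axis=0)
    wide = wide.reindex(sample_ids, axis=1)
    wide = wide.fillna(0.0)
    wide.index = [feature_id(acc, score_type) for acc in wide.index]
    lab = pd.Series({s: labels[s] for s in sample_ids}, name="class")
    return SampleQuantMatrix(scores=wide, labels=lab, provenance=provenance)


def combine_matrices(a: SampleQuantMatrix, b: SampleQuantMatrix) -> SampleQuantMatrix:
    """Stack two score blocks over the same samples into one feature matrix.

    Features stay tagged with their score type, so the same accession may
    appear once per block; the sample set and labels must agree exactly.
    """
    if set(a.samples) != set(b.samples):
        only_a = sorted(set(a.samples) - set(b.samples))
        only_b = sorted(set(b.samples) - set(a.samples))
        raise QuantifyError(
            f"sample sets differ: only in first {only_a}, only in second {only_b}"
        )
    mismatched = [s for s in a.samples if a.labels[s] != b.labels[s]]
    if mismatched:
        raise QuantifyError(f"class labels disagree for samples: {mismatched}")
    overlap = set(a.features) & set(b.features)
    if overlap:
        raise QuantifyError(
            f"feature ids present in both matrices: {sorted(overlap)}"
        )
    scores = pd.concat([a.scores, b.scores[a.samples]], axis=0)
    prov = " + ".join(p for p in (a.provenance, b.provenance) if p) or "combined"
    return SampleQuantMatrix(scores=scores, labels=a.labels.copy(), provenance=prov)


def filter_anomalous_samples(
    m: SampleQuantMatrix, min_fraction_of_median: float = 0.25,
) -> tuple[SampleQuantMatrix, list[str]]:
    """Drop samples identifying anomalously few proteins.

    A sample is removed when its nonzero-protein count falls below
    ``min_fraction_of_median`` times the median nonzero-protein count over
    all samples — a reproducible form of the by-inspection removal of a
    sample with very few identified proteins.
    """
    if not (0.0 < min_fraction_of_median < 1.0):
        raise QuantifyError(
            f"min_fraction_of_median must be in (0, 1), got {min_fraction_of_median}"
        )
    if m.n_samples == 0:
        raise QuantifyError("matrix has no samples")
    counts = (m.scores.to_numpy() != 0.0).sum(axis=0)
    median = float(np.median(counts))
    threshold = min_fraction_of_median * median
    keep = [s for s, c in zip(m.samples, counts) if c >= threshold]
    removed = [s for s, c in zip(m.samples, counts) if c < threshold]
    if not keep:
        raise QuantifyError(
            f"all {m.n_samples} samples fall below {threshold:.1f} nonzero proteins; "
            "threshold too aggressive"
        )
    if not removed:
        return m, []
    return m.subset_samples(keep), removed
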