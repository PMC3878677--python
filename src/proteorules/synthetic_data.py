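"""Synthetic secretome datasets with the explant study's design.

Emulates a four-treatment cartilage-explant experiment (control, IL-1β,
carprofen, IL-1β+carprofen; six replicates per treatment across two
subjects) at two levels: a peptide-identification table feeding the emPAI
stage, and protein-level score matrices produced directly. Marker proteins
are planted with elevated abundance in chosen treatment classes on top of
a shared sparse background, and one sample can be made anomalously sparse
the way a failed identification run is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import SampleQuantMatrix, feature_id

CONTROL = "control"
IL1B = "IL-1β"
CARPROFEN = "carprofen"
IL1B_CARPROFEN = "IL-1β+carprofen"

PAPER_CLASSES = (CONTROL, IL1B, CARPROFEN, IL1B_CARPROFEN)

# Dispersion of the negative-binomial peptide-count draw; a moderate amount
# of extra-Poisson variation typical of spectral-count data.
_NB_DISPERSION = 5.0
# Scale of the saturating transform mapping latent abundance to a
# probability-type score: 1 - exp(-abundance / scale).
_PROB_SCALE = 0.3
# Between-subject multiplicative offset (log-sd); subjects are pooled in the
# analysis, so this is deliberately mild.
_SUBJECT_LOG_SD = 0.15


class GeneratorError(ValueError):
    """Raised for invalid study designs or generator configurations."""


# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class StudyDesign:
    """Treatment classes, replicate counts, and subject structure."""

    classes: tuple[str, ...]
    replicates_per_class: Mapping[str, int]
    subjects: int = 2
    default_class: str = CONTROL

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise GeneratorError("classification needs >= 2 classes")
        if len(set(self.classes)) != len(self.classes):
            raise GeneratorError("class names must be unique")
        if self.default_class not in self.classes:
            raise GeneratorError(
                f"default class {self.default_class!r} not among classes {self.classes}"
            )
        if self.subjects < 1:
            raise GeneratorError("subjects must be >= 1")
        for cls in self.classes:
            n = self.replicates_per_class.get(cls, 0)
            if n < 1:
                raise GeneratorError(f"class {cls!r} needs >= 1 replicate, got {n}")

    @property
    def n_samples(self) -> int:
        return sum(self.replicates_per_class[c] for c in self.classes)

    def sample_table(self) -> pd.DataFrame:
        """One row per sample: sample_id, class, subject.

        Replicates of each class are assigned to subjects round-robin, so
        six replicates over two subjects give three per subject.
        """
        rows = []
        for cls in self.classes:
            for r in range(self.replicates_per_class[cls]):
                subject = r % self.subjects + 1
                rows.append({
                    "sample_id": f"{cls}_s{subject}_r{r + 1}",
                    "class": cls,
                    "subject": subject,
                })
        return pd.DataFrame(rows)


def generate_design(
    paper_defaults: bool = True,
    *,
    classes: Sequence[str] | None = None,
    replicates_per_class: Mapping[str, int] | None = None,
    subjects: int = 2,
    default_class: str | None = None,
) -> StudyDesign:
    """Build a study design; with ``paper_defaults`` the explant layout of
    four treatments x six replicates over two subjects (24 samples), with
    the untreated control as the default class."""
    if paper_defaults:
        return StudyDesign(
            classes=PAPER_CLASSES,
            replicates_per_class={c: 6 for c in PAPER_CLASSES},
            subjects=2,
            default_class=CONTROL,
        )
    if classes is None or replicates_per_class is None:
        raise GeneratorError(
            "custom designs need explicit classes and replicates_per_class"
        )
    classes = tuple(classes)
    if default_class is None:
        default_class = classes[0]
    return StudyDesign(
        classes=classes,
        replicates_per_class=dict(replicates_per_class),
        subjects=subjects,
        default_class=default_class,
    )


# ---------------------------------------------------------------------------
# generator configuration


@dataclass(frozen=True)
class MarkerSpec:
    """A planted marker protein elevated in selected treatment classes.

    ``presence_prob_in`` overrides the per-class probability that the
    protein is detectable at all (default 1.0), which emulates proteins
    found across all treatment groups except one.
    """

    protein_id: str
    elevated_in: frozenset[str]
    baseline_score: float = 0.05
    effect_multiplier: float = 10.0
    presence_prob_in: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "elevated_in", frozenset(self.elevated_in))
        if self.effect_multiplier <= 1.0:
            raise GeneratorError(
                f"effect_multiplier must be > 1, got {self.effect_multiplier}"
            )
        if self.baseline_score < 0:
            raise GeneratorError(
                f"baseline_score must be >= 0, got {self.baseline_score}"
            )
        for cls, p in self.presence_prob_in.items():
            if not (0.0 <= p <= 1.0):
                raise GeneratorError(
                    f"presence probability for {cls!r} out of [0, 1]: {p}"
                )


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic secretome generator."""

    seed: int
    n_background_proteins: int = 150
    markers: tuple[MarkerSpec, ...] = ()
    dropout_prob: float = 0.1
    noise_cv: float = 0.3
    anomalous_sample: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if not (0.0 <= self.dropout_prob < 1.0):
            raise GeneratorError(
                f"dropout_prob must be in [0, 1), got {self.dropout_prob}"
            )
        if self.noise_cv < 0:
            raise GeneratorError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_background_proteins < 0:
            raise GeneratorError(
                f"n_background_proteins must be >= 0, got {self.n_background_proteins}"
            )
        if self.anomalous_sample is not None:
            cls, frac = self.anomalous_sample
            if not (0.0 < frac <= 0.25):
                raise GeneratorError(
                    f"anomalous retained fraction must be in (0, 0.25], got {frac}"
                )
        ids = [m.protein_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise GeneratorError(f"duplicate marker protein ids: {ids}")


def default_markers() -> tuple[MarkerSpec, ...]:
    """One marker per treated class, mirroring the proteins that dominate
    the study's per-class rankings: MMP-3 for IL-1β, MGP for carprofen,
    IL-8 for the combined treatment."""
    return (
        MarkerSpec("MMP-3", frozenset({IL1B})),
        MarkerSpec("MGP", frozenset({CARPROFEN})),
        MarkerSpec("IL-8", frozenset({IL1B_CARPROFEN})),
    )


def study_config(seed: int) -> GeneratorConfig:
    """The generator configuration emulating the full study: 150 shared
    background proteins, the default marker panel, 10% dropout, 30%
    multiplicative noise, and one IL-1β+carprofen sample retaining only 5%
    of the median protein count."""
    return GeneratorConfig(
        seed=seed,
        n_background_proteins=150,
        markers=default_markers(),
        dropout_prob=0.1,
        noise_cv=0.3,
        anomalous_sample=(IL1B_CARPROFEN, 0.05),
    )


# ---------------------------------------------------------------------------
# latent abundance model


def _validate_markers_against_design(design: StudyDesign, config: GeneratorConfig) -> None:
    known = set(design.classes)
    for m in config.markers:
        unknown = set(m.elevated_in) - known
        if unknown:
            raise GeneratorError(
                f"marker {m.protein_id!r} elevated in unknown classes {sorted(unknown)}"
            )
    if config.anomalous_sample is not None:
        cls = config.anomalous_sample[0]
        if cls not in known:
            raise GeneratorError(f"anomalous_sample class {cls!r} not in design")


def _latent_abundance(
    design: StudyDesign, config: GeneratorConfig, rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the latent protein-by-sample abundance and sample metadata.

    Abundance = baseline x class effect x subject offset x lognormal noise,
    zeroed by per-(protein, sample) dropout and per-class marker absence.
    The anomalous sample, if configured, additionally keeps only a small
    random subset of its detectable proteins.
    """
    _validate_markers_against_design(design, config)
    samples = design.sample_table()
    n_samp = len(samples)

    protein_ids = [m.protein_id for m in config.markers]
    protein_ids += [f"BG{i + 1:04d}" for i in range(config.n_background_proteins)]
    n_prot = len(protein_ids)

    # Fixed draw order keeps a given seed byte-reproducible.
    background_base = rng.lognormal(mean=np.log(0.05), sigma=1.0,
                                    size=config.n_background_proteins)
    subject_offsets = rng.lognormal(mean=0.0, sigma=_SUBJECT_LOG_SD,
                                    size=design.subjects)
    if config.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.noise_cv ** 2)))
        noise = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                              size=(n_prot, n_samp))
    else:
        noise = np.ones((n_prot, n_samp))
    present = rng.random(size=(n_prot, n_samp)) >= config.dropout_prob

    base = np.empty(n_prot)
    mult = np.ones((n_prot, n_samp))
    classes = samples["class"].to_numpy()
    for i, marker in enumerate(config.markers):
        base[i] = marker.baseline_score
        elevated = np.isin(classes, list(marker.elevated_in))
        mult[i, elevated] = marker.effect_multiplier
        if marker.presence_prob_in:
            probs = np.array([marker.presence_prob_in.get(c, 1.0) for c in classes])
            present[i] &= rng.random(size=n_samp) < probs
    base[len(config.markers):] = background_base

    subj = samples["subject"].to_numpy() - 1
    abundance = base[:, None] * mult * subject_offsets[subj][None, :] * noise
    abundance = np.where(present, abundance, 0.0)

    if config.anomalous_sample is not None and n_prot > 0:
        cls, frac = config.anomalous_sample
        cls_idx = np.flatnonzero(classes == cls)
        target_idx = int(rng.choice(cls_idx))
        nonzero_counts = (abundance > 0).sum(axis=0)
        median_count = float(np.median(nonzero_counts))
        n_keep = int(np.floor(frac * median_count))
        detectable = np.flatnonzero(abundance[:, target_idx] > 0)
        n_keep = min(n_keep, len(detectable))
        kept = rng.choice(detectable, size=n_keep, replace=False) if n_keep else []
        mask = np.zeros(n_prot, dtype=bool)
        mask[np.asarray(kept, dtype=int)] = True
        abundance[~mask, target_idx] = 0.0

    table = pd.DataFrame(abundance, index=protein_ids,
                         columns=samples["sample_id"].tolist())
    return table, samples


# ---------------------------------------------------------------------------
# outputs


def generate_peptide_table(design: StudyDesign, config: GeneratorConfig) -> pd.DataFrame:
    """Peptide-identification counts, one row per (protein, sample).

    Each protein has a fixed number of theoretically observable tryptic
    peptides; observed counts are negative-binomial with mean proportional
    to the latent abundance, so marker proteins yield stochastically more
    peptides in their elevated classes. The same seed reproduces the table
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    abundance, samples = _latent_abundance(design, config, rng)
    protein_ids = list(abundance.index)
    sample_ids = list(abundance.columns)
    if not protein_ids:
        return pd.DataFrame(columns=["protein_id", "sample_id",
                                     "observed_peptides", "observable_peptides"])

    observable = rng.integers(5, 51, size=len(protein_ids))
    mu = abundance.to_numpy() * observable[:, None]
    p = _NB_DISPERSION / (_NB_DISPERSION + mu)
    observed = rng.negative_binomial(_NB_DISPERSION, p)
    observed[mu == 0] = 0

    long = pd.DataFrame({
        "protein_id": np.repeat(protein_ids, len(sample_ids)),
        "sample_id": np.tile(sample_ids, len(protein_ids)),
        "observed_peptides": observed.ravel(),
        "observable_peptides": np.repeat(observable, len(sample_ids)),
    })
    return long


def generate_quant_matrix(
    design: StudyDesign, config: GeneratorConfig, score_type: str = "empai",
) -> SampleQuantMatrix:
    """Protein-level score matrix produced directly from latent abundance.

    ``empai`` scores are the latent abundances themselves (nonnegative,
    unbounded); ``probability`` scores pass the abundance through a
    saturating transform ``1 - exp(-a / 0.3)`` so strong proteins approach
    certainty. Absent proteins score exactly 0 and class labels are
    attached per the design.
    """
    if score_type not in ("empai", "probability"):
        raise GeneratorError(f"score_type must be 'empai' or 'probability', got {score_type!r}")
    rng = np.random.default_rng(config.seed)
    abundance, samples = _latent_abundance(design, config, rng)

    values = abundance.to_numpy()
    if score_type == "probability":
        values = 1.0 - np.exp(-values / _PROB_SCALE)
        values = np.clip(values, 0.0, 1.0)
    scores = pd.DataFrame(values,
                          index=[feature_id(p, score_type) for p in abundance.index],
                          columns=abundance.columns)
    scores = scores.reindex(sorted(scores.index), axis=0)
    labels = pd.Series(samples["class"].to_numpy(),
                       index=samples["sample_id"].tolist(), name="class")
    return SampleQuantMatrix(
        scores=scores, labels=labels,
        provenance=f"synthetic {score_type} matrix, seed={config.seed}",
    )


def marker_manifest(config: GeneratorConfig) -> pd.DataFrame:
    """Ground-truth table of planted markers for downstream checks."""
    rows = [{
        "protein_id": m.protein_id,
        "elevated_in": ";".join(sorted(m.elevated_in)),
        "baseline_score": m.baseline_score,
        "effect_multiplier": m.effect_multiplier,
    } for m in config.markers]
    return pd.DataFrame(rows, columns=["protein_id", "elevated_in",
                                       "baseline_score", "effect_multiplier"])
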