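# Methods

`proteorules` reimplements, as a reusable library, a classification-driven
biomarker-discovery analysis for label-free mass-spectrometry secretome
data: per-sample protein scores are fed to a stochastic threshold-rule
learner, the learner is evaluated by leave-one-out cross-validation with
permutation significance testing, and large ensembles of learner runs are
mined for per-class protein rankings and protein-pair networks. This note
records the models, the defaults and why they were chosen, and what the
synthetic data does and does not establish.

## Quantification

Two per-sample protein scores are supported.

**emPAI.** The protein abundance index is the number of observed peptides
divided by the number of theoretically observable tryptic peptides,
PAI = N_observed / N_observable, and the exponentially modified form
emPAI = 10^PAI − 1 is proportional to absolute protein amount. We compute
it exactly; a protein with no observed peptides scores 0.

**Probability score.** A per-protein identification probability combined
from independent peptide-level probabilities as 1 − Π(1 − p_i). This is a
deliberately simple closed form: it preserves the two properties the
downstream analysis relies on (bounded in [0, 1], monotone in evidence)
without modelling peptide degeneracy or protein grouping, which are out of
scope.

A score matrix holds features as `accession|score_type`, so a combined
emPAI + probability matrix carries the same accession once per score
block, and the two stay distinct features throughout ranking and network
mining. A protein absent from a sample scores exactly 0 rather than
missing: rule conditions of the form "greater than 0" are only meaningful
with explicit zeros.

**Anomalous-sample filter.** The study dropped one sample by inspection
because very few proteins were identified in it. We operationalise this
as a reproducible rule: a sample is removed when its nonzero-protein
count is below `min_fraction_of_median` (default 0.25) times the median
nonzero-protein count over samples. On the default synthetic study this
removes exactly the planted sparse sample, 24 → 23.

## The rule learner

The classifier is an ordered list of conjunctive threshold rules with an
explicit default class — the untreated control group when present,
otherwise the majority class. Each rule is `IF feature > x [AND …] THEN
class`; inequalities are strict; prediction takes the class of the first
matching rule, and samples matching no rule fall to the default. No rule
may predict the default class, so the control group is characterised by
the absence of treatment signatures, and rankings and networks never
contain the default class.

Learning is sequential covering with a seeded genetic search per rule:

1. Score every single threshold condition (feature × direction ×
   candidate threshold) on the not-yet-covered samples; candidate
   thresholds are midpoints between consecutive distinct observed values,
   so learned thresholds never sit on a training score.
2. Seed a population from the top of that table (the first individual
   takes the optimum; the rest draw from the ten best), then evolve for a
   fixed number of generations with tournament selection, uniform
   crossover on condition lists, and mutations that add or remove a
   condition or perturb a threshold.
3. Append the best admissible rule, remove the samples it covers, and
   repeat until only default-class samples remain, `max_rules` is hit, or
   no rule is admissible.

**Fitness.** A candidate covering `cov` of the remaining samples, of
which a fraction `acc` belong to its best non-default class, scores

    fitness = acc × min(1, cov / (breakpoint × n_train)) × margin × 0.5^(k−1)

with `k` the number of conditions. The coverage term (breakpoint default
0.25) is measured against the full training set, not the shrinking
remainder, so late rules that chase one or two leftover samples stay
penalised. The margin term is the narrowest gap any of the rule's
thresholds sits in, where gap width is measured as a saturating
log-fold-change, g/(g + log 2) with g the log-ratio of the flanking
observed values (offset by half the feature's median positive value so
zeros stay finite). The parsimony term halves fitness per extra
condition. Margin and parsimony are the learner's generalisation
pressure: with ~150 features and ~23 samples, conjunctions of narrow-gap
thresholds reach perfect in-sample accuracy by chance, and a fitness
without these terms selects them; thresholds centred in large abundance
fold-changes are the ones that survive resampling. Admissibility requires
accuracy ≥ `min_rule_accuracy` (default 0.7) and coverage of at least
half the breakpoint.

**Determinism and stochasticity.** All randomness flows from one integer
seed through a single generator; the same seed and data reproduce the
rule set byte-for-byte, while different seeds explore different
near-optimal rule sets — the property the ensemble analysis depends on.

**Tie-breaking.** Equal-fitness rules are ordered by wider coverage, then
fewer conditions, then lexicographic condition lists, so results do not
depend on dictionary order or floating-point enumeration order.

## Evaluation

With ~23 samples, leave-one-out cross-validation extracts the most
information from the data: one model per held-out sample, each trained
with its own seed derived by hashing the base seed with the split index.
Accuracy is reported both as a fraction and as a percentage rounded to
one decimal (18/23 → 78.3).

Significance is assessed by a one-tailed permutation test: class labels
are reassigned uniformly at random while preserving the class-size
multiset, the full LOOCV evaluation is re-run per permutation (default
50), and the empirical p-value is (r + 1)/(n + 1) with r the number of
permuted accuracies at or above the observed one. This estimator can
never be zero and resolves no further than 1/(n + 1); a Gaussian
upper-tail p fitted to the permuted accuracies is reported alongside for
comparison with analyses that quote far smaller values, but the empirical
p is primary.

## Ensemble mining

A single run is one sample from the distribution of models the learner
can produce, so the mining stage trains `n_runs` rule sets (default
10,000; consecutive seeds from a base seed) on the full matrix and
counts, per non-default class:

- **Ranking** — how many rules each feature appears in (once per rule,
  however many conditions use it), with `share` = 100 × count / total
  feature-appearances in that class's rules;
- **Pairs** — for every rule using ≥ 2 distinct features, each unordered
  2-subset counts once toward the rule's class.

The network keeps the `k` (default 100) most frequent pairs per class,
with deterministic lexicographic tie-breaks, and is exported as SIF and
GraphML with class, count, and a per-class colour attribute (blue for
IL-1β, red for carprofen, green for the combined treatment). Hub proteins
are ranked by number of distinct neighbours across classes.

## Synthetic data

No per-sample quantification matrices were published for the original
study, so the generator emulates its design: four treatment classes
(control, IL-1β, carprofen, IL-1β+carprofen), six replicates per class
split across two subjects (24 samples), and one IL-1β+carprofen sample
retaining only 5% of the median protein count, mimicking a failed
identification run. Subject identity is a mild multiplicative offset
(log-SD 0.15) and is metadata only — the analysis pools subjects.

Latent abundance per protein and sample is
baseline × class-effect × subject-offset × lognormal noise, zeroed by
per-cell dropout. Defaults: 150 background proteins with lognormal
baselines (median 0.05, log-SD 1), dropout probability 0.1, noise CV 0.3.
The marker panel plants one elevated protein per treated class, following
the class associations of the proteins that dominate the original
rankings: MMP-3 for IL-1β, MGP for carprofen, IL-8 for IL-1β+carprofen,
each with effect multiplier 10. Marker presence can additionally be
suppressed per class to emulate proteins detected everywhere except one
treatment group.

Two outputs share this latent layer. The peptide table draws observed
peptide counts from a negative binomial (dispersion 5) with mean
abundance × observable peptides, observable counts fixed per protein
(5–50); it feeds the emPAI stage. The direct score matrix uses the latent
abundance itself as the emPAI-type score and the saturating transform
1 − exp(−a/0.3) as the probability-type score. Score magnitudes were
chosen so that thresholds in the 0.01–0.9 range printed in the original
example rules are plausible; no distributional facts about the real
scores are published, so this is a plausibility choice, not a fit.

**What the synthetic data does not capture:** correlated proteins
(co-regulation, shared peptides), batch structure beyond the subject
offset, heavy-tailed contaminants, or intensity-dependent missingness.
Passing tests therefore demonstrate that the pipeline recovers planted
class structure of realistic sparsity and magnitude — not performance on
real spectra.

## Problem sizes and numerical choices

The test suite scales the study down where full size adds nothing:
parameter-recovery checks run LOOCV at 15 generations × 40 individuals
and 200-run ensembles over 20 generator seeds; null calibration uses 50
repetitions of 19 permutations each; the mining oracle uses 120 random
rule-set fixtures. The pipeline defaults (10,000 runs, 50 permutations,
k = 100) remain the library defaults.

Two findings shaped the null-calibration setup. First, the permutation
test assumes exchangeable samples; the study's two-subject blocking
violates this under permutation (permuted labels correlate with the
per-subject offset, so permuted accuracies acquire genuine spurious
signal and the p-values become conservative). Calibration therefore uses
a single-subject design; on blocked designs the permutation p is valid
but conservative, which is the safe direction. Second, a learner whose
admission bar no rule can clear on pure noise predicts the default class
for every sample, making the null accuracy distribution an atom at the
default-class fraction and the p-value distribution degenerate rather
than uniform; calibration therefore lowers the accuracy bar and coverage
breakpoint so the learner responds to noise and the accuracy spectrum is
informative.

Degenerate inputs are rejected loudly: single-class designs, empty
matrices, probability scores above 1, unlabeled samples, duplicate
(protein, sample) rows, observable peptide counts below 1. Features with
a single distinct value admit no thresholds and are unusable by the
learner. The permutation p-value is well-defined with zero-variance
permuted accuracies; only the Gaussian companion degenerates (to 0 or 1,
with a warning).

## Known limitations

- The learner's margin and parsimony pressure favour single-condition
  rules on cleanly separable data; multi-protein rules (and hence dense
  pair networks) mostly arise when single features cannot reach the
  accuracy bar, which is rarer in the synthetic data than in real
  secretome profiles.
- Seeds where a marker drops out of two or more of its class's six
  replicates are genuinely ambiguous at n = 23; LOOCV accuracy then falls
  below 0.8 with no learner able to do better from the data alone.
- The probability-score stand-in ignores peptide dependence and protein
  inference; it is a monotone evidence combiner, not a calibrated
  identification probability.
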