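# proteorules

Rule-ensemble classification and biomarker mining for label-free
mass-spectrometry secretome data.

## The problem

A cartilage-explant secretome experiment asks which secreted proteins
distinguish treatment conditions: tissue discs cultured in medium alone
(control), with the pro-inflammatory cytokine IL-1β, with the NSAID
carprofen, or with both. Label-free MS/MS yields, per sample, a sparse
vector of protein scores — the exponentially modified protein abundance
index (emPAI = 10^PAI − 1, PAI = observed peptides / theoretically
observable tryptic peptides) and/or a per-protein identification
probability. With only ~6 replicates per class and hundreds of protein
features, the analysis needs classifiers whose decisions are readable and
whose recurrent structure across many stochastic runs can be mined for
candidate biomarkers.

`proteorules` implements that pipeline end to end:

1. **quantify** — emPAI / probability scoring, matrix assembly
   (`accession|score_type` features, explicit zeros for absent proteins),
   combination of score blocks, and a reproducible filter for samples
   with anomalously few identified proteins;
2. **rule_learner** — a seeded stochastic sequential-covering learner
   producing ordered rule sets of strict threshold conditions
   (`IF MMP-3 > 0.1 AND UBIB < 0.2 THEN IL-1β`) with an explicit default
   class (the untreated control) for which no rules are ever emitted;
3. **evaluation** — leave-one-out cross-validation, confusion matrices,
   and one-tailed permutation significance testing with class sizes
   preserved, p = (r + 1)/(n + 1);
4. **ensemble_mining** — thousands of seeded runs aggregated into
   per-class protein rankings (count and share of rule appearances) and
   protein-pair networks (top-k most frequent within-rule pairs per
   class, exported as SIF/GraphML);
5. **synthetic_data** — a generator reproducing the study design (4
   classes × 6 replicates over 2 subjects, one anomalously sparse
   sample, planted marker proteins over a sparse lognormal background)
   so every stage is testable without the unpublished raw matrices.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run the full pipeline on the synthetic study (reduced ensemble for a
quick demonstration):

```sh
proteorules --verbose run-all --seed 7 --score-type empai \
    --n-runs 300 --n-permutations 10 --out demo/
```

which prints

```
retained 23 samples; LOOCV accuracy 91.3%; p_empirical 0.0909; report -> demo/report.json
```

and writes the filtered matrix, per-split predictions, confusion matrix,
per-class rankings, SIF/GraphML networks, and a single `report.json`
holding every seed, count, accuracy and p-value. In this run the anomaly
filter removed the one planted sparse IL-1β+carprofen sample (24 → 23
samples); LOOCV classified 21 of 23 samples correctly (91.3%, the two
errors being IL-1β samples whose marker dropped out, predicted as
control); the observed accuracy exceeded all 10 label-permuted
accuracies, so the empirical p-value is its floor of 1/11 ≈ 0.0909 (use
`--n-permutations 50` for the study-scale test, floor 1/51 ≈ 0.0196);
and the top-ranked protein for each treated class in the 300-run
ensemble ranking is the planted marker for that class — MMP-3 for IL-1β
(in 297 of 300 rule sets, a 98.0% share), MGP for carprofen (300/300),
IL-8 for IL-1β+carprofen (300/300) — mirroring the readable rule sets,
e.g.

```
IF MGP|empai > 0.17574838562870262 THEN carprofen
IF IL-8|empai > 0.1706448381255153 THEN IL-1β+carprofen
IF MMP-3|empai > 0.17707902746929205 THEN IL-1β
DEFAULT control
```

The same stages are available as `simulate`, `quantify`, `train`,
`loocv`, `permute`, `mine` and `network` subcommands, and as plain
library calls:

```python
import proteorules as pr

design = pr.generate_design(paper_defaults=True)        # 24 samples
matrix = pr.generate_quant_matrix(design, pr.study_config(seed=7), "empai")
filtered, removed = pr.filter_anomalous_samples(matrix, 0.25)
result = pr.run_loocv(filtered, pr.LearnerConfig(seed=7))
rulesets = pr.run_ensemble(filtered, pr.LearnerConfig(), n_runs=300, base_seed=7)
ranking = pr.rank_proteins(rulesets)
net = pr.build_network(pr.extract_pairs(rulesets), k=100)
```

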