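# prolncs

Proliferation-subtype discovery and prognostic lncRNA signatures for bulk
tumor transcriptomes.

Tumors that look identical under the microscope can differ sharply in how
fast they proliferate and how their patients fare. `prolncs` implements a
complete discovery pipeline for this problem, aimed at bulk expression
cohorts split into an mRNA and a lncRNA feature space with right-censored
survival follow-up:

1. **Pathway activity** — single-sample gene-set scores (an ssGSEA-style
   random-walk statistic; a GSVA-flavored variant behind a method tag) turn
   the gene × sample matrix into a pathway × sample activity matrix, with
   moderated-t differential activity between groups.
2. **Consensus subtypes** — repeated k-means over subsampled cohorts yields
   a consensus matrix; the number of clusters is chosen by PAC (proportion
   of ambiguous clustering), peripheral samples are removed by silhouette
   width, and subtype-differential lncRNAs are extracted.
3. **Label transfer** — nearest template prediction (cosine distance to
   binary marker templates, permutation confidence, FDR-based exclusion)
   carries the subtypes to independent cohorts.
4. **ProLnc modulators** — for each lncRNA *l* and mRNA *m*, the
   first-order partial correlation given tumor purity *z*,

       r_lm·z = (r_lm − r_lz · r_mz) / √((1 − r_lz²)(1 − r_mz²)),

   is converted to t = r·√(dof/(1−r²)) with dof = n − 3, the transcriptome
   is ranked by OI = sign(PCC)·(−log₁₀ p), each proliferation pathway is
   tested by a weighted Kolmogorov–Smirnov enrichment against a
   sample-permutation null, and confidence collapses to

       FSI = (1 − 2·FDR) · sign(ES)  ∈ [−1, 1].

   Pairs with FDR < 0.001 are flagged as proliferation-derived lncRNAs.
5. **Stable prognostic selection** — differential lncRNAs ∩ modulators
   (PALs) are screened by univariate Cox (p < 0.01), tested for robustness
   by 70% resampling (selected if p < 0.05 in ≥ 80% of runs), and kept only
   if significant with a consistent direction of effect in ≥ 3 cohorts.
6. **Risk signature** — a LASSO-penalized Cox model with the penalty chosen
   by 10-fold cross-validated partial-likelihood deviance; the risk score
   is the linear predictor Σ βᵢxᵢ, evaluated by Harrell's C, IPCW
   time-dependent AUC, log-rank-optimal dichotomization, and multivariable
   Cox independence tests.

Every stage is exercisable on synthetic multi-cohort data with planted
ground truth (`prolncs.simulate`), so subtype recovery, modulator
sensitivity, null calibration and signature performance are all measurable.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/05_signature_and_evaluation.py` (the end-to-end pipeline on
a four-cohort synthetic design, 350/100/64/68 samples) prints:

```
PAC selects k = 2; 12 differential lncRNAs; 12 PALs (differential AND modulator)
bootstrap-stable: ['LNC0002', 'LNC0006', 'LNC0008', 'LNC0016', 'LNC0035']
stable prognostic (>=3 of 4 cohorts, consistent sign): ['LNC0002', 'LNC0006', 'LNC0008', 'LNC0035']
planted prognostic truth: ['LNC0002', 'LNC0006', 'LNC0008', 'LNC0016', 'LNC0035']

signature: 4 lncRNAs at lambda = 0.0058
  LNC0002: coef = +0.435 (risk)
  ...
Harrell C-index per cohort (0.5 = random, 1.0 = perfect ranking):
  discovery: 0.707
  validation 1: 0.751
IPCW AUC for death by t on the discovery cohort:
  t = 12 months: AUC = 0.762 (152 cases / 191 controls)
```

Reading this: consensus clustering finds exactly the two planted subtypes;
the funnel (differential ∩ modulator → screen → bootstrap → cross-cohort
consensus) recovers four of the five planted prognostic lncRNAs with no
false selections (the fifth reached significance in only two of the four
cohorts — exactly the borderline case the consensus filter is designed to
arbitrate); and the fitted signature ranks survival well in all four
cohorts, with coefficient signs matching the planted risk/protective
directions.

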