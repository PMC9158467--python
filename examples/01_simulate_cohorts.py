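"""Generate a synthetic multi-cohort design with planted ground truth.

Builds seven disjoint pathway gene sets plus a background transcriptome,
then four cohorts that share the same planted structure (two subtypes,
purity-confounded modulator lncRNAs, prognostic lncRNAs with
proportional-hazards effects) but differ by batch offsets and noise —
the substrate every other example runs on.
"""

import pandas as pd

import prolncs as P

gene_sets = P.generate_gene_sets(n_pathways=7, genes_per_pathway=50,
                                 n_background=2000, seed=1)
print(f"{len(gene_sets)} pathway gene sets over {len(gene_sets.universe)} mRNAs")

cohorts = P.generate_multi_cohorts(
    gene_sets,
    n_samples=[350, 100, 64, 68],   # discovery + three validation cohorts
    subtype_shift=2.0,              # S2 pathway means sit 2 SD above S1
    modulator_frac=0.2,             # 20% of lncRNAs mirror one pathway
    n_lnc=60,
    hazard_beta=0.8,                # planted log hazard per SD of expression
    censor_rate=0.3,
    n_cohorts=4,
    batch_sd=0.5,
    seeds=[11, 12, 13, 14],
)

mrna, lnc, surv, truth = cohorts[0]
print(f"discovery cohort: {mrna.n_features} mRNAs x {mrna.n_samples} samples, "
      f"{lnc.n_features} lncRNAs")
print(f"observed censoring fraction: {1 - surv.event.mean():.2f} "
      "(events are deaths; the rest are administratively censored)")
counts = pd.Series(truth.subtype_of_sample).value_counts()
print(f"planted subtypes: { {str(k): int(v) for k, v in counts.items()} }  "
      "(S2 = hyperproliferative)")
print(f"planted modulator pairs: {len(truth.modulator_pairs)}; "
      f"prognostic lncRNAs: {truth.prognostic_lnc}")
print("positive coefficients are risk factors, negative ones protective;")
print("all downstream examples try to re-discover exactly this truth.")
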