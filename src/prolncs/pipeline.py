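"""End-to-end orchestration of the discovery pipeline on multi-cohort data.

The stages mirror the full analysis: pathway activity scoring, consensus
subtype discovery on the discovery cohort, silhouette core filtering,
subtype-differential lncRNAs, ProLnc modulator inference, PAL intersection,
bootstrap-stable prognostic screening, cross-cohort consensus, LASSO-Cox
signature fitting, and survival evaluation on every cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .activity import score_gene_sets
from .consensus import consensus_cluster, differential_lncrnas, silhouette_core_filter
from .containers import GeneSetCollection
from .evaluation import harrell_cindex
from .ntp import build_templates, ntp_predict
from .prolnc import run_prolnc
from .selection import bootstrap_stability_select, cross_cohort_consensus, intersect_pals, univariate_cox
from .signature import compute_risk_score, fit_lasso_cox

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    consensus: list
    best_k: int
    assignments: pd.Series
    core_samples: list
    delnc: pd.DataFrame
    prolnc_table: pd.DataFrame
    pals: list
    stability: pd.DataFrame
    cohort_cox: list
    sppal: pd.DataFrame
    model: object = None
    risk_scores: list = field(default_factory=list)
    cindex: list = field(default_factory=list)
    ntp_predictions: list = field(default_factory=list)


def run_pipeline(
    gene_sets: GeneSetCollection,
    cohorts,
    purities=None,
    *,
    k_range=range(2, 10),
    consensus_iters: int = 100,
    n_perm: int = 200,
    bootstrap_runs: int = 200,
    n_markers: int = 50,
    min_cohorts: int = 3,
    n_folds: int = 10,
    seed: int = 0,
) -> PipelineResult:
    """Run the whole discovery pipeline.

    ``cohorts`` is a list of ``(mrna, lnc, survival, truth)`` tuples (the
    generator's output); the first cohort is the discovery cohort. Tumor
    purity is taken from ``purities`` (list of Series) or, if absent, from
    each cohort's truth object.
    """
    mrna, lnc, surv, truth = cohorts[0]
    if purities is None:
        purities = [pd.Series(c[3].purity) for c in cohorts]

    activity = score_gene_sets(mrna, gene_sets)
    consensus = consensus_cluster(
        activity, k_range=k_range, n_iter=consensus_iters, seed=seed
    )
    best = min(consensus, key=lambda r: r.pac)
    core, _ = silhouette_core_filter(activity, best.assignments)
    delnc = differential_lncrnas(lnc, best.assignments.loc[core])

    prolnc_table = run_prolnc(
        lnc, mrna, purities[0], gene_sets, n_perm=n_perm, seed=seed
    )
    modulators = set(prolnc_table.loc[prolnc_table["flagged"], "lnc_id"])
    pals = intersect_pals(set(delnc.index[delnc["flagged"]]), modulators)

    stability = bootstrap_stability_select(
        lnc.values.loc[pals] if pals else lnc.values.iloc[:0],
        surv,
        runs=bootstrap_runs,
        seed=seed,
    )
    survivors = list(stability.index[stability["selected"]])

    cohort_cox = []
    for _, c_lnc, c_surv, _ in cohorts:
        rows = []
        for fid in survivors:
            if fid not in c_lnc.values.index:
                continue
            try:
                res = univariate_cox(
                    c_lnc.values.loc[fid, c_surv.sample_ids], c_surv, feature=fid
                )
            except ValueError:
                continue
            rows.append((fid, res.beta, res.p))
        cohort_cox.append(
            pd.DataFrame(rows, columns=["feature", "beta", "p"]).set_index("feature")
        )
    sppal = (
        cross_cohort_consensus(cohort_cox, min_cohorts=min_cohorts)
        if len(cohort_cox) >= 2 and survivors
        else pd.DataFrame(columns=["kept", "direction"])
    )
    final_feats = list(sppal.index[sppal["kept"]]) if len(sppal) else []

    result = PipelineResult(
        consensus=consensus,
        best_k=best.k,
        assignments=best.assignments,
        core_samples=core,
        delnc=delnc,
        prolnc_table=prolnc_table,
        pals=pals,
        stability=stability,
        cohort_cox=cohort_cox,
        sppal=sppal,
    )

    # subtype transfer to the validation cohorts
    try:
        template = build_templates(mrna, best.assignments.loc[core], n_markers=n_markers)
        for c_mrna, _, _, _ in cohorts[1:]:
            result.ntp_predictions.append(
                ntp_predict(c_mrna, template, n_perm=n_perm, seed=seed)
            )
    except ValueError:
        pass

    if len(final_feats) >= 2:
        X = lnc.values.loc[final_feats, surv.sample_ids].T
        result.model = fit_lasso_cox(X, surv, n_folds=n_folds, seed=seed)
        if result.model.features:
            for _, c_lnc, c_surv, _ in cohorts:
                Xc = c_lnc.values.loc[:, c_surv.sample_ids].T
                score = compute_risk_score(Xc, result.model)
                result.risk_scores.append(score)
                result.cindex.append(harrell_cindex(score, c_surv))
    return result
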