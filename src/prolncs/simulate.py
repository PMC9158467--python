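"""Synthetic multi-cohort generator with planted ground truth.

The generator emulates the structure the discovery pipeline is built for:

* correlated pathway gene modules whose mean activity separates two sample
  subtypes (S2 shifted upward by ``subtype_shift`` within-subtype SD units);
* lncRNAs that are true pathway modulators — noisy linear mixtures of one
  pathway's mean expression — with tumor purity as a shared confounder, so
  that naive correlations are inflated and the purity adjustment downstream
  is falsifiable;
* a subset of lncRNAs with planted proportional-hazards effects feeding an
  exponential survival simulator with independent uniform censoring;
* multiple cohorts sharing the truth structure but separated by additive
  gene-level batch offsets and independent noise.

Expression is Gaussian on the log2 scale: every downstream statistic is
rank- or correlation-based, so count-level noise models would add nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import CohortTruth, ExpressionMatrix, GeneSetCollection, SurvivalTable

__all__ = ["generate_gene_sets", "generate_cohort", "generate_multi_cohorts"]

# loading of the shared per-pathway factor / purity on pathway genes; the
# residual SD is set so the within-subtype gene SD is exactly 1
_W_FACTOR = 0.6
_W_PURITY = 0.4
_LNC_PURITY = 0.5  # purity loading of every lncRNA (confounding strength)
_BASELINE_MEDIAN = 24.0  # months; exponential baseline median survival


def generate_gene_sets(
    n_pathways: int,
    genes_per_pathway: int,
    n_background: int,
    seed: int,
) -> GeneSetCollection:
    """Disjoint pathway gene sets plus a background mRNA pool.

    The returned collection carries the background pool on its
    ``background`` attribute and the full mRNA universe (pathway genes then
    background, in generation order) on ``universe``.
    """
    if n_pathways < 1 or genes_per_pathway < 1 or n_background < 0:
        raise ValueError("counts must be positive (background may be zero)")
    rng = np.random.default_rng(seed)
    total = n_pathways * genes_per_pathway + n_background
    ids = [f"MRNA{i:05d}" for i in range(total)]
    order = rng.permutation(total)
    sets = {}
    pos = 0
    for p in range(n_pathways):
        members = [ids[j] for j in order[pos : pos + genes_per_pathway]]
        sets[f"PATHWAY_{p + 1:02d}"] = members
        pos += genes_per_pathway
    gs = GeneSetCollection(sets)
    gs.background = [ids[j] for j in order[pos:]]
    gs.universe = [g for members in gs.values() for g in members] + gs.background
    return gs


@dataclass
class _CohortPlan:
    """Seed-derived structure shared by every cohort of a design."""

    gene_sets: GeneSetCollection
    mrna_ids: list
    gene_mu: np.ndarray
    lnc_ids: list
    lnc_mu: np.ndarray
    modulator_pathway: dict  # lnc id -> pathway name
    prognostic_beta: dict  # lnc id -> log hazard per SD


def _make_plan(
    gene_sets: GeneSetCollection,
    n_lnc: int,
    modulator_frac: float,
    hazard_beta: float,
    n_prognostic: int,
    seed: int,
) -> _CohortPlan:
    rng = np.random.default_rng([seed, 0x5EED])
    mrna_ids = list(getattr(gene_sets, "universe", None) or gene_sets.all_genes)
    gene_mu = rng.normal(7.0, 2.0, size=len(mrna_ids))
    lnc_ids = [f"LNC{i:04d}" for i in range(n_lnc)]
    lnc_mu = rng.normal(4.0, 1.5, size=n_lnc)

    n_mod = int(round(modulator_frac * n_lnc))
    mod_idx = rng.choice(n_lnc, size=n_mod, replace=False)
    pathways = list(gene_sets)
    modulator_pathway = {
        lnc_ids[i]: pathways[j % len(pathways)]
        for j, i in enumerate(sorted(mod_idx))
    }

    n_prog = min(n_prognostic, n_lnc)
    pool = sorted(modulator_pathway) if len(modulator_pathway) >= n_prog else lnc_ids
    prog = [pool[i] for i in rng.choice(len(pool), size=n_prog, replace=False)]
    prognostic_beta = {
        lnc: (hazard_beta if j % 2 == 0 else -hazard_beta)
        for j, lnc in enumerate(sorted(prog))
    }
    return _CohortPlan(
        gene_sets, mrna_ids, gene_mu, lnc_ids, lnc_mu, modulator_pathway, prognostic_beta
    )


def _solve_censor_tau(t_event: np.ndarray, censor_rate: float) -> float:
    """Upper bound of the uniform censoring law achieving the target rate.

    With C ~ U(0, tau) independent of T, P(censored | T=t) = min(t/tau, 1);
    the expected censored fraction over the realized event times is monotone
    decreasing in tau, so the root is unique.
    """

    def frac(tau: float) -> float:
        return float(np.mean(np.minimum(t_event / tau, 1.0))) - censor_rate

    lo = float(np.min(t_event)) * 1e-6
    hi = float(np.max(t_event)) * 1e6
    return brentq(frac, lo, hi)


def generate_cohort(
    gene_sets: GeneSetCollection,
    n_samples: int,
    subtype_shift: float,
    modulator_frac: float,
    n_lnc: int,
    hazard_beta: float,
    censor_rate: float,
    seed: int,
    *,
    n_prognostic: int = 5,
    mixture_weight: float = 0.8,
    plan: _CohortPlan | None = None,
    batch_offsets: np.ndarray | None = None,
    sample_prefix: str | None = None,
):
    """One synthetic cohort: (mRNA matrix, lncRNA matrix, survival, truth).

    ``censor_rate`` must lie in [0, 1); 0 disables censoring entirely.
    ``mixture_weight`` is the loading of the pathway-mean signal in modulator
    lncRNAs. ``plan``/``batch_offsets``/``sample_prefix`` are internal hooks
    used by :func:`generate_multi_cohorts` to share truth across cohorts.
    """
    if not 0.0 <= modulator_frac <= 1.0:
        raise ValueError("modulator_frac must lie in [0, 1]")
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    if plan is None:
        plan = _make_plan(gene_sets, n_lnc, modulator_frac, hazard_beta, n_prognostic, seed)

    rng = np.random.default_rng([seed, 0xC001])
    prefix = sample_prefix if sample_prefix is not None else f"S{seed}"
    sample_ids = [f"{prefix}_{i:04d}" for i in range(n_samples)]

    # subtype labels, ~50/50
    n_s2 = n_samples // 2
    is_s2 = np.zeros(n_samples, dtype=bool)
    is_s2[rng.choice(n_samples, size=n_s2, replace=False)] = True
    subtype = np.where(is_s2, "S2", "S1")

    purity = rng.uniform(0.3, 1.0, size=n_samples)
    # standardized purity so loadings are on the unit-variance scale
    pz = (purity - 0.65) / np.sqrt((1.0 - 0.3) ** 2 / 12.0)

    resid_sd = np.sqrt(1.0 - _W_FACTOR**2 - _W_PURITY**2)
    factors = {p: rng.normal(0.0, 1.0, size=n_samples) for p in gene_sets}

    n_genes = len(plan.mrna_ids)
    mrna = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    pathway_of_gene = {}
    for p, members in gene_sets.items():
        for g in members:
            pathway_of_gene[g] = p
    for i, g in enumerate(plan.mrna_ids):
        p = pathway_of_gene.get(g)
        if p is None:
            continue
        mrna[i] = (
            _W_FACTOR * factors[p]
            + _W_PURITY * pz
            + resid_sd * mrna[i]
            + subtype_shift * is_s2
        )
    mrna += plan.gene_mu[:, None]
    if batch_offsets is not None:
        mrna += batch_offsets[:, None]
    mrna_df = pd.DataFrame(mrna, index=plan.mrna_ids, columns=sample_ids)

    # pathway mean signal each modulator mixes in, z-scored within cohort
    path_mean_z = {}
    for p, members in gene_sets.items():
        sub = mrna_df.loc[[g for g in members if g in mrna_df.index]]
        m = sub.to_numpy().mean(axis=0)
        sd = m.std()
        path_mean_z[p] = (m - m.mean()) / (sd if sd > 0 else 1.0)

    lnc = np.empty((n_lnc, n_samples))
    lnc_resid = {}
    res_share = {}
    for i, lid in enumerate(plan.lnc_ids):
        noise = rng.normal(0.0, 1.0, size=n_samples)
        if lid in plan.modulator_pathway:
            sig = path_mean_z[plan.modulator_pathway[lid]]
            res = np.sqrt(max(0.05, 1.0 - mixture_weight**2))
            lnc[i] = mixture_weight * sig + res * noise
        else:
            res = np.sqrt(1.0 - _LNC_PURITY**2)
            lnc[i] = _LNC_PURITY * pz + res * noise
        if lid in plan.prognostic_beta:
            lnc_resid[lid] = noise
            res_share[lid] = res
    lnc += plan.lnc_mu[:, None]
    lnc_df = pd.DataFrame(lnc, index=plan.lnc_ids, columns=sample_ids)

    # Exponential proportional-hazards survival. The planted hazard acts on
    # each prognostic lncRNA's intrinsic (pathway-orthogonal) component, so
    # the prognostic truth belongs to that lncRNA itself: co-modulators of
    # the same pathway stay prognostically null and false-selection rates
    # downstream are meaningful. The coefficient on the component is scaled
    # by 1/residual-share so the recorded beta is the lncRNA's marginal
    # (univariate) log hazard per SD of expression.
    lp = np.zeros(n_samples)
    for lid, beta in plan.prognostic_beta.items():
        u = lnc_resid[lid]
        uz = (u - u.mean()) / (u.std() if u.std() > 0 else 1.0)
        lp += (beta / res_share[lid]) * uz
    lam0 = np.log(2.0) / _BASELINE_MEDIAN
    t_event = rng.exponential(1.0, size=n_samples) / (lam0 * np.exp(lp))
    if censor_rate > 0:
        tau = _solve_censor_tau(t_event, censor_rate)
        c = rng.uniform(0.0, tau, size=n_samples)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(n_samples, dtype=int)

    surv = SurvivalTable(
        pd.DataFrame({"time": np.maximum(time, 1e-8), "event": event}, index=sample_ids)
    )
    truth = CohortTruth(
        subtype_of_sample=dict(zip(sample_ids, subtype)),
        modulator_pairs={(l, p) for l, p in plan.modulator_pathway.items()},
        prognostic_lnc=dict(plan.prognostic_beta),
        purity=dict(zip(sample_ids, purity)),
        seed=seed,
    )
    return (
        ExpressionMatrix(mrna_df, "mRNA"),
        ExpressionMatrix(lnc_df, "lncRNA"),
        surv,
        truth,
    )


def generate_multi_cohorts(
    gene_sets: GeneSetCollection,
    n_samples,
    subtype_shift: float,
    modulator_frac: float,
    n_lnc: int,
    hazard_beta: float,
    censor_rate: float,
    n_cohorts: int,
    batch_sd: float,
    seeds,
    **kwargs,
):
    """Cohorts sharing planted truth, separated by gene-level batch offsets.

    ``n_samples`` may be a scalar or a sequence of per-cohort sizes. Batch
    offsets are additive N(0, batch_sd) per gene, drawn independently per
    cohort; with ``batch_sd=0`` and identical seeds the cohorts coincide.
    """
    if n_cohorts < 2:
        raise ValueError("n_cohorts must be >= 2")
    seeds = list(seeds)
    if len(seeds) != n_cohorts:
        raise ValueError("seeds length must equal n_cohorts")
    if np.isscalar(n_samples):
        sizes = [int(n_samples)] * n_cohorts
    else:
        sizes = [int(v) for v in n_samples]
        if len(sizes) != n_cohorts:
            raise ValueError("n_samples length must equal n_cohorts")

    plan = _make_plan(
        gene_sets,
        n_lnc,
        modulator_frac,
        hazard_beta,
        kwargs.pop("n_prognostic", 5),
        seeds[0],
    )
    out = []
    for c in range(n_cohorts):
        if batch_sd > 0:
            brng = np.random.default_rng([seeds[c], 0xBA7C])
            offs = brng.normal(0.0, batch_sd, size=len(plan.mrna_ids))
        else:
            offs = None
        out.append(
            generate_cohort(
                gene_sets,
                sizes[c],
                subtype_shift,
                modulator_frac,
                n_lnc,
                hazard_beta,
                censor_rate,
                seeds[c],
                plan=plan,
                batch_offsets=offs,
                **kwargs,
            )
        )
    return out
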