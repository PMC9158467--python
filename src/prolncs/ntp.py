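"""Nearest template prediction: transferring subtype labels across cohorts.

Marker genes for each subtype are chosen by moderated-t ranking; a sample in
a new cohort is assigned the subtype whose binary marker template is nearest
in cosine distance over z-scored expression. Confidence comes from a
permutation null of random marker sets of the same sizes, and samples whose
BH FDR exceeds a threshold are excluded rather than forced into a subtype.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, moderated_t
from .containers import ExpressionMatrix

__all__ = ["SubtypeTemplate", "build_templates", "ntp_predict"]

logger = logging.getLogger(__name__)


@dataclass
class SubtypeTemplate:
    """Per-subtype marker gene lists (disjoint; all markers are 'up' in
    their own subtype) plus optional signed template values."""

    markers: dict[str, list[str]]
    signed: bool = False
    marker_stats: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        names = sorted(self.markers)
        if len(names) < 2:
            raise ValueError("need at least two subtypes")
        for i, a in enumerate(names):
            if len(self.markers[a]) < 5:
                raise ValueError(f"subtype {a!r} has fewer than 5 markers")
            for b in names[i + 1 :]:
                if set(self.markers[a]) & set(self.markers[b]):
                    raise ValueError("marker sets must be disjoint")

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.markers)

    @property
    def union(self) -> list[str]:
        return [g for s in self.subtypes for g in self.markers[s]]


def build_templates(
    expr: ExpressionMatrix,
    assignments,
    n_markers: int = 50,
) -> SubtypeTemplate:
    """Top ``n_markers`` up-regulated genes per subtype by moderated t.

    Requires at least 5 markers per subtype with moderated p < 0.05; errors
    otherwise. ``n_markers`` larger than the number of available significant
    genes is capped with a warning.
    """
    assignments = pd.Series(assignments)
    groups = sorted(assignments.unique())
    if len(groups) != 2:
        raise ValueError("exactly two subtypes are required")
    a_ids = list(assignments.index[assignments == groups[0]])
    b_ids = list(assignments.index[assignments == groups[1]])
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("each subtype needs >= 3 samples")
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    delta, t, p = moderated_t(vals.loc[:, a_ids].to_numpy(), vals.loc[:, b_ids].to_numpy())
    tab = pd.DataFrame({"t": t, "p": p, "delta": delta}, index=vals.index)

    markers = {}
    for name, sign in ((groups[0], 1.0), (groups[1], -1.0)):
        cand = tab[(np.sign(tab["t"]) == sign) & (tab["p"] < 0.05)]
        cand = cand.reindex((sign * cand["t"]).sort_values(ascending=False).index)
        if len(cand) < 5:
            raise ValueError(f"fewer than 5 significant markers for subtype {name!r}")
        take = min(n_markers, len(cand))
        if take < n_markers:
            warnings.warn(
                f"subtype {name!r}: only {take} significant markers available "
                f"(requested {n_markers})",
                stacklevel=2,
            )
        markers[str(name)] = list(cand.index[:take])
    return SubtypeTemplate(markers=markers, marker_stats=tab)


def _zscore_genes(vals: pd.DataFrame, means=None, sds=None) -> pd.DataFrame:
    if means is None:
        means = vals.mean(axis=1)
    if sds is None:
        sds = vals.std(axis=1, ddof=0)
    sds = sds.replace(0, 1.0) if isinstance(sds, pd.Series) else sds
    return vals.sub(means, axis=0).div(sds, axis=0)


def ntp_predict(
    expr_new: ExpressionMatrix,
    template: SubtypeTemplate,
    n_perm: int = 1000,
    fdr_exclude: float = 0.2,
    seed: int = 0,
    gene_means=None,
    gene_sds=None,
) -> pd.DataFrame:
    """Predict subtype labels in a new cohort with permutation confidence.

    Gene values are z-scored across the cohort's samples (or with
    ``gene_means``/``gene_sds`` supplied, e.g. for single-sample prediction);
    each sample is labeled by the nearest binary template in cosine distance
    over the present markers. The permutation p-value compares the observed
    distance with distances to random marker sets of the same per-subtype
    sizes drawn from the measured genes (add-one rule), and samples with BH
    FDR above ``fdr_exclude`` are flagged excluded.
    """
    vals = expr_new.values if isinstance(expr_new, ExpressionMatrix) else expr_new
    union = template.union
    present = [g for g in union if g in vals.index]
    missing = [g for g in union if g not in vals.index]
    if len(present) < 0.5 * len(union):
        raise ValueError(
            f"fewer than 50% of template markers measured; missing: {missing}"
        )

    z = _zscore_genes(vals, gene_means, gene_sds)
    subtypes = template.subtypes
    # binary template columns over the present marker union
    tmpl = np.zeros((len(present), len(subtypes)))
    pos = {g: i for i, g in enumerate(present)}
    sizes = []
    for j, s in enumerate(subtypes):
        kept = [g for g in template.markers[s] if g in pos]
        sizes.append(len(kept))
        for g in kept:
            tmpl[pos[g], j] = 1.0
    if min(sizes) == 0:
        raise ValueError("a subtype lost all its markers in this cohort")

    xs = z.loc[present].to_numpy().T  # samples x markers
    tnorm = np.linalg.norm(tmpl, axis=0)
    xnorm = np.linalg.norm(xs, axis=1)
    xnorm[xnorm == 0] = 1.0
    cosd = 1.0 - (xs @ tmpl) / (xnorm[:, None] * tnorm[None, :])

    best = cosd.argmin(axis=1)
    ties = np.isclose(cosd.min(axis=1, keepdims=True), cosd).sum(axis=1) > 1
    if ties.any():
        # argmin already returns the first (lexicographically first subtype)
        logger.info("%d sample(s) had tied template distances", int(ties.sum()))
    labels = np.array(subtypes)[best]
    d_obs = cosd[np.arange(len(best)), best]

    # shared null: random marker index sets of the same per-subtype sizes,
    # drawn from all measured genes; reused across samples so single-sample
    # and batch predictions agree for a fixed seed
    rng = np.random.default_rng(seed)
    all_genes = z.to_numpy()
    n_genes, n_samp = all_genes.shape
    m_total = sum(sizes)
    null_d = np.empty((n_perm, n_samp, len(subtypes)))
    for b in range(n_perm):
        ridx = rng.choice(n_genes, size=m_total, replace=False)
        xr = all_genes[ridx].T  # samples x m_total
        rt = np.zeros((m_total, len(subtypes)))
        start = 0
        for j, m in enumerate(sizes):
            rt[start : start + m, j] = 1.0
            start += m
        xrnorm = np.linalg.norm(xr, axis=1)
        xrnorm[xrnorm == 0] = 1.0
        null_d[b] = 1.0 - (xr @ rt) / (xrnorm[:, None] * np.linalg.norm(rt, axis=0)[None, :])

    p = np.empty(n_samp)
    for i in range(n_samp):
        nd = null_d[:, i, best[i]]
        p[i] = (np.sum(nd <= d_obs[i]) + 1.0) / (n_perm + 1.0)
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "label": labels,
            "distance": d_obs,
            "p": p,
            "fdr": fdr,
            "excluded": fdr > fdr_exclude,
        },
        index=vals.columns,
    )
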