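"""Per-sample gene-set activity scoring and downstream group comparisons.

Two single-sample scorers are provided behind a method tag:

* ``ssgsea`` — the random-walk sum statistic: genes are ranked per sample by
  expression (descending, ties broken by feature id), hits accumulate weight
  ``|rank statistic|^alpha`` normalized to 1, misses accumulate ``1/(N-Nh)``,
  and the score is the sum of the running (hit - miss) difference over all
  positions.
* ``gsva`` — a GSVA-flavored variant: gene-wise Gaussian kernel-CDF
  standardization across samples before ranking, and the signed maximum
  deviation of the walk instead of its sum.

Both are rank-based, so any strictly monotone transform of a sample's
expression leaves its scores unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

from ._stats import bh_adjust, moderated_t
from .containers import ExpressionMatrix, GeneSetCollection, SurvivalTable

__all__ = [
    "ActivityMatrix",
    "score_gene_sets",
    "differential_activity",
    "km_optimal_cutoff",
]


@dataclass
class ActivityMatrix:
    """Gene-set x sample enrichment scores with the scorer tag."""

    values: pd.DataFrame
    method: str = "ssgsea"

    @property
    def set_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _kcdf_standardize(x: np.ndarray) -> np.ndarray:
    """Gene-wise Gaussian kernel CDF across samples (GSVA's first step)."""
    out = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):
        row = x[i]
        sd = row.std()
        if sd == 0:
            out[i] = 0.5
            continue
        h = sd / 4.0
        out[i] = stats.norm.cdf((row[:, None] - row[None, :]) / h).mean(axis=1)
    return out


def score_gene_sets(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
    min_size: int = 5,
    method: str = "ssgsea",
) -> ActivityMatrix:
    """Score every gene set in every sample.

    Sets with fewer than ``min_size`` members present in ``expr`` — or with
    no non-members, which leaves the miss walk undefined — are dropped with a
    warning. ``normalize=True`` rescales the whole matrix by its
    (max - min), the cohort-wide normalization some ssGSEA implementations
    apply.
    """
    if expr.n_features < 2:
        raise ValueError("expression matrix needs >= 2 genes")
    values = expr.values
    features = values.index
    n = len(features)

    x = values.to_numpy(dtype=float)
    if method == "gsva":
        x = _kcdf_standardize(x)
    elif method != "ssgsea":
        raise ValueError(f"unknown method {method!r}")

    # per-sample descending order; ties broken by feature id so results are
    # reproducible across runs and platforms
    id_rank = np.argsort(np.argsort(features.to_numpy()))
    key = x - id_rank[:, None] * 1e-12
    order = np.argsort(-key, axis=0, kind="stable")

    if method == "ssgsea":
        rank_stat = np.arange(n, 0, -1, dtype=float)  # N..1 down the list
    else:
        rank_stat = np.arange(n, 0, -1, dtype=float) - (n + 1) / 2.0
    w_all = np.abs(rank_stat) ** alpha

    feat_pos = {g: i for i, g in enumerate(features)}
    rows = {}
    dropped = []
    for name, genes in sets.items():
        idx = [feat_pos[g] for g in genes if g in feat_pos]
        if len(idx) < min_size or len(idx) == n:
            dropped.append(name)
            continue
        memb = np.zeros(n, dtype=bool)
        memb[idx] = True
        hit = memb[order]  # genes-in-rank-order x samples
        w = np.where(hit, w_all[:, None], 0.0)
        p_hit = np.cumsum(w, axis=0) / w.sum(axis=0, keepdims=True)
        miss = (~hit).astype(float)
        p_miss = np.cumsum(miss, axis=0) / (n - len(idx))
        diff = p_hit - p_miss
        if method == "ssgsea":
            rows[name] = diff.sum(axis=0)
        else:
            amax = np.abs(diff).argmax(axis=0)
            rows[name] = diff[amax, np.arange(diff.shape[1])]
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} gene set(s) with <{min_size} present members "
            f"or no non-members: {dropped}",
            stacklevel=2,
        )
    if not rows:
        missing = list(sets)
        raise ValueError(f"no gene set overlaps the expression features: {missing}")
    mat = pd.DataFrame(rows, index=values.columns).T
    if normalize:
        span = mat.to_numpy().max() - mat.to_numpy().min()
        if span > 0:
            mat = mat / span
    return ActivityMatrix(mat, method=method)


def differential_activity(
    activity: ActivityMatrix,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Moderated-t differential activity between two sample groups.

    Returns one row per gene set with the mean difference (a - b), moderated
    t statistic, two-sided p, and BH FDR across sets.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs >= 3 samples")
    vals = activity.values if isinstance(activity, ActivityMatrix) else activity
    a = vals.loc[:, group_a].to_numpy()
    b = vals.loc[:, group_b].to_numpy()
    delta, t, p = moderated_t(a, b)
    return pd.DataFrame(
        {"set_name": vals.index, "delta": delta, "t_stat": t, "p": p, "fdr": bh_adjust(p)}
    ).set_index("set_name")


def km_optimal_cutoff(
    score,
    surv: SurvivalTable,
    min_prop: float = 0.1,
):
    """Log-rank-optimal dichotomizing cutoff for a continuous score.

    Scans cutoffs at observed score values keeping both strata at least
    ``min_prop`` of the cohort (and at least one event each), and returns the
    midpoint split maximizing the log-rank statistic, with that split's
    chi-square and (uncorrected) p-value. The p-value is optimistic because
    the cutoff is maximally selected; downstream use should treat it as
    descriptive.
    """
    score = np.asarray(score, dtype=float)
    time, event = surv.time, surv.event
    n = len(score)
    if n != len(time):
        raise ValueError("score and survival table differ in length")
    if event.sum() == 0:
        raise ValueError("log-rank undefined: no events observed")
    uniq = np.unique(score)
    if uniq.size < 2:
        raise ValueError("no admissible cutoff: all scores identical")
    min_n = max(int(np.ceil(min_prop * n)), 1)
    best = None
    for i in range(uniq.size - 1):
        low = score <= uniq[i]
        n_low = int(low.sum())
        if n_low < min_n or n - n_low < min_n:
            continue
        if event[low].sum() == 0 or event[~low].sum() == 0:
            continue
        res = logrank_test(time[low], time[~low], event[low], event[~low])
        cut = (uniq[i] + uniq[i + 1]) / 2.0
        if best is None or res.test_statistic > best[1]:
            best = (cut, res.test_statistic, res.p_value)
    if best is None:
        raise ValueError("no admissible cutoff under the given constraints")
    return best
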