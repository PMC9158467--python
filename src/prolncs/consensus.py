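"""Consensus k-means subtype discovery with PAC model selection.

The procedure repeatedly subsamples the cohort, clusters the subsample with
k-means (Euclidean), and records how often each sample pair lands in the same
cluster among the iterations where both were drawn. The resulting consensus
matrix is summarized by PAC (proportion of ambiguous clustering: entries in
an intermediate band), the k with the lowest PAC being the cleanest
partition. Final memberships come from average-linkage hierarchical
clustering of (1 - consensus), and peripheral samples are removed by
silhouette width before downstream differential analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

from ._stats import bh_adjust, moderated_t
from .activity import ActivityMatrix
from .containers import ExpressionMatrix

__all__ = [
    "ConsensusResult",
    "consensus_cluster",
    "pac_score",
    "silhouette_core_filter",
    "differential_lncrnas",
]


@dataclass
class ConsensusResult:
    k: int
    consensus_matrix: pd.DataFrame
    assignments: pd.Series
    pac: float
    mean_silhouette: float


def _activity_values(activity) -> pd.DataFrame:
    return activity.values if isinstance(activity, ActivityMatrix) else activity


def _zscore_rows(df: pd.DataFrame) -> np.ndarray:
    x = df.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def pac_score(consensus_matrix, lower: float = 0.1, upper: float = 0.9) -> float:
    """Fraction of strictly-upper-triangle entries strictly inside (lower, upper)."""
    if lower >= upper:
        raise ValueError("lower must be < upper")
    cm = np.asarray(
        consensus_matrix.to_numpy()
        if isinstance(consensus_matrix, pd.DataFrame)
        else consensus_matrix,
        dtype=float,
    )
    iu = np.triu_indices_from(cm, k=1)
    vals = cm[iu]
    return float(np.mean((vals > lower) & (vals < upper)))


def consensus_cluster(
    activity,
    k_range=range(2, 10),
    n_iter: int = 1000,
    sample_frac: float = 0.8,
    seed: int = 0,
) -> list[ConsensusResult]:
    """Consensus k-means over a range of k.

    Rows (gene sets) are z-scored across samples before clustering so every
    pathway contributes equally to the Euclidean geometry. Each iteration
    draws ``sample_frac`` of the samples without replacement and clusters
    them once per k with a k-means++ start from the iteration's RNG stream.
    """
    vals = _activity_values(activity)
    samples = list(vals.columns)
    n = len(samples)
    k_range = list(k_range)
    if n < 2 * max(k_range):
        raise ValueError("need at least 2*max(k) samples")
    X = _zscore_rows(vals).T  # samples x features

    rng = np.random.default_rng(seed)
    m = max(2, int(round(sample_frac * n)))
    together = {k: np.zeros((n, n)) for k in k_range}
    cosampled = np.zeros((n, n))
    for _ in range(n_iter):
        idx = rng.choice(n, size=m, replace=False)
        cosampled[np.ix_(idx, idx)] += 1
        sub = X[idx]
        for k in k_range:
            km = KMeans(
                n_clusters=k,
                n_init=1,
                init="k-means++",
                random_state=int(rng.integers(2**31 - 1)),
            )
            labels = km.fit_predict(sub)
            for c in range(k):
                members = idx[labels == c]
                together[k][np.ix_(members, members)] += 1

    never = (cosampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pair(s) never co-subsampled; "
            "their consensus entries are set to 0",
            stacklevel=2,
        )
    results = []
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            cm = np.where(cosampled > 0, together[k] / np.maximum(cosampled, 1), 0.0)
        np.fill_diagonal(cm, 1.0)
        cm = (cm + cm.T) / 2.0
        dist = 1.0 - cm
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=k, criterion="maxclust")
        try:
            sil = float(silhouette_score(X, labels)) if len(set(labels)) > 1 else np.nan
        except ValueError:
            sil = np.nan
        results.append(
            ConsensusResult(
                k=k,
                consensus_matrix=pd.DataFrame(cm, index=samples, columns=samples),
                assignments=pd.Series(labels, index=samples, name="cluster"),
                pac=pac_score(cm),
                mean_silhouette=sil,
            )
        )
    return results


def silhouette_core_filter(activity, assignments):
    """Drop peripheral samples (silhouette width <= 0) from the partition.

    Returns ``(core_samples, widths)``. Samples in singleton clusters get
    width 0 and are removed, with a warning.
    """
    vals = _activity_values(activity)
    assignments = pd.Series(assignments)
    samples = list(assignments.index)
    labels = assignments.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    X = _zscore_rows(vals.loc[:, samples]).T
    if (counts == 1).any():
        warnings.warn("singleton cluster(s): member widths set to 0 and removed", stacklevel=2)
    widths = silhouette_samples(X, labels)
    widths = pd.Series(widths, index=samples, name="silhouette_width")
    core = [s for s in samples if widths[s] > 0]
    return core, widths


def differential_lncrnas(
    lnc_expr: ExpressionMatrix,
    assignments,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Subtype-differential lncRNAs by moderated t on log2 expression.

    Flags a lncRNA iff |mean difference| >= ``lfc_min`` (log2 scale) and
    BH FDR < ``fdr_max``. Thresholds are conventional defaults and exposed
    because no canonical values exist for them.
    """
    assignments = pd.Series(assignments)
    groups = assignments.unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    groups = sorted(groups)
    a = assignments.index[assignments == groups[1]]  # second label minus first
    b = assignments.index[assignments == groups[0]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 core samples")
    vals = lnc_expr.values if isinstance(lnc_expr, ExpressionMatrix) else lnc_expr
    delta, t, p = moderated_t(vals.loc[:, a].to_numpy(), vals.loc[:, b].to_numpy())
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "lnc_id": vals.index,
            "log2fc": delta,
            "t_stat": t,
            "p": p,
            "fdr": fdr,
            "flagged": (np.abs(delta) >= lfc_min) & (fdr < fdr_max),
        }
    ).set_index("lnc_id")
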