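"""Small shared statistical helpers (moderated t, BH adjustment)."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["moderated_t", "bh_adjust"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def moderated_t(
    a: np.ndarray,
    b: np.ndarray,
    prior_df: float = 4.0,
):
    """Row-wise two-sample t with empirical-Bayes variance shrinkage.

    Per-feature pooled variances are shrunk toward their grand mean with
    ``prior_df`` pseudo-degrees of freedom, stabilising features whose sample
    variance is small by chance. Returns ``(delta, t, p)`` where ``delta`` is
    ``mean(a) - mean(b)`` per row.

    Parameters
    ----------
    a, b : arrays of shape (features, n1) and (features, n2)
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    delta = a.mean(axis=1) - b.mean(axis=1)
    df = n1 + n2 - 2
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    s2_0 = s2.mean()
    s2_tilde = (prior_df * s2_0 + df * s2) / (prior_df + df)
    denom = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, delta / np.where(denom > 0, denom, 1.0), 0.0)
        t = np.where((denom == 0) & (delta != 0), np.sign(delta) * np.inf, t)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
    p = np.clip(p, 0.0, 1.0)
    return delta, t, p
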