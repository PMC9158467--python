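"""Signature performance: concordance, IPCW time-dependent AUC, correlates.

Harrell's C treats score ties as half-concordant and excludes pairs that are
not comparable under censoring. The time-dependent AUC is the
cumulative/dynamic variant with inverse-probability-of-censoring weights
from the Kaplan-Meier estimate of the censoring distribution — under zero
censoring it reduces exactly to the Mann-Whitney AUC between cases
(event <= t) and controls (observed beyond t). C-index comparison uses a
paired bootstrap of the difference rather than a closed-form variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from ._stats import bh_adjust
from .containers import SurvivalTable

__all__ = [
    "TimeAUC",
    "harrell_cindex",
    "time_dependent_auc",
    "compare_cindices",
    "correlate_with_score",
]


@dataclass
class TimeAUC:
    horizon: float
    auc: float
    n_cases: int
    n_controls: int


def _score_array(score, surv: SurvivalTable) -> np.ndarray:
    if isinstance(score, pd.Series):
        score = score.loc[surv.sample_ids]
    return np.asarray(score, dtype=float)


def harrell_cindex(score, surv: SurvivalTable) -> float:
    """Harrell concordance of a risk score (higher score = higher risk)."""
    s = _score_array(score, surv)
    try:
        # lifelines expects higher prediction = longer survival
        return float(concordance_index(surv.time, -s, surv.event))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs under censoring") from exc


def time_dependent_auc(score, surv: SurvivalTable, horizons) -> list[TimeAUC]:
    """IPCW cumulative/dynamic AUC at each horizon (months)."""
    s = _score_array(score, surv)
    time, event = surv.time, surv.event
    horizons = [float(t) for t in horizons]
    t_max = time.max()
    out = []
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    for t in horizons:
        if t >= t_max:
            raise ValueError(f"horizon {t} beyond the observed follow-up {t_max}")
        n_cases = int(np.sum((time <= t) & (event == 1)))
        n_controls = int(np.sum(time > t))
        if n_cases == 0 or n_controls == 0:
            raise ValueError(f"horizon {t} has no cases or no controls")
        auc, _ = cumulative_dynamic_auc(y, y, s, [t])
        out.append(TimeAUC(t, float(auc[0]), n_cases, n_controls))
    return out


def compare_cindices(score_a, score_b, surv: SurvivalTable, n_boot: int = 1000, seed: int = 0):
    """Paired-bootstrap comparison of two risk scores' C-indices.

    Returns ``(delta, p)`` with delta = C_a - C_b on the full data and a
    two-sided percentile-bootstrap p (add-one smoothed).
    """
    a = _score_array(score_a, surv)
    b = _score_array(score_b, surv)
    if a.size != b.size:
        raise ValueError("scores must cover identical samples")
    n = a.size
    if n < 50:
        warnings.warn("fewer than 50 samples; comparison is unstable", stacklevel=2)
    time, event = surv.time, surv.event

    def _c(s, t, e):
        return concordance_index(t, -s, e)

    delta = float(_c(a, time, event) - _c(b, time, event))
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if event[idx].sum() == 0:
            continue
        try:
            deltas.append(_c(a[idx], time[idx], event[idx]) - _c(b[idx], time[idx], event[idx]))
        except ZeroDivisionError:
            continue
    deltas = np.asarray(deltas)
    lo = (np.sum(deltas <= 0) + 1.0) / (deltas.size + 1.0)
    hi = (np.sum(deltas >= 0) + 1.0) / (deltas.size + 1.0)
    p = float(min(1.0, 2.0 * min(lo, hi)))
    return delta, p


def correlate_with_score(
    features: pd.DataFrame,
    score,
    r_min: float = 0.4,
    fdr_max: float = 0.001,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate every feature row with the risk score and flag hits.

    A feature is flagged iff |r| > ``r_min`` and BH FDR < ``fdr_max``.
    Spearman by default (robust to the score's scale); constant rows are
    skipped with a warning.
    """
    score = pd.Series(score)
    shared = [s for s in features.columns if s in score.index]
    if len(shared) < 10:
        raise ValueError("need >= 10 shared samples")
    X = features.loc[:, shared].to_numpy(dtype=float)
    y = score.loc[shared].to_numpy(dtype=float)
    n = len(shared)

    const = np.ptp(X, axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s) skipped", stacklevel=2
        )
    keep = ~const
    Xk = X[keep]
    if method == "spearman":
        Xk = stats.rankdata(Xk, axis=1)
        yv = stats.rankdata(y)
    elif method == "pearson":
        yv = y
    else:
        raise ValueError(f"unknown method {method!r}")
    xm = Xk - Xk.mean(axis=1, keepdims=True)
    ym = yv - yv.mean()
    denom = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum())
    r = np.clip((xm @ ym) / denom, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = np.clip(2.0 * stats.t.sf(np.abs(t), n - 2), 0.0, 1.0)
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "feature": features.index[keep],
            "r": r,
            "p": p,
            "fdr": fdr,
            "flagged": (np.abs(r) > r_min) & (fdr < fdr_max),
        }
    ).set_index("feature")
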