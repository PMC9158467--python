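"""Stable prognostic lncRNA selection: screen, bootstrap, cohort consensus.

The funnel combines subtype-differential lncRNAs with pathway modulators
(PALs), keeps those passing a stringent univariate-Cox screen on the
discovery cohort, tests each survivor's robustness by repeated 70%
subsampling, and finally requires significance with a consistent direction
of effect in at least three independent cohorts (SPPALs).
"""

from __future__ import annotations

import logging
import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._cox import cox_univariate_fast
from .containers import ExpressionMatrix, SurvivalTable

__all__ = [
    "CoxResult",
    "intersect_pals",
    "univariate_cox",
    "bootstrap_stability_select",
    "cross_cohort_consensus",
]

logger = logging.getLogger(__name__)


@dataclass
class CoxResult:
    feature: str
    beta: float
    hr: float
    se: float
    z: float
    p: float
    n: int
    events: int
    converged: bool = True


def intersect_pals(delncs, modulators, how: str = "intersection") -> list[str]:
    """Combine differential lncRNAs with modulator lncRNAs into PALs.

    Intersection by default (a lncRNA must show both subtype-differential
    expression and pathway modulation); union available by flag.
    """
    a, b = set(delncs), set(modulators)
    out = a & b if how == "intersection" else a | b
    if not out:
        warnings.warn("PAL set is empty", stacklevel=2)
    return sorted(out)


def _align(x, surv: SurvivalTable):
    if isinstance(x, pd.Series):
        x = x.loc[surv.sample_ids].to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def univariate_cox(x, surv: SurvivalTable, feature: str = "x") -> CoxResult:
    """Single-covariate Cox partial-likelihood fit (Breslow ties)."""
    xv = _align(x, surv)
    fit = cox_univariate_fast(xv, surv.time, surv.event)
    return CoxResult(feature=feature, **fit)


def bootstrap_stability_select(
    expr,
    surv: SurvivalTable,
    screen_p: float = 0.01,
    frac: float = 0.7,
    runs: int = 1000,
    alpha: float = 0.05,
    keep_rate: float = 0.8,
    seed: int = 0,
    features=None,
    replace: bool = False,
) -> pd.DataFrame:
    """Two-stage stability selection of prognostic features.

    Stage 1 keeps features whose full-data univariate Cox p is below
    ``screen_p``. Stage 2 draws ``runs`` subsamples of ceil(frac*n) samples
    (without replacement by default; classical bootstrap via ``replace``),
    refits, and records the fraction of runs with p < ``alpha``; a feature is
    selected iff that inclusion rate reaches ``keep_rate``. Each feature has
    its own RNG stream keyed by (seed, feature id), so results are invariant
    to feature order. Resamples with fewer than two events are redrawn up to
    10 times, then counted as non-significant.
    """
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    vals = vals.loc[:, surv.sample_ids]
    n = vals.shape[1]
    if n < 30:
        raise ValueError("need >= 30 samples")
    if surv.event.sum() < 10:
        raise ValueError("need >= 10 events")
    time, event = surv.time, surv.event
    feats = list(features) if features is not None else list(vals.index)

    rows = []
    m = math.ceil(frac * n)
    for fid in feats:
        x = vals.loc[fid].to_numpy(dtype=float)
        try:
            full = cox_univariate_fast(x, time, event)
        except ValueError:
            rows.append((fid, np.nan, np.nan, False))
            continue
        if full["p"] >= screen_p:
            rows.append((fid, full["p"], np.nan, False))
            continue
        rng = np.random.default_rng([seed, zlib.crc32(str(fid).encode())])
        hits = 0
        for _ in range(runs):
            for _retry in range(10):
                idx = rng.choice(n, size=m, replace=replace)
                if event[idx].sum() >= 2:
                    break
            else:
                logger.warning("resample for %s kept < 2 events; counted as null", fid)
                continue
            if np.ptp(x[idx]) == 0:
                continue
            fit = cox_univariate_fast(x[idx], time[idx], event[idx])
            if fit["p"] < alpha:
                hits += 1
        rate = hits / runs
        rows.append((fid, full["p"], rate, rate >= keep_rate))
    return pd.DataFrame(
        rows, columns=["feature", "screen_p", "inclusion_rate", "selected"]
    ).set_index("feature")


def cross_cohort_consensus(
    cohort_tables,
    min_cohorts: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep features significant in >= ``min_cohorts`` cohorts with one sign.

    ``cohort_tables`` is a sequence (or mapping) of per-cohort data frames
    indexed by feature with ``beta`` and ``p`` columns. A feature missing
    from a cohort counts as non-significant there. Features whose
    significant cohorts disagree in the sign of beta are excluded even when
    the count is sufficient. Direction is ``risk`` (beta > 0) or
    ``protective`` (beta < 0).
    """
    if isinstance(cohort_tables, dict):
        tables = list(cohort_tables.values())
    else:
        tables = list(cohort_tables)
    if len(tables) < 2:
        raise ValueError("need >= 2 cohort tables")
    universe = sorted(set().union(*(set(t.index) for t in tables)))
    rows = []
    for fid in universe:
        sig_betas = []
        n_present = 0
        for t in tables:
            if fid not in t.index:
                logger.info("feature %s absent from a cohort; treated as null", fid)
                continue
            n_present += 1
            if t.loc[fid, "p"] < alpha:
                sig_betas.append(float(t.loc[fid, "beta"]))
        n_sig = len(sig_betas)
        consistent = n_sig > 0 and (all(b > 0 for b in sig_betas) or all(b < 0 for b in sig_betas))
        kept = n_sig >= min_cohorts and consistent
        direction = ""
        if kept:
            direction = "risk" if sig_betas[0] > 0 else "protective"
        rows.append((fid, n_present, n_sig, consistent, kept, direction))
    return pd.DataFrame(
        rows,
        columns=["feature", "n_cohorts", "n_significant", "sign_consistent", "kept", "direction"],
    ).set_index("feature")
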