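"""LASSO-Cox risk signature: fit, risk scores, independence testing.

The signature is an L1-penalized Cox model over the selected lncRNAs.
The penalty is chosen by k-fold cross-validation (folds stratified by event
status) at the minimum of the mean partial-likelihood deviance; features are
standardized internally for penalization and coefficients are returned on
the original expression scale. The risk score of a patient is the Cox linear
predictor (no intercept), so any positive rescaling of the coefficients
preserves the risk ordering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import breslow_loglik
from .containers import SurvivalTable

__all__ = ["SignatureModel", "fit_lasso_cox", "compute_risk_score", "multivariate_cox"]


@dataclass
class SignatureModel:
    """Selected features with Cox coefficients and the chosen penalty."""

    features: list[str]
    coefficients: dict[str, float]
    lambda_opt: float
    cv_curve: pd.DataFrame = field(repr=False, default=None)

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "coefficients": self.coefficients,
            "lambda_opt": self.lambda_opt,
            "cv_curve": self.cv_curve.to_dict(orient="list")
            if self.cv_curve is not None
            else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        curve = pd.DataFrame(d["cv_curve"]) if d["cv_curve"] else None
        return cls(d["features"], d["coefficients"], d["lambda_opt"], curve)


def _surv_y(surv: SurvivalTable):
    return Surv.from_arrays(event=surv.event.astype(bool), time=surv.time)


def fit_lasso_cox(
    X: pd.DataFrame,
    surv: SurvivalTable,
    n_folds: int = 10,
    lambda_grid=None,
    seed: int = 0,
    rule: str = "min",
) -> SignatureModel:
    """Cross-validated L1-penalized Cox fit.

    ``X`` is samples x features. ``lambda_grid`` defaults to the 100-value
    log-spaced path auto-scaled from the data. ``rule`` is ``"min"`` (lowest
    mean CV deviance, the default) or ``"1se"``.
    """
    if X.shape[1] < 2:
        raise ValueError("need >= 2 candidate features")
    X = X.loc[surv.sample_ids]
    event = surv.event
    if event.sum() < n_folds:
        raise ValueError("need at least one event per fold")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0, 1.0)
    Xs = ((X - mu) / sd).to_numpy()
    y = _surv_y(surv)

    if lambda_grid is None:
        probe = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=100, alpha_min_ratio=1e-3)
        probe.fit(Xs, y)
        lambda_grid = np.asarray(probe.alphas_)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    time_arr = surv.time
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=lambda_grid, fit_baseline_model=False)
    final.fit(Xs, y)
    fold_fits = []
    # the solver may stop the path early; align all fits on the common prefix
    n_common = len(final.alphas_)
    for tr, te in skf.split(Xs, event):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=lambda_grid, fit_baseline_model=False
        )
        model.fit(Xs[tr], y[tr])
        fold_fits.append((te, model.coef_))
        n_common = min(n_common, model.coef_.shape[1])
    lambda_grid = lambda_grid[:n_common]
    dev = np.zeros((n_folds, n_common))
    for f, (te, coefs) in enumerate(fold_fits):
        for j in range(n_common):
            lp = Xs[te] @ coefs[:, j]
            dev[f, j] = -2.0 * breslow_loglik(lp, time_arr[te], event[te])
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    j_min = int(np.argmin(mean_dev))
    if rule == "1se":
        thresh = mean_dev[j_min] + se_dev[j_min]
        j_opt = int(np.flatnonzero(mean_dev <= thresh)[0])  # largest lambda within 1 SE
    else:
        j_opt = j_min
    lambda_opt = float(lambda_grid[j_opt])

    beta_std = final.coef_[:, j_opt]
    beta = beta_std / sd.to_numpy()
    nz = np.flatnonzero(beta_std != 0)
    if nz.size == 0:
        warnings.warn("all coefficients shrunk to zero at the optimal penalty", stacklevel=2)
    features = [X.columns[i] for i in nz]
    curve = pd.DataFrame(
        {"lambda": lambda_grid, "mean_deviance": mean_dev, "se": se_dev}
    )
    return SignatureModel(
        features=features,
        coefficients={X.columns[i]: float(beta[i]) for i in nz},
        lambda_opt=lambda_opt,
        cv_curve=curve,
    )


def compute_risk_score(X: pd.DataFrame, model: SignatureModel) -> pd.Series:
    """Linear predictor sum(coef_i * x_i); empty models score 0 everywhere."""
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise ValueError(f"features missing from the expression matrix: {missing}")
    score = pd.Series(0.0, index=X.index, name="risk_score")
    for f in model.features:
        score += model.coefficients[f] * X[f]
    return score


def multivariate_cox(score, covariates: pd.DataFrame, surv: SurvivalTable) -> pd.DataFrame:
    """Multivariable Cox fit of the risk score adjusted for covariates.

    Constant covariate columns are dropped with a warning; a covariate pair
    (including the score) with |r| = 1 raises a collinearity error. Returns
    one row per term with beta, HR, 95% CI and p.
    """
    score = pd.Series(score)
    df = pd.DataFrame({"risk_score": score.loc[surv.sample_ids]})
    cov = covariates.loc[surv.sample_ids] if covariates is not None else pd.DataFrame(index=df.index)
    for c in cov.columns:
        col = cov[c].astype(float)
        if col.nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
            continue
        df[c] = col
    corr = df.corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    if np.any(np.isclose(np.abs(corr[iu]), 1.0)):
        raise ValueError("collinear covariate pair (|r| = 1)")
    df["time"] = surv.time
    df["event"] = surv.event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"multivariate Cox did not converge: {exc}") from exc
    out = cph.summary[
        ["coef", "exp(coef)", "se(coef)", "z", "p",
         "exp(coef) lower 95%", "exp(coef) upper 95%"]
    ].copy()
    out.columns = ["beta", "hr", "se", "z", "p", "hr_ci_low", "hr_ci_high"]
    return out
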