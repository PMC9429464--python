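"""Indicator-level ICCs, predictor correlations and collinearity checks.

The indicator ICC quantifies how much of each ordinal item's variability
sits between households.  It is computed on the latent-response scale
from a two-level random-intercept ordinal probit null model for that
item: with household effect variance sigma2_b and a unit within-level
probit residual, ICC = sigma2_b / (sigma2_b + 1).

Collinearity follows the usual auxiliary-regression workflow: tolerance
is 1 - R^2 of a predictor regressed on all the others, VIF its
reciprocal, with conventional concern flags at VIF > 5 or
tolerance < 0.20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from .synthetic import HouseholdDataset, PREDICTOR_IND, PREDICTOR_HH

__all__ = [
    "CollinearityReport",
    "ItemICCFit",
    "indicator_icc",
    "predictor_correlations",
    "collinearity",
]

_VIF_SENTINEL = np.inf


@dataclass
class ItemICCFit:
    item: str
    icc: float
    sigma2_b: float
    thresholds: np.ndarray
    loglik: float
    converged: bool


@dataclass
class CollinearityReport:
    predictors: list[str]
    tolerance: dict[str, float]
    vif: dict[str, float]
    aux_r2: dict[str, float]
    correlations: pd.DataFrame
    flagged: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tolerance": self.tolerance,
            "VIF": self.vif,
            "aux_R2": self.aux_r2,
            "flagged": {p: p in self.flagged for p in self.predictors},
        })


def _gh(n):
    t, w = np.polynomial.hermite.hermgauss(n)
    return t, w / np.sqrt(np.pi)


def indicator_icc(dataset: HouseholdDataset | pd.DataFrame, item: str,
                  n_nodes: int = 15) -> ItemICCFit:
    """Household ICC of one ordinal item on the latent-response scale.

    Fits the random-intercept ordinal probit null model for the item by
    maximum likelihood with Gauss-Hermite quadrature over the household
    effect; cut-points are parameterized as (tau_1, log-increments) to
    stay increasing.
    """
    df = dataset.df if isinstance(dataset, HouseholdDataset) else dataset
    use = df[["household_id", item]].dropna().sort_values(
        "household_id", kind="stable")
    y = use[item].to_numpy()
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValueError(f"degenerate item {item!r}: one observed category")
    hh = use["household_id"].to_numpy()
    _, starts = np.unique(hh, return_index=True)
    starts = np.sort(starts)
    codes = np.searchsorted(cats, y)
    K = len(cats)
    t, w = _gh(n_nodes)

    # start: marginal thresholds, modest household effect
    cum = np.cumsum(np.bincount(codes, minlength=K))[:-1] / len(y)
    tau0 = ndtri(cum)
    x0 = np.concatenate(([tau0[0]], np.log(np.maximum(np.diff(tau0), 1e-3)),
                         [np.log(0.1)]))

    cap = 30.0

    def unpack(x):
        tau = np.concatenate(([x[0]], x[0] + np.cumsum(np.exp(x[1:K - 1]))))
        s_b = np.exp(x[K - 1] / 2)
        return tau, s_b

    def negll(x):
        tau, s_b = unpack(x)
        aug = np.concatenate(([-cap], tau, [cap]))
        u = np.sqrt(2.0) * s_b * t
        z_hi = aug[codes + 1][:, None] - u[None, :]
        z_lo = aug[codes][:, None] - u[None, :]
        P = np.clip(ndtr(z_hi) - ndtr(z_lo), 1e-300, None)
        logA = np.log(P)
        S = np.add.reduceat(logA, starts, axis=0)
        M = S.max(axis=1, keepdims=True)
        ll = (M[:, 0] + np.log((w[None, :] * np.exp(S - M)).sum(axis=1))).sum()
        return -ll

    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6,
                                     "fatol": 1e-8})
    tau, s_b = unpack(res.x)
    sigma2_b = float(s_b**2)
    return ItemICCFit(item=item, icc=sigma2_b / (sigma2_b + 1.0),
                      sigma2_b=sigma2_b, thresholds=tau,
                      loglik=-float(res.fun), converged=bool(res.success))


def predictor_correlations(dataset: HouseholdDataset | pd.DataFrame,
                           predictors: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlations of the predictors on their numeric codings
    (binary as 0/1, ordinal as integer scores)."""
    df = dataset.df if isinstance(dataset, HouseholdDataset) else dataset
    predictors = predictors or (PREDICTOR_IND + PREDICTOR_HH)
    sub = df[predictors].dropna()
    if len(sub) < 2:
        raise ValueError("need at least two complete rows")
    const = [c for c in predictors if sub[c].nunique() == 1]
    if const:
        warnings.warn(f"constant predictors, correlations undefined: {const}",
                      stacklevel=2)
    return sub.astype(float).corr()


def collinearity(dataset: HouseholdDataset | pd.DataFrame,
                 predictors: list[str] | None = None) -> CollinearityReport:
    """Tolerance and VIF per predictor from auxiliary regressions.

    Each predictor is regressed (with intercept) on all the others;
    tolerance = 1 - R^2, VIF = 1/tolerance.  Exact collinearity yields
    an infinite-VIF sentinel and a flag.
    """
    df = dataset.df if isinstance(dataset, HouseholdDataset) else dataset
    predictors = predictors or (PREDICTOR_IND + PREDICTOR_HH)
    sub = df[predictors].dropna().astype(float)
    X = sub.to_numpy()
    n, k = X.shape
    tol, vif, r2 = {}, {}, {}
    flagged = []
    for i, name in enumerate(predictors):
        y = X[:, i]
        if k == 1:
            r2[name], tol[name], vif[name] = 0.0, 1.0, 1.0
            continue
        others = np.column_stack((np.ones(n), np.delete(X, i, axis=1)))
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = float(((y - y.mean())**2).sum())
        if ss_tot == 0:
            r2[name] = np.nan
            tol[name] = np.nan
            vif[name] = _VIF_SENTINEL
            flagged.append(name)
            warnings.warn(f"zero-variance predictor {name!r}", stacklevel=2)
            continue
        r2_i = 1.0 - float((resid**2).sum()) / ss_tot
        r2[name] = r2_i
        t = 1.0 - r2_i
        if t <= 1e-12:
            tol[name] = 0.0
            vif[name] = _VIF_SENTINEL
            flagged.append(name)
            continue
        tol[name] = t
        vif[name] = 1.0 / t
        if vif[name] > 5.0 or t < 0.20:
            flagged.append(name)
    corr = predictor_correlations(sub, predictors)
    return CollinearityReport(predictors=list(predictors), tolerance=tol,
                              vif=vif, aux_r2=r2, correlations=corr,
                              flagged=flagged)
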