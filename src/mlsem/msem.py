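"""Two-level structural model for a latent factor measured by ordinal items.

The individual-level psychiatric-morbidity factor eta_ij is measured by
twelve ordinal indicators through an ordinal-probit measurement model
(loadings invariant across levels) and regressed on individual
predictors; its household-level random intercept eta_j is regressed on
household predictors:

    eta_j^(HH)  = gamma' Z_j + u_j,             u_j ~ N(0, psi_hh)
    eta_ij      = beta' X_ij + eta_j^(HH) + e_ij,  e_ij ~ N(0, psi_ind)
    P(Y_pij = c | eta_ij) = Phi((tau_pc - lambda_p eta_ij)/sqrt(theta_p))
                          - Phi((tau_p,c-1 - lambda_p eta_ij)/sqrt(theta_p))

Estimation is full-information maximum likelihood with nested
Gauss-Hermite quadrature: the outer rule integrates the household
residual u_j, the inner rule each member's residual e_ij.  The gradient
of the log-likelihood is computed analytically alongside the value, so
fits at survey scale (~900 households) take seconds.

By default the measurement parameters (loadings, thresholds, residual
variances) are fixed at their stage-1/DWLS estimates (two-stage mode);
joint estimation of the loadings is available behind a flag.  The
error-covariance structure of the ML backend is diagonal: freed error
covariances belong to the measurement report, not the multilevel fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from .synthetic import HouseholdDataset, ITEM_NAMES, PREDICTOR_IND, PREDICTOR_HH

__all__ = [
    "MSEMSpec",
    "MSEMFit",
    "NullModelFit",
    "MSEMError",
    "DEFAULT_HYPOTHESES",
    "household_loglik",
    "fit_msem",
    "fit_null_model",
    "latent_icc",
    "explained_variance",
    "hypothesis_tests",
    "standardize",
]

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
_TAU_CAP = 30.0  # stands in for +/- infinity on the latent-response scale
_PSI_FLOOR = 1e-8


class MSEMError(RuntimeError):
    pass


#: hypothesized sign of each structural coefficient (directional tests)
DEFAULT_HYPOTHESES = {
    "X_co": +1, "X1_age": -1, "X2_male": -1, "X3_working": -1,
    "X4_history": +1, "X5_householder": +1, "X6_closeness": -1,
    "X7_bmi": +1, "Z1_deprivation": +1, "Z2_closeness": -1,
}


@dataclass
class MSEMSpec:
    """Measurement and structural specification of the two-level model.

    ``thresholds`` is a list of increasing cut-point vectors (one per
    item, on the latent-response scale); ``categories`` the matching
    observed category values per item.  ``theta`` holds the indicator
    residual variances (diagonal).  One loading vector serves both
    levels (cross-level invariance), with the first loading fixed to 1.
    """

    loadings: np.ndarray
    thresholds: list
    theta: np.ndarray
    categories: list | None = None
    item_names: list[str] = field(default_factory=lambda: list(ITEM_NAMES))
    predictors_ind: list[str] = field(default_factory=lambda: list(PREDICTOR_IND))
    predictors_hh: list[str] = field(default_factory=lambda: list(PREDICTOR_HH))
    #: center predictors and estimate a free latent intercept.  Centering
    #: keeps the optimization well conditioned; the intercept absorbs
    #: whatever latent mean the fixed thresholds do not already carry
    #: (zero for stage-1 marginal thresholds, the structural mean for
    #: generator-scale thresholds).
    center: bool = True
    estimate_loadings: bool = False

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.isclose(self.loadings[0], 1.0):
            raise ValueError("identification requires the first loading fixed to 1")
        if np.any(self.theta <= 0):
            raise ValueError("theta must hold positive residual variances")
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        for t in self.thresholds:
            if np.any(np.diff(t) <= 0):
                raise ValueError("thresholds must be strictly increasing per item")
        if self.categories is None:
            self.categories = [np.arange(1, len(t) + 2) for t in self.thresholds]

    @classmethod
    def from_cfa(cls, cfa_fit, polymat, theta_floor: float = 0.05, **kwargs):
        """Measurement part from a DWLS fit: loadings from the fit,
        thresholds from stage 1, residual variances from the delta
        convention theta_p = 1 - lambda_p^2 psi (floored with a warning
        in Heywood territory)."""
        lam = cfa_fit.loadings
        theta = 1.0 - lam**2 * cfa_fit.psi
        if np.any(theta < theta_floor):
            warnings.warn("residual variances floored; near-Heywood loadings",
                          stacklevel=2)
            theta = np.maximum(theta, theta_floor)
        items = polymat.items
        thresholds = [polymat.thresholds[it] for it in items]
        categories = [polymat.thresholds.categories[it] for it in items]
        return cls(loadings=lam, thresholds=thresholds, theta=theta,
                   categories=categories, item_names=list(items), **kwargs)

    @classmethod
    def from_truth(cls, ground_truth: dict, **kwargs):
        """Measurement part fixed at a generator's stored parameters."""
        lam = np.asarray(ground_truth["loadings"], dtype=float)
        tau = np.asarray(ground_truth["thresholds"], dtype=float)
        theta = np.asarray(ground_truth["theta_diag"], dtype=float)
        return cls(loadings=lam, thresholds=list(tau), theta=theta, **kwargs)


@dataclass
class MSEMFit:
    spec: MSEMSpec
    param_names: list[str]
    beta: np.ndarray
    gamma: np.ndarray
    intercept: float
    psi_ind: float
    psi_hh: float
    loadings: np.ndarray
    se: dict
    acov: np.ndarray | None
    loglik: float
    aic: float
    bic: float
    n_params: int
    n_individuals: int
    n_households: int
    converged: bool
    n_iter: int
    boundary: list[str]
    predictor_means: dict

    def estimates(self) -> dict:
        out = dict(zip(self.spec.predictors_ind, self.beta))
        out.update(zip(self.spec.predictors_hh, self.gamma))
        out["psi_ind"] = self.psi_ind
        out["psi_hh"] = self.psi_hh
        return out

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        est = self.estimates()[name]
        se = self.se.get(name, np.nan)
        return est - z * se, est + z * se


@dataclass
class NullModelFit:
    psi_ind: float
    psi_hh: float
    fit: MSEMFit


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _prepare(df: pd.DataFrame, spec: MSEMSpec):
    """Sort by household, map item codes to cut-point bins, build arrays."""
    cols = (["household_id"] + spec.item_names + spec.predictors_ind
            + spec.predictors_hh)
    use = df[cols].dropna()
    if use.empty:
        raise MSEMError("no complete cases available for the model variables")
    use = use.sort_values("household_id", kind="stable").reset_index(drop=True)
    n = len(use)
    p = len(spec.item_names)

    tau_lo = np.empty((n, p))
    tau_hi = np.empty((n, p))
    for j, item in enumerate(spec.item_names):
        cats = np.asarray(spec.categories[j])
        aug = np.concatenate(([-_TAU_CAP],
                              np.clip(spec.thresholds[j], -_TAU_CAP, _TAU_CAP),
                              [_TAU_CAP]))
        codes = use[item].to_numpy()
        idx = np.searchsorted(cats, codes)
        bad = (idx >= len(cats)) | (cats[np.minimum(idx, len(cats) - 1)] != codes)
        if bad.any():
            raise MSEMError(
                f"item {item}: codes {sorted(set(codes[bad]))} not among "
                f"the specified categories {list(cats)}")
        tau_lo[:, j] = aug[idx]
        tau_hi[:, j] = aug[idx + 1]

    X = use[spec.predictors_ind].to_numpy(dtype=float)
    Z = use[spec.predictors_hh].to_numpy(dtype=float)
    means = {}
    if spec.center:
        for k, c in enumerate(spec.predictors_ind):
            means[c] = float(X[:, k].mean())
            X[:, k] -= means[c]
        for k, c in enumerate(spec.predictors_hh):
            means[c] = float(Z[:, k].mean())
            Z[:, k] -= means[c]

    hh = use["household_id"].to_numpy()
    _, starts = np.unique(hh, return_index=True)
    return use, X, Z, tau_lo, tau_hi, np.sort(starts), means


def _gh_rule(n_nodes: int):
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    return t, w / np.sqrt(np.pi)


# ---------------------------------------------------------------------------
# likelihood core
# ---------------------------------------------------------------------------

def _loglik_core(m, s_ind, s_hh, lam, sd_theta, tau_lo, tau_hi, starts,
                 nodes_out, nodes_in, want_grad=True, want_lam_grad=False):
    """Log-likelihood (and gradients) of all households.

    Returns ``(ll, d_m, d_s_ind, d_s_hh, d_lam)`` where ``d_m`` is the
    per-individual gradient with respect to the structural linear
    predictor.  Gradient entries are None when not requested.
    """
    t_out, w_out = nodes_out
    t_in, w_in = nodes_in
    n, p = tau_lo.shape
    u = np.sqrt(2.0) * s_hh * t_out            # (K,)
    e = np.sqrt(2.0) * s_ind * t_in            # (L,)
    eta = m[:, None, None] + u[None, :, None] + e[None, None, :]

    logg = np.zeros_like(eta)
    d_eta = np.zeros_like(eta) if want_grad else None
    lam_terms = [] if want_lam_grad else None
    for j in range(p):
        z_hi = (tau_hi[:, j, None, None] - lam[j] * eta) / sd_theta[j]
        z_lo = (tau_lo[:, j, None, None] - lam[j] * eta) / sd_theta[j]
        P = np.clip(ndtr(z_hi) - ndtr(z_lo), 1e-300, None)
        logg += np.log(P)
        if want_grad or want_lam_grad:
            pdf_diff = (np.exp(-0.5 * z_hi**2) - np.exp(-0.5 * z_lo**2)) \
                * _INV_SQRT_2PI
            term = -pdf_diff / (P * sd_theta[j])
            if want_grad:
                d_eta += lam[j] * term
            if want_lam_grad:
                lam_terms.append(eta * term)

    M = logg.max(axis=2, keepdims=True)
    G = w_in[None, None, :] * np.exp(logg - M)
    A = G.sum(axis=2)                           # (n, K)
    logA = M[:, :, 0] + np.log(A)
    S = np.add.reduceat(logA, starts, axis=0)   # (J, K)
    lw = np.log(w_out)[None, :] + S
    Mh = lw.max(axis=1, keepdims=True)
    L = np.exp(lw - Mh)
    ll_j = Mh[:, 0] + np.log(L.sum(axis=1))
    ll = float(ll_j.sum())
    if not want_grad and not want_lam_grad:
        return ll, None, None, None, None

    pi = L / L.sum(axis=1, keepdims=True)       # (J, K) posterior outer weights
    sizes = np.diff(np.concatenate((starts, [n])))
    pi_i = np.repeat(pi, sizes, axis=0)         # (n, K)

    d_m = d_s_ind = d_s_hh = d_lam = None
    if want_grad:
        Dbar = (G * d_eta).sum(axis=2) / A
        Ebar = (G * d_eta * t_in[None, None, :]).sum(axis=2) / A
        d_m = (pi_i * Dbar).sum(axis=1)
        d_s_hh = float(np.sqrt(2.0) * (pi_i * Dbar * t_out[None, :]).sum())
        d_s_ind = float(np.sqrt(2.0) * (pi_i * Ebar).sum())
    if want_lam_grad:
        d_lam = np.empty(p)
        for j in range(p):
            Lbar = (G * lam_terms[j]).sum(axis=2) / A
            d_lam[j] = float((pi_i * Lbar).sum())
    return ll, d_m, d_s_ind, d_s_hh, d_lam


def household_loglik(block: pd.DataFrame, spec: MSEMSpec, beta, gamma,
                     psi_ind: float, psi_hh: float, n_nodes: int = 15) -> float:
    """Log-probability of one household's complete-case block.

    Nested quadrature: the outer rule integrates the household residual,
    the inner rule each member's individual residual.  At least 7 nodes
    are required per dimension.
    """
    if n_nodes < 7:
        raise ValueError("Gauss-Hermite rule needs at least 7 nodes")
    if block[spec.item_names + spec.predictors_ind + spec.predictors_hh] \
            .isna().any().any():
        raise MSEMError("household block must be listwise complete")
    spec_nc = MSEMSpec(loadings=spec.loadings, thresholds=spec.thresholds,
                       theta=spec.theta, categories=spec.categories,
                       item_names=spec.item_names,
                       predictors_ind=spec.predictors_ind,
                       predictors_hh=spec.predictors_hh, center=False)
    _, X, Z, tau_lo, tau_hi, starts, _ = _prepare(block, spec_nc)
    m = X @ np.asarray(beta, float) + Z @ np.asarray(gamma, float)
    rule = _gh_rule(n_nodes)
    ll, *_ = _loglik_core(m, np.sqrt(psi_ind), np.sqrt(psi_hh),
                          spec.loadings, np.sqrt(spec.theta), tau_lo, tau_hi,
                          starts, rule, rule, want_grad=False)
    if not np.isfinite(ll):
        hh = block["household_id"].iloc[0]
        raise MSEMError(f"non-finite log-likelihood for household {hh!r}")
    return ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_msem(dataset: HouseholdDataset | pd.DataFrame, spec: MSEMSpec,
             n_nodes: int = 15, structural: bool = True,
             start: np.ndarray | None = None, max_iter: int = 500,
             compute_se: bool = True) -> MSEMFit:
    """Maximize the full-information likelihood of the two-level model.

    ``structural=False`` constrains beta = gamma = 0 (the null model) so
    only the variance components are estimated.  Variance components are
    optimized on the log scale to enforce non-negativity; estimates
    below 1e-6 are flagged as boundary solutions.  Standard errors come
    from the numerical Hessian of the log-likelihood at the optimum.
    """
    df = dataset.df if isinstance(dataset, HouseholdDataset) else dataset
    use, X, Z, tau_lo, tau_hi, starts, means = _prepare(df, spec)
    n = len(use)
    J = len(starts)
    rule = _gh_rule(n_nodes)
    lam_free = spec.estimate_loadings
    p = len(spec.item_names)
    sd_theta = np.sqrt(spec.theta)

    # design matrix of the latent linear predictor; a free intercept
    # accompanies centering (see MSEMSpec.center) so that the latent
    # mean left over by the fixed thresholds is absorbed — in the null
    # model too, where it stands in for the freely estimated measurement
    # location of a one-stage fit
    with_icpt = spec.center
    blocks = [np.ones((n, 1))] if with_icpt else []
    dnames = ["intercept"] if with_icpt else []
    if structural:
        blocks += [X, Z]
        dnames += spec.predictors_ind + spec.predictors_hh
    D = np.hstack(blocks) if blocks else np.zeros((n, 0))
    kd = D.shape[1]
    # internal column scaling keeps the optimization well conditioned
    col_scale = np.array([max(D[:, i].std(), 1e-12) if D[:, i].std() > 0
                          else 1.0 for i in range(kd)])
    Ds = D / col_scale

    names = dnames + ["psi_ind", "psi_hh"]
    if lam_free:
        names += [f"lambda_{it}" for it in spec.item_names[1:]]

    def split(params):
        coef = params[:kd]
        q_ind, q_hh = params[kd], params[kd + 1]
        lam = (np.concatenate(([1.0], params[kd + 2:]))
               if lam_free else spec.loadings)
        return coef, q_ind, q_hh, lam

    def negll_grad(params):
        coef, q_ind, q_hh, lam = split(params)
        s_ind, s_hh = np.exp(q_ind / 2), np.exp(q_hh / 2)
        m = Ds @ coef if kd else np.zeros(n)
        ll, d_m, d_s_ind, d_s_hh, d_lam = _loglik_core(
            m, s_ind, s_hh, lam, sd_theta, tau_lo, tau_hi, starts,
            rule, rule, want_grad=True, want_lam_grad=lam_free)
        if not np.isfinite(ll):
            raise MSEMError("non-finite log-likelihood during optimization")
        g = [Ds.T @ d_m] if kd else []
        g.append([d_s_ind * s_ind / 2, d_s_hh * s_hh / 2])
        if lam_free:
            g.append(d_lam[1:])
        grad = np.concatenate([np.atleast_1d(np.asarray(x)) for x in g])
        return -ll, -grad

    k = kd + 2 + (p - 1) * lam_free
    if start is None:
        start = np.zeros(k)
        start[kd] = np.log(0.02)
        start[kd + 1] = np.log(0.01)
        if lam_free:
            start[kd + 2:] = spec.loadings[1:]
    bounds = [(None, None)] * kd \
        + [(np.log(_PSI_FLOOR), np.log(50.0))] * 2 \
        + [(None, None)] * ((p - 1) * lam_free)
    res = optimize.minimize(negll_grad, start, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-11,
                                     "gtol": 1e-6})
    if not res.success and "ABNORMAL" in str(res.message):
        raise MSEMError(f"MSEM optimization failed: {res.message}; "
                        f"trace: {res.nit} iterations, |g|={np.abs(res.jac).max():.2e}")
    coef_s, q_ind, q_hh, lam = split(res.x)
    coef = coef_s / col_scale
    psi_ind, psi_hh = float(np.exp(q_ind)), float(np.exp(q_hh))
    ll = -float(res.fun)

    icpt = float(coef[0]) if with_icpt else 0.0
    off = 1 if with_icpt else 0
    if structural:
        beta = coef[off:off + len(spec.predictors_ind)]
        gamma = coef[off + len(spec.predictors_ind):kd]
    else:
        beta = np.zeros(len(spec.predictors_ind))
        gamma = np.zeros(len(spec.predictors_hh))

    boundary = [nm for nm, v in (("psi_ind", psi_ind), ("psi_hh", psi_hh))
                if v < 1e-6]
    se: dict = {}
    acov = None
    if compute_se:
        H = _num_hessian(negll_grad, res.x)
        # back-transform: internal scaling for coefficients, delta method
        # from the log scale for the variance components
        tr = np.ones(k)
        tr[:kd] = 1.0 / col_scale
        tr[kd] = psi_ind
        tr[kd + 1] = psi_hh
        try:
            cov_int = np.linalg.inv(H)
            acov = cov_int * np.outer(tr, tr)
            sdiag = np.sqrt(np.clip(np.diag(acov), 0.0, None))
            se = dict(zip(names, sdiag))
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian; standard errors unavailable",
                          stacklevel=2)
            se = {nm: np.nan for nm in names}

    return MSEMFit(spec=spec, param_names=names, beta=np.asarray(beta),
                   gamma=np.asarray(gamma), intercept=icpt,
                   psi_ind=psi_ind, psi_hh=psi_hh,
                   loadings=np.asarray(lam), se=se, acov=acov, loglik=ll,
                   aic=-2 * ll + 2 * k, bic=-2 * ll + k * np.log(n),
                   n_params=k, n_individuals=n, n_households=J,
                   converged=bool(res.success), n_iter=int(res.nit),
                   boundary=boundary, predictor_means=means)


def _num_hessian(fun_grad, x, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        h = step * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        gp = fun_grad(xp)[1]
        gm = fun_grad(xm)[1]
        H[i] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def fit_null_model(dataset, spec: MSEMSpec, n_nodes: int = 15,
                   **kwargs) -> NullModelFit:
    """Structural-baseline model: measurement part as specified, all
    structural coefficients constrained to zero; returns the two latent
    variance components."""
    fit = fit_msem(dataset, spec, n_nodes=n_nodes, structural=False, **kwargs)
    return NullModelFit(psi_ind=fit.psi_ind, psi_hh=fit.psi_hh, fit=fit)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def latent_icc(psi_hh: float, psi_ind: float) -> float:
    """Proportion of latent-factor variance between households."""
    if psi_hh < 0 or psi_ind < 0:
        raise ValueError("variance components must be non-negative")
    tot = psi_hh + psi_ind
    if tot == 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return psi_hh / tot


def explained_variance(psi_null: float, psi_full: float) -> float:
    """Proportional reduction in a latent variance component relative to
    the null model: (psi_null - psi_full) / psi_null."""
    if psi_null <= 0:
        raise ValueError("psi_null must be positive")
    out = (psi_null - psi_full) / psi_null
    if out < 0:
        warnings.warn("explained variance is negative (full-model variance "
                      "exceeds the null-model variance)", stacklevel=2)
    return out


def hypothesis_tests(fit: MSEMFit, directions: dict | None = None
                     ) -> pd.DataFrame:
    """Directional z-tests of the structural coefficients.

    One-sided p-values in the hypothesized direction with significance
    tiers a (<0.01), b (<0.05), c (<0.1), ns; two-sided p-values are
    reported alongside.
    """
    directions = DEFAULT_HYPOTHESES if directions is None else directions
    est = fit.estimates()
    rows = []
    for name, sign in directions.items():
        if name not in est:
            continue
        e = est[name]
        s = fit.se.get(name, np.nan)
        if not np.isfinite(s) or s == 0:
            rows.append({"parameter": name, "estimate": e, "se": s,
                         "z": np.nan, "p_one_sided": np.nan,
                         "p_two_sided": np.nan, "tier": "undefined"})
            continue
        z = e / s
        p1 = float(ndtr(-sign * z))
        p2 = 2 * float(ndtr(-abs(z)))
        tier = "a" if p1 < 0.01 else "b" if p1 < 0.05 else \
               "c" if p1 < 0.1 else "ns"
        rows.append({"parameter": name, "estimate": e, "se": s, "z": z,
                     "p_one_sided": p1, "p_two_sided": p2, "tier": tier})
    return pd.DataFrame(rows)


def standardize(fit: MSEMFit, dataset: HouseholdDataset | pd.DataFrame
                ) -> dict:
    """Standardized coefficients and loadings.

    beta_std = beta * SD(X) / SD(eta) with SD(eta) from the model-implied
    total latent variance (structural part plus both residual
    components); lambda_std = lambda_p * SD(eta) / SD(Ystar_p).
    """
    df = dataset.df if isinstance(dataset, HouseholdDataset) else dataset
    use = df[fit.spec.predictors_ind + fit.spec.predictors_hh].dropna()
    X = use[fit.spec.predictors_ind].to_numpy(dtype=float)
    Z = use[fit.spec.predictors_hh].to_numpy(dtype=float)
    lin = X @ fit.beta + Z @ fit.gamma
    var_eta = float(np.var(lin)) + fit.psi_ind + fit.psi_hh
    sd_eta = np.sqrt(var_eta)

    out = {"sd_eta": sd_eta, "beta": {}, "gamma": {}, "loadings": {}}
    for k, name in enumerate(fit.spec.predictors_ind):
        sd_x = float(X[:, k].std())
        if sd_x == 0:
            warnings.warn(f"zero-variance predictor {name!r}", stacklevel=2)
            out["beta"][name] = np.nan
        else:
            out["beta"][name] = float(fit.beta[k] * sd_x / sd_eta)
    for k, name in enumerate(fit.spec.predictors_hh):
        sd_z = float(Z[:, k].std())
        if sd_z == 0:
            warnings.warn(f"zero-variance predictor {name!r}", stacklevel=2)
            out["gamma"][name] = np.nan
        else:
            out["gamma"][name] = float(fit.gamma[k] * sd_z / sd_eta)
    for p, item in enumerate(fit.spec.item_names):
        sd_y = np.sqrt(fit.loadings[p]**2 * var_eta + fit.spec.theta[p])
        out["loadings"][item] = float(fit.loadings[p] * sd_eta / sd_y)
    return out
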