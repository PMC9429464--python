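"""One-factor measurement model for ordinal items, fit by DWLS.

The 12 item latent responses load on a single psychiatric-morbidity
factor.  With thresholds fixed at their stage-1 values and the latent
responses standardized (delta convention, unit diagonal), the free
parameters are the loadings (first fixed to 1), the factor variance and
any freed error covariances.  The discrepancy

    F = (s - sigma(theta))' W^{-1} (s - sigma(theta))

is minimized, where s stacks the 66 sample polychoric correlations and W
is the diagonal of their asymptotic variances.  chi2 = (n - 1) * F_hat.

Also provides the fit indices used for ordinal CFA (CFI, TLI, RMSEA and
a W-metric GFI), score-test modification indices for fixed-to-zero error
covariances, and the stepwise procedure that frees the largest such
covariance while fit improves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .polychoric import PolychoricMatrix

__all__ = [
    "ModelSpec",
    "CFAFit",
    "FitIndices",
    "CFAError",
    "implied_correlations",
    "fit_dwls",
    "fit_baseline",
    "fit_indices",
    "modification_indices",
    "stepwise_free_covariances",
]


class CFAError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Loading pattern and free error covariances of the one-factor model.

    The first loading is fixed to 1 to set the factor scale; the factor
    variance is free; thresholds are fixed at stage-1 values and play no
    role in the correlation-structure discrepancy.
    """

    n_items: int = 12
    free_covs: list[tuple[int, int]] = field(default_factory=list)
    item_names: list[str] | None = None

    def __post_init__(self):
        self.free_covs = [tuple(sorted(p)) for p in self.free_covs]
        if len(set(self.free_covs)) != len(self.free_covs):
            raise ValueError("duplicate free covariance pairs")
        for a, b in self.free_covs:
            if not (0 <= a < b < self.n_items):
                raise ValueError(f"invalid covariance pair ({a}, {b})")

    @property
    def n_free(self) -> int:
        # loadings 2..p, factor variance, freed covariances
        return (self.n_items - 1) + 1 + len(self.free_covs)

    @property
    def n_statistics(self) -> int:
        return self.n_items * (self.n_items - 1) // 2

    @property
    def df(self) -> int:
        return self.n_statistics - self.n_free

    def with_freed(self, pair: tuple[int, int]) -> "ModelSpec":
        return ModelSpec(self.n_items, self.free_covs + [tuple(sorted(pair))],
                         self.item_names)


@dataclass
class CFAFit:
    spec: ModelSpec
    loadings: np.ndarray          # length p, first entry 1
    psi: float                    # factor variance
    error_covs: dict[tuple[int, int], float]
    se_loadings: np.ndarray       # NaN for the fixed first loading
    se_psi: float
    se_error_covs: dict[tuple[int, int], float]
    discrepancy: float
    chi2: float
    df: int
    n: int
    converged: bool
    n_iter: int
    heywood: bool
    residuals: np.ndarray         # s - sigma_hat, off-diagonal order (i<j)

    @property
    def standardized_loadings(self) -> np.ndarray:
        """Loadings on the correlation scale: lambda_p * sqrt(psi)."""
        return self.loadings * np.sqrt(max(self.psi, 0.0))


@dataclass
class FitIndices:
    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    cfi: float
    tli: float | None
    rmsea: float | None
    gfi: float


# ---------------------------------------------------------------------------

def _offdiag_indices(p: int):
    return np.triu_indices(p, k=1)


def implied_correlations(loadings, psi, error_covs, n_items: int = 12) -> np.ndarray:
    """Model-implied correlation matrix under the delta convention.

    Off-diagonals are lambda_p lambda_q psi + theta_pq; the diagonal is
    fixed to 1.  Warns if the implied matrix is not PSD.
    """
    lam = np.asarray(loadings, dtype=float)
    sigma = psi * np.outer(lam, lam)
    for (a, b), v in error_covs.items():
        sigma[a, b] += v
        sigma[b, a] += v
    np.fill_diagonal(sigma, 1.0)
    if np.linalg.eigvalsh(sigma).min() < -1e-8:
        warnings.warn("model-implied correlation matrix is not positive "
                      "semi-definite", stacklevel=2)
    return sigma


def _unpack(params: np.ndarray, spec: ModelSpec):
    p = spec.n_items
    lam = np.concatenate(([1.0], params[:p - 1]))
    psi = params[p - 1]
    covs = {pair: params[p + i] for i, pair in enumerate(spec.free_covs)}
    return lam, psi, covs


def _sigma_and_jac(params: np.ndarray, spec: ModelSpec):
    """Off-diagonal implied correlations and their Jacobian."""
    p = spec.n_items
    lam, psi, covs = _unpack(params, spec)
    iu, ju = _offdiag_indices(p)
    sigma = psi * lam[iu] * lam[ju]
    m = len(iu)
    jac = np.zeros((m, spec.n_free))
    # d/d lambda_r (r = 1..p-1, parameter index r-1)
    for col, r in enumerate(range(1, p)):
        jac[:, col] = psi * (np.where(iu == r, lam[ju], 0.0)
                             + np.where(ju == r, lam[iu], 0.0))
    jac[:, p - 1] = lam[iu] * lam[ju]
    pair_pos = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(iu, ju))}
    for i, pair in enumerate(spec.free_covs):
        k = pair_pos[pair]
        sigma[k] += covs[pair]
        jac[k, p + i] = 1.0
    return sigma, jac, pair_pos


def _sample_vectors(polymat: PolychoricMatrix):
    p = len(polymat.items)
    iu, ju = _offdiag_indices(p)
    s = polymat.rho[iu, ju]
    w = polymat.avar[iu, ju]
    w = np.where(np.isfinite(w) & (w > 0), w, np.nanmax(w[np.isfinite(w)]))
    return s, w


def _start_values(polymat: PolychoricMatrix, spec: ModelSpec) -> np.ndarray:
    """First-principal-component start for loadings and factor variance."""
    vals, vecs = np.linalg.eigh(polymat.rho)
    v = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-3))
    if v[0] < 0:
        v = -v
    v[0] = max(v[0], 0.05)
    psi0 = float(v[0] ** 2)
    lam0 = v / v[0]
    start = np.concatenate((lam0[1:], [psi0], np.zeros(len(spec.free_covs))))
    return start


def fit_dwls(polymat: PolychoricMatrix, spec: ModelSpec,
             n: int | None = None, start: np.ndarray | None = None,
             max_iter: int = 500) -> CFAFit:
    """Minimize the diagonally weighted least-squares discrepancy.

    ``n`` defaults to the smallest pairwise sample size in ``polymat``.
    Standard errors come from the sandwich form, which with a diagonal
    weight matrix equal to the asymptotic variances of s reduces to
    (Delta' W^{-1} Delta)^{-1} / (n - 1).
    """
    if spec.df < 0:
        raise CFAError(f"model not identified: df = {spec.df} < 0")
    n = n if n is not None else polymat.n
    s, w = _sample_vectors(polymat)
    sw = np.sqrt(w)

    def resid(params):
        sigma, _, _ = _sigma_and_jac(params, spec)
        return (s - sigma) / sw

    def jac(params):
        _, J, _ = _sigma_and_jac(params, spec)
        return -J / sw[:, None]

    x0 = start if start is not None else _start_values(polymat, spec)
    res = optimize.least_squares(resid, x0, jac=jac, method="lm",
                                 max_nfev=max_iter, xtol=1e-12, ftol=1e-12)
    if not (res.status > 0):
        raise CFAError(f"DWLS did not converge: {res.message} "
                       f"({res.nfev} evaluations)")
    lam, psi, covs = _unpack(res.x, spec)
    F = float(2.0 * res.cost)
    chi2 = max((n - 1) * F, 0.0)

    # sandwich SEs; Gamma approximated by W (only diagonal avar estimated)
    _, J, _ = _sigma_and_jac(res.x, spec)
    Jw = J / sw[:, None]
    try:
        acov = np.linalg.inv(Jw.T @ Jw) / (n - 1)
        se = np.sqrt(np.clip(np.diag(acov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(spec.n_free, np.nan)
    p = spec.n_items
    se_lam = np.concatenate(([np.nan], se[:p - 1]))
    se_covs = {pair: float(se[p + i]) for i, pair in enumerate(spec.free_covs)}

    std = lam * np.sqrt(max(psi, 0.0))
    heywood = bool(np.any(np.abs(std) > 1.0))
    if heywood:
        warnings.warn("Heywood case: a standardized loading exceeds 1",
                      stacklevel=2)
    sigma_hat, _, _ = _sigma_and_jac(res.x, spec)
    return CFAFit(spec=spec, loadings=lam, psi=float(psi), error_covs=covs,
                  se_loadings=se_lam, se_psi=float(se[p - 1]),
                  se_error_covs=se_covs, discrepancy=F, chi2=chi2,
                  df=spec.df, n=n, converged=True, n_iter=int(res.nfev),
                  heywood=heywood, residuals=s - sigma_hat)


def fit_baseline(polymat: PolychoricMatrix, n: int | None = None) -> CFAFit:
    """Independence model: zero loadings and covariances, implied = I."""
    n = n if n is not None else polymat.n
    s, w = _sample_vectors(polymat)
    F = float(np.sum(s**2 / w))
    p = len(polymat.items)
    spec = ModelSpec(n_items=p)
    return CFAFit(spec=spec, loadings=np.zeros(p), psi=0.0, error_covs={},
                  se_loadings=np.full(p, np.nan), se_psi=np.nan,
                  se_error_covs={}, discrepancy=F, chi2=(n - 1) * F,
                  df=p * (p - 1) // 2, n=n, converged=True, n_iter=0,
                  heywood=False, residuals=s)


def fit_indices(fit: CFAFit, baseline: CFAFit, n: int | None = None) -> FitIndices:
    """CFI, TLI, RMSEA and W-metric GFI from model and baseline chi-squares.

    With df = 0 the RMSEA and TLI are undefined and reported as None.
    GFI is 1 - F_hat / F_baseline, i.e. the weighted residual sum of
    squares relative to the weighted total (the baseline discrepancy).
    """
    n = n if n is not None else fit.n
    chi2, df = fit.chi2, fit.df
    chi2_b, df_b = baseline.chi2, baseline.df
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0
    if df > 0 and df_b > 0 and chi2_b / df_b != 1.0:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = None
    rmsea = (np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
             if df > 0 else None)
    gfi = 1.0 - fit.discrepancy / baseline.discrepancy \
        if baseline.discrepancy > 0 else 1.0
    return FitIndices(chi2=chi2, df=df, baseline_chi2=chi2_b, baseline_df=df_b,
                      cfi=float(cfi), tli=None if tli is None else float(tli),
                      rmsea=None if rmsea is None else float(rmsea),
                      gfi=float(gfi))


def modification_indices(fit: CFAFit, polymat: PolychoricMatrix
                         ) -> list[tuple[tuple[int, int], float, float]]:
    """Score (Lagrange-multiplier) statistics for fixed-to-zero error
    covariances.

    For each candidate pair, the expected drop in chi2 if that covariance
    were freed, obtained from the Gauss-Newton quadratic model of the
    weighted discrepancy at the optimum, together with the expected
    parameter change.  Sorted by MI, descending.
    """
    spec = fit.spec
    s, w = _sample_vectors(polymat)
    sw = np.sqrt(w)
    p = spec.n_items
    params = np.concatenate((fit.loadings[1:], [fit.psi],
                             [fit.error_covs[q] for q in spec.free_covs]))
    _, J, pair_pos = _sigma_and_jac(params, spec)
    Jw = J / sw[:, None]
    r = fit.residuals / sw
    Q, _ = np.linalg.qr(Jw)
    rM = r - Q @ (Q.T @ r)

    out = []
    free = set(spec.free_covs)
    for pair, k in pair_pos.items():
        if pair in free:
            continue
        d = np.zeros(len(r))
        d[k] = 1.0 / sw[k]
        dM = d - Q @ (Q.T @ d)
        dd = float(d @ dM)
        if dd < 1e-12:
            warnings.warn(f"singular information for pair {pair}; skipped",
                          stacklevel=2)
            continue
        g = float(d @ rM)
        mi = (fit.n - 1) * g * g / dd
        epc = g / dd
        out.append((pair, float(max(mi, 0.0)), float(epc)))
    out.sort(key=lambda t: -t[1])
    return out


def stepwise_free_covariances(polymat: PolychoricMatrix, spec: ModelSpec,
                              n: int | None = None, mi_threshold: float = 3.84,
                              max_steps: int | None = None
                              ) -> tuple[ModelSpec, list[dict], CFAFit]:
    """Free the largest-MI error covariance while fit improves.

    The default rule frees covariances while the largest modification
    index exceeds the chi2(1) 5% critical value 3.84 and degrees of
    freedom remain.  Returns the final spec, an audit trail (one record
    per step with the pair, MI, and chi2 before/after) and the final fit.
    """
    n = n if n is not None else polymat.n
    trail: list[dict] = []
    fit = fit_dwls(polymat, spec, n=n)
    step = 0
    while True:
        if fit.df <= 0:
            trail.append({"step": step, "note": "saturated (df = 0); stopping"})
            break
        if max_steps is not None and step >= max_steps:
            break
        mis = modification_indices(fit, polymat)
        if not mis or mis[0][1] <= mi_threshold:
            break
        pair, mi, epc = mis[0]
        new_spec = fit.spec.with_freed(pair)
        if new_spec.df < 0:
            break
        new_fit = fit_dwls(polymat, new_spec, n=n)
        trail.append({
            "step": step + 1, "freed": pair, "mi": mi, "epc": epc,
            "chi2_before": fit.chi2, "chi2_after": new_fit.chi2,
            "df_after": new_fit.df,
        })
        fit = new_fit
        step += 1
    return fit.spec, trail, fit
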