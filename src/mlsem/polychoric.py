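"""Thresholds and polychoric correlations for ordinal items.

Stage-1 statistics for limited-information SEM with ordinal indicators:
each item is treated as a discretized standard-normal latent response cut
at estimated thresholds; each pair of items gets a two-step maximum
likelihood estimate of the latent-response (polychoric) correlation with
an asymptotic variance that later serves as a DWLS weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri, owens_t

__all__ = [
    "ThresholdSet",
    "PolychoricMatrix",
    "PolychoricError",
    "bvn_cdf",
    "estimate_thresholds",
    "polychoric_pair",
    "polychoric_matrix",
]

#: absolute bound applied to every polychoric estimate so that downstream
#: weight matrices stay finite
RHO_CLIP = 0.995

# beyond |z| = 8.5 the univariate normal tail is < 1e-17, so infinite
# thresholds can be replaced by this sentinel inside Owen's formula
_Z_CAP = 8.5


class PolychoricError(RuntimeError):
    """Raised when a threshold or correlation estimate is not computable."""


# ---------------------------------------------------------------------------
# bivariate normal CDF (Owen's T formula)
# ---------------------------------------------------------------------------

def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorized over ``h`` and ``k`` (``rho`` scalar), using Owen's T
    function.  Accurate to ~1e-15; infinite bounds are supported.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)

    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            return ndtr(np.minimum(h, k))
        return np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0)

    h = np.clip(h, -_Z_CAP, _Z_CAP)
    k = np.clip(k, -_Z_CAP, _Z_CAP)
    # Owen's formula divides by h and k; nudge exact zeros off the axis
    # (the result is continuous there, error ~1e-12 per unit slope).
    eps = 1e-12
    h = np.where(np.abs(h) < eps, eps, h)
    k = np.where(np.abs(k) < eps, eps, k)

    denom = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    beta = np.where(h * k > 0, 0.0, 0.5)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    return np.clip(out, 0.0, 1.0)


def _cell_probs(tau_r: np.ndarray, tau_c: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities for a table with given cut-points."""
    a = np.concatenate(([-np.inf], tau_r, [np.inf]))
    b = np.concatenate(([-np.inf], tau_c, [np.inf]))
    grid = bvn_cdf(a[:, None], b[None, :], rho)
    return np.diff(np.diff(grid, axis=0), axis=1)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSet:
    """Standard-normal cut-points per item, strictly increasing.

    ``categories`` records the observed category values per item in
    ascending order (length = number of cut-points + 1), so that codes
    can be mapped back onto the cut-points after any collapsing.
    """

    taus: dict[str, np.ndarray] = field(default_factory=dict)
    categories: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, item: str) -> np.ndarray:
        return self.taus[item]

    def items(self):
        return self.taus.items()

    def to_dict(self) -> dict[str, list[float]]:
        return {k: list(map(float, v)) for k, v in self.taus.items()}


def estimate_thresholds(counts, item: str | None = None) -> np.ndarray:
    """Thresholds from category counts of one ordinal item.

    tau_c is the standard-normal quantile of the cumulative proportion
    through category c.  Empty categories are collapsed into their
    neighbour (with a warning), so the returned vector is strictly
    increasing and finite.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or np.any(counts < 0):
        raise ValueError("counts must be a non-negative 1-d vector")
    n = counts.sum()
    label = item or "item"
    if (counts > 0).sum() < 2:
        raise PolychoricError(f"degenerate item {label!r}: all observations in one category")
    if (counts == 0).any():
        warnings.warn(f"empty categories collapsed for {label!r}", stacklevel=2)
    cum = np.cumsum(counts)[:-1] / n
    cum = np.unique(cum[(cum > 0) & (cum < 1)])
    return ndtri(cum)


# ---------------------------------------------------------------------------
# pairwise estimation
# ---------------------------------------------------------------------------

def _collapse_table(table: np.ndarray) -> np.ndarray:
    """Drop zero-margin rows/columns (empty categories carry no likelihood)."""
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return table


def polychoric_pair(
    table,
    thresholds: tuple[np.ndarray, np.ndarray] | None = None,
    names: tuple[str, str] = ("row", "col"),
) -> tuple[float, float]:
    """Two-step ML polychoric correlation from a two-way contingency table.

    Thresholds are fixed at the margin-implied values (unless supplied);
    rho maximizes the multinomial likelihood with bivariate-normal cell
    probabilities.  Returns ``(rho, asymptotic variance)``; rho is clipped
    to +/-0.995 and the variance at a clip boundary is ``inf``.
    """
    table = _collapse_table(table)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise PolychoricError(
            f"degenerate margins for pair {names}: need >=2 categories each way"
        )
    n = table.sum()
    if thresholds is None:
        tau_r = estimate_thresholds(table.sum(axis=1), item=names[0])
        tau_c = estimate_thresholds(table.sum(axis=0), item=names[1])
    else:
        tau_r, tau_c = (np.asarray(t, dtype=float) for t in thresholds)

    mask = table > 0

    def negll(rho: float) -> float:
        p = np.clip(_cell_probs(tau_r, tau_c, rho), 1e-300, None)
        return -float(np.sum(table[mask] * np.log(p[mask])))

    res = optimize.minimize_scalar(
        negll, bounds=(-RHO_CLIP, RHO_CLIP), method="bounded",
        options={"xatol": 1e-9},
    )
    if not res.success:  # pragma: no cover - bounded Brent always converges
        raise PolychoricError(
            f"polychoric estimation failed for pair {names}: {res.message} "
            f"after {res.nfev} evaluations"
        )
    rho = float(res.x)

    if abs(rho) >= RHO_CLIP - 1e-6:
        rho = float(np.sign(rho) * RHO_CLIP)
        return rho, np.inf

    # observed information by central second difference of the negative
    # log-likelihood; step balanced against the bound
    step = min(1e-4, (RHO_CLIP - abs(rho)) / 2)
    d2 = (negll(rho + step) - 2.0 * negll(rho) + negll(rho - step)) / step**2
    avar = 1.0 / d2 if d2 > 0 else np.inf
    return rho, float(avar)


# ---------------------------------------------------------------------------
# full matrix
# ---------------------------------------------------------------------------

@dataclass
class PolychoricMatrix:
    """Pairwise polychoric correlations with DWLS weight information.

    Attributes
    ----------
    items : item names, in matrix order.
    rho : symmetric correlation matrix with unit diagonal.
    avar : matrix of asymptotic variances on the sqrt(n) scale, i.e. the
        variance of sqrt(n_pair) * (rho_hat - rho); divide by n_pair for
        the finite-sample variance of an estimate.  Diagonal entries are
        0 by convention.  These are the DWLS weights.
    thresholds : per-item standard-normal cut-points.
    n_pairwise : observations used per pair.
    """

    items: list[str]
    rho: np.ndarray
    avar: np.ndarray
    thresholds: ThresholdSet
    n_pairwise: np.ndarray

    @property
    def n(self) -> int:
        """Smallest pairwise n; the sample size used for chi-square scaling."""
        off = self.n_pairwise[~np.eye(len(self.items), dtype=bool)]
        return int(off.min()) if off.size else 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.items, columns=self.items)

    def to_json_dict(self) -> dict:
        return {
            "items": self.items,
            "rho": self.rho.tolist(),
            "avar": self.avar.tolist(),
            "thresholds": self.thresholds.to_dict(),
            "n_pairwise": self.n_pairwise.tolist(),
        }


def polychoric_matrix(data: pd.DataFrame, items: list[str] | None = None) -> PolychoricMatrix:
    """All pairwise polychoric correlations of an ordinal item matrix.

    ``data`` holds one column per item with small-integer category codes;
    missing entries (NaN) are dropped pairwise.  In the pipeline the data
    are already listwise complete, so pairwise and listwise coincide.
    """
    if items is None:
        items = list(data.columns)
    if len(items) < 2:
        raise ValueError("need at least two items")
    p = len(items)
    rho = np.eye(p)
    avar = np.zeros((p, p))
    npair = np.zeros((p, p), dtype=int)

    taus = ThresholdSet()
    for name in items:
        col = data[name].dropna().to_numpy()
        cats = np.unique(col)
        counts = np.array([(col == c).sum() for c in cats], dtype=float)
        taus.taus[name] = estimate_thresholds(counts, item=name)
        taus.categories[name] = cats[counts > 0]
        npair[items.index(name), items.index(name)] = col.size

    for a in range(p):
        for b in range(a + 1, p):
            sub = data[[items[a], items[b]]].dropna()
            table = pd.crosstab(sub[items[a]], sub[items[b]]).to_numpy()
            try:
                r, v = polychoric_pair(table, names=(items[a], items[b]))
            except PolychoricError as exc:
                raise PolychoricError(
                    f"pair ({items[a]}, {items[b]}): {exc}"
                ) from exc
            rho[a, b] = rho[b, a] = r
            avar[a, b] = avar[b, a] = v * len(sub)
            npair[a, b] = npair[b, a] = len(sub)

    return PolychoricMatrix(items=list(items), rho=rho, avar=avar,
                            thresholds=taus, n_pairwise=npair)
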