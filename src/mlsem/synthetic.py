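"""Synthetic clustered GHQ-12 questionnaire data with known ground truth.

Generates households of two or more adults whose twelve ordinal item
responses are driven by a two-level latent psychiatric-morbidity factor:

    eta_hh_j  = gamma' Z_j + u_j,           u_j ~ N(0, psi_hh)
    eta_ij    = beta' X_ij + eta_hh_j + e_ij,  e_ij ~ N(0, psi_ind)
    Ystar_pij = lambda_p * eta_ij + eps_pij,   eps ~ N(0, theta)
    Y_pij     = c   iff   tau_{p,c-1} < Ystar_pij <= tau_{p,c}

Defaults reproduce the study conditions of a large English household
health survey: item margins, predictor margins, loadings and structural
coefficients match the published estimates, so the generator doubles as a
ground-truth oracle for every downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import truncnorm

__all__ = [
    "SimulationConfig",
    "PredictorDists",
    "HouseholdDataset",
    "ITEM_NAMES",
    "PREDICTOR_IND",
    "PREDICTOR_HH",
    "DEFAULT_LOADINGS",
    "DEFAULT_ITEM_MARGINS",
    "DEFAULT_BETA",
    "DEFAULT_GAMMA",
    "default_config",
    "thresholds_from_margins",
    "structural_moments",
    "generate_households",
    "derive_coresident_flag",
    "apply_missingness",
]

ITEM_NAMES = [f"Y{p}" for p in range(1, 13)]
PREDICTOR_IND = ["X_co", "X1_age", "X2_male", "X3_working", "X4_history",
                 "X5_householder", "X6_closeness", "X7_bmi"]
PREDICTOR_HH = ["Z1_deprivation", "Z2_closeness"]

#: unstandardized loadings of the 12 GHQ items on the morbidity factor
#: (first fixed to 1 by the identification convention)
DEFAULT_LOADINGS = np.array([1.0, 1.415, 0.954, 1.837, 0.964, 2.059,
                             3.366, 3.575, 3.482, 4.516, 4.225, 3.634])

#: marginal response proportions (categories 1..4) per item, matching the
#: survey's observed frequency table
DEFAULT_ITEM_MARGINS = np.array([
    [52, 1748, 181, 18],
    [191, 1596, 164, 42],
    [133, 1747, 108, 12],
    [95, 1598, 247, 55],
    [84, 1753, 109, 19],
    [189, 1612, 137, 31],
    [673, 1025, 255, 47],
    [541, 1096, 315, 44],
    [760, 1059, 140, 34],
    [811, 891, 228, 40],
    [886, 873, 174, 34],
    [1349, 502, 91, 29],
], dtype=float)
DEFAULT_ITEM_MARGINS /= DEFAULT_ITEM_MARGINS.sum(axis=1, keepdims=True)

#: structural coefficients (order: X_co, age, male, working, history,
#: householder, closeness, BMI) and household-level (deprivation,
#: household closeness)
DEFAULT_BETA = np.array([0.020, -0.001, -0.026, -0.019, 0.076, 0.028,
                         -0.056, 0.002])
DEFAULT_GAMMA = np.array([0.004, -0.013])

_MOMENT_SEED = 20140901  # internal seed for predictor-moment Monte Carlo


@dataclass
class PredictorDists:
    """Generating distributions for the predictors (survey-margin defaults)."""

    age_mean: float = 55.76
    age_sd: float = 18.38
    age_min: float = 16.0
    age_max: float = 100.0
    p_male: float = 0.497
    p_working: float = 0.464
    p_history: float = 0.241
    p_householder: float = 0.828
    closeness_probs: tuple = (0.011, 0.051, 0.309, 0.444, 0.185)
    bmi_mean: float = 26.72
    bmi_sd: float = 5.3
    bmi_min: float = 14.0
    deprivation_probs: tuple = (0.256, 0.233, 0.214, 0.164, 0.133)
    z2_noise_sd: float = 0.1


@dataclass
class SimulationConfig:
    """Everything needed to generate one clustered-questionnaire dataset.

    ``thresholds`` are cut-points on the latent-response scale; ``theta``
    is the indicator residual variance structure — a length-12 vector
    (diagonal) or a 12x12 PSD matrix; ``None`` selects the delta
    convention Var(Ystar_p) = 1 at the generating parameter values.
    """

    n_households: int = 888
    household_size_probs: dict = field(default_factory=lambda: {2: 0.7, 3: 0.2, 4: 0.1})
    loadings: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    thresholds: np.ndarray | None = None  # (12, 3); None -> from DEFAULT_ITEM_MARGINS
    psi_ind: float = 0.013
    psi_hh: float = 0.003
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    gamma: np.ndarray = field(default_factory=lambda: DEFAULT_GAMMA.copy())
    theta: np.ndarray | None = None
    predictor_dists: PredictorDists = field(default_factory=PredictorDists)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_households < 1:
            raise ValueError("n_households must be a positive count")
        if any(s < 2 for s in self.household_size_probs):
            raise ValueError("household_size_probs: household sizes must be >= 2")
        if not np.isclose(sum(self.household_size_probs.values()), 1.0):
            raise ValueError("household_size_probs must sum to 1")
        if self.psi_ind < 0:
            raise ValueError("psi_ind must be >= 0")
        if self.psi_hh < 0:
            raise ValueError("psi_hh must be >= 0")
        if len(self.loadings) != 12:
            raise ValueError("loadings must have length 12")
        if len(self.beta) != 8 or len(self.gamma) != 2:
            raise ValueError("beta must have length 8 and gamma length 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.thresholds is not None:
            th = np.asarray(self.thresholds, dtype=float)
            if th.shape != (12, 3):
                raise ValueError("thresholds must have shape (12, 3)")
            if np.any(np.diff(th, axis=1) <= 0):
                raise ValueError("thresholds must be strictly increasing per item")
        if self.theta is not None:
            th = np.asarray(self.theta, dtype=float)
            if th.ndim == 1:
                if np.any(th <= 0):
                    raise ValueError("theta diagonal entries must be positive")
            else:
                ev = np.linalg.eigvalsh(th)
                if ev.min() < -1e-10:
                    raise ValueError("theta must be positive semi-definite")

    def to_json_dict(self) -> dict:
        d = {
            "n_households": self.n_households,
            "household_size_probs": {str(k): v for k, v in self.household_size_probs.items()},
            "loadings": list(map(float, self.loadings)),
            "psi_ind": self.psi_ind,
            "psi_hh": self.psi_hh,
            "beta": list(map(float, self.beta)),
            "gamma": list(map(float, self.gamma)),
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }
        if self.thresholds is not None:
            d["thresholds"] = np.asarray(self.thresholds).tolist()
        if self.theta is not None:
            d["theta"] = np.asarray(self.theta).tolist()
        return d


@dataclass
class HouseholdDataset:
    """Individuals nested in households, one row per individual.

    ``df`` columns: household_id, person_id, Y1..Y12 (codes 1-4 or NaN),
    the eight individual predictors, the two household predictors, and —
    when generated — the ground-truth latent scores eta_ind / eta_hh.
    ``ground_truth`` stores the generating parameters when known.
    """

    df: pd.DataFrame
    ground_truth: dict | None = None

    @property
    def n_individuals(self) -> int:
        return len(self.df)

    @property
    def n_households(self) -> int:
        return self.df["household_id"].nunique()

    def to_csv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False, na_rep="NA")
        if sidecar and self.ground_truth is not None:
            with open(path.with_suffix(".truth.json"), "w") as fh:
                json.dump(self.ground_truth, fh, indent=1)

    def copy(self) -> "HouseholdDataset":
        gt = dict(self.ground_truth) if self.ground_truth is not None else None
        return HouseholdDataset(self.df.copy(), gt)


# ---------------------------------------------------------------------------
# configuration helpers
# ---------------------------------------------------------------------------

def _sample_predictors(rng: np.random.Generator, sizes: np.ndarray,
                       dists: PredictorDists) -> pd.DataFrame:
    """Draw predictors for households of the given sizes (one row/person)."""
    n = int(sizes.sum())
    J = len(sizes)
    hh = np.repeat(np.arange(1, J + 1), sizes)
    person = np.concatenate([np.arange(1, s + 1) for s in sizes])

    a = (dists.age_min - dists.age_mean) / dists.age_sd
    b = (dists.age_max - dists.age_mean) / dists.age_sd
    age = truncnorm.rvs(a, b, loc=dists.age_mean, scale=dists.age_sd,
                        size=n, random_state=rng)
    male = (rng.random(n) < dists.p_male).astype(int)
    working = (rng.random(n) < dists.p_working).astype(int)
    history = (rng.random(n) < dists.p_history).astype(int)
    householder = (rng.random(n) < dists.p_householder).astype(int)
    closeness = rng.choice(np.arange(1, 6), size=n, p=np.asarray(dists.closeness_probs))
    bmi = np.maximum(rng.normal(dists.bmi_mean, dists.bmi_sd, size=n), dists.bmi_min)

    z1_hh = rng.choice(np.arange(1, 6), size=J, p=np.asarray(dists.deprivation_probs))
    z1 = np.repeat(z1_hh, sizes)
    # household closeness: mean of members' closeness plus small noise
    sums = np.zeros(J)
    np.add.at(sums, hh - 1, closeness)
    z2_hh = sums / sizes + rng.normal(0.0, dists.z2_noise_sd, size=J)
    z2 = np.clip(np.repeat(z2_hh, sizes), 1.0, 5.0)

    df = pd.DataFrame({
        "household_id": hh, "person_id": person,
        "X_co": 0,  # filled by derive_coresident_flag
        "X1_age": age, "X2_male": male, "X3_working": working,
        "X4_history": history, "X5_householder": householder,
        "X6_closeness": closeness.astype(int), "X7_bmi": bmi,
        "Z1_deprivation": z1.astype(int), "Z2_closeness": z2,
    })
    return df


def structural_moments(config: SimulationConfig, n_mc: int = 20000) -> tuple[float, float]:
    """Mean and variance of the structural part beta'X + gamma'Z.

    Estimated by an internal fixed-seed Monte Carlo over the predictor
    distributions (exact zeros when all coefficients are zero), so that
    default thresholds and the delta-scale residual variances are
    reproducible functions of the configuration alone.
    """
    if not np.any(config.beta) and not np.any(config.gamma):
        return 0.0, 0.0
    rng = np.random.default_rng(_MOMENT_SEED)
    sizes_avail = np.array(sorted(config.household_size_probs))
    probs = np.array([config.household_size_probs[s] for s in sizes_avail], dtype=float)
    J = max(2, int(np.ceil(n_mc / float(sizes_avail @ probs))))
    sizes = rng.choice(sizes_avail, size=J, p=probs)
    df = _sample_predictors(rng, sizes, config.predictor_dists)
    df = _coresident_flag_inplace(df)
    lin = df[PREDICTOR_IND].to_numpy() @ np.asarray(config.beta, float) \
        + df[PREDICTOR_HH].to_numpy() @ np.asarray(config.gamma, float)
    return float(lin.mean()), float(lin.var())


def thresholds_from_margins(margins: np.ndarray, loadings: np.ndarray,
                            latent_mean: float, ystar_sd: np.ndarray | float = 1.0
                            ) -> np.ndarray:
    """Cut-points that reproduce target marginal category probabilities.

    Under the (approximately) normal marginal of the latent response with
    mean ``lambda_p * latent_mean`` and the given SD, category c has
    probability ``margins[p, c]`` when the cut-points are placed at the
    matching normal quantiles.
    """
    margins = np.asarray(margins, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    cum = np.cumsum(margins, axis=1)[:, :-1]
    sd = np.broadcast_to(np.asarray(ystar_sd, dtype=float), (len(loadings),))
    return ndtri(cum) * sd[:, None] + loadings[:, None] * latent_mean


def default_config(**overrides) -> SimulationConfig:
    """Study-condition configuration with thresholds matching the survey margins."""
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    if cfg.thresholds is None:
        mu, _ = structural_moments(cfg)
        cfg = replace(cfg, thresholds=thresholds_from_margins(
            DEFAULT_ITEM_MARGINS, cfg.loadings, mu))
    return cfg


def _resolve_theta(config: SimulationConfig) -> np.ndarray:
    """Residual variance structure; delta convention Var(Ystar)=1 by default."""
    if config.theta is not None:
        th = np.asarray(config.theta, dtype=float)
        return np.diag(th) if th.ndim == 1 else th
    _, var_struct = structural_moments(config)
    var_eta = var_struct + config.psi_ind + config.psi_hh
    lam = np.asarray(config.loadings, dtype=float)
    diag = 1.0 - lam**2 * var_eta
    if np.any(diag <= 0):
        raise ValueError(
            "theta: delta convention gives non-positive residual variance; "
            "supply theta explicitly or reduce the latent variance")
    return np.diag(diag)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_households(config: SimulationConfig) -> HouseholdDataset:
    """Generate a clustered ordinal dataset with stored ground truth."""
    config.validate()
    if config.thresholds is None:
        config = default_config(**{
            k: getattr(config, k) for k in (
                "n_households", "household_size_probs", "loadings", "psi_ind",
                "psi_hh", "beta", "gamma", "theta", "predictor_dists",
                "missing_rate", "seed")})
    theta = _resolve_theta(config)
    tau = np.asarray(config.thresholds, dtype=float)
    lam = np.asarray(config.loadings, dtype=float)
    beta = np.asarray(config.beta, dtype=float)
    gamma = np.asarray(config.gamma, dtype=float)

    rng = np.random.default_rng(config.seed)
    sizes_avail = np.array(sorted(config.household_size_probs))
    probs = np.array([config.household_size_probs[s] for s in sizes_avail], dtype=float)
    sizes = rng.choice(sizes_avail, size=config.n_households, p=probs)
    df = _sample_predictors(rng, sizes, config.predictor_dists)
    df = _coresident_flag_inplace(df)

    J = config.n_households
    n = len(df)
    hh_index = df["household_id"].to_numpy() - 1

    z_block = df.groupby("household_id", sort=True)[PREDICTOR_HH].first().to_numpy()
    u = rng.normal(0.0, np.sqrt(config.psi_hh), size=J)
    eta_hh = z_block @ gamma + u
    e = rng.normal(0.0, np.sqrt(config.psi_ind), size=n)
    eta_ind = df[PREDICTOR_IND].to_numpy() @ beta + eta_hh[hh_index] + e

    eps = rng.multivariate_normal(np.zeros(12), theta, size=n, method="cholesky")
    ystar = lam[None, :] * eta_ind[:, None] + eps
    # category = 1 + number of cut-points below the latent response
    y = 1 + (ystar[:, :, None] > tau[None, :, :]).sum(axis=2)
    for p, name in enumerate(ITEM_NAMES):
        df[name] = y[:, p].astype(int)
    df["eta_ind"] = eta_ind
    df["eta_hh"] = eta_hh[hh_index]
    cols = (["household_id", "person_id"] + ITEM_NAMES + PREDICTOR_IND
            + PREDICTOR_HH + ["eta_ind", "eta_hh"])
    df = df[cols]

    truth = config.to_json_dict()
    truth["thresholds"] = tau.tolist()
    truth["theta_diag"] = np.diag(theta).tolist()
    ds = HouseholdDataset(df, ground_truth=truth)
    if config.missing_rate > 0:
        ds = apply_missingness(ds, config.missing_rate,
                               seed=int(rng.integers(2**31 - 1)))
    return ds


def _coresident_flag_inplace(df: pd.DataFrame) -> pd.DataFrame:
    sizes = df.groupby("household_id")["person_id"].transform("size")
    if (sizes < 2).any():
        bad = df.loc[sizes < 2, "household_id"].unique()
        raise ValueError(
            f"derive_coresident_flag: households with a single member: {list(bad)}")
    others = df.groupby("household_id")["X4_history"].transform("sum") - df["X4_history"]
    df["X_co"] = (others > 0).astype(int)
    return df


def derive_coresident_flag(dataset: HouseholdDataset) -> HouseholdDataset:
    """Set X_co = 1 iff any *other* member of the household has a history
    of common mental disorder (X4).  Idempotent; errors on singleton
    households (they have no co-residents)."""
    out = dataset.copy()
    _coresident_flag_inplace(out.df)
    return out


def apply_missingness(dataset: HouseholdDataset, rate: float, seed: int) -> HouseholdDataset:
    """MCAR missingness on the item responses and the partially observed
    predictors (closeness, BMI, household closeness), cell-wise at the
    given rate.  Reproducible for a fixed seed."""
    if not 0 <= rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    out = dataset.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    cols = ITEM_NAMES + ["X6_closeness", "X7_bmi", "Z2_closeness"]
    mask = rng.random((len(out.df), len(cols))) < rate
    for j, c in enumerate(cols):
        out.df[c] = out.df[c].astype(float).mask(mask[:, j])
    if out.ground_truth is not None:
        out.ground_truth["missing_rate_applied"] = rate
        out.ground_truth["missing_seed"] = seed
    return out
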