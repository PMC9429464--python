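"""Two-level structural model: likelihood, fitting, derived quantities."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import norm

from mlsem import (DEFAULT_BETA, DEFAULT_GAMMA, ITEM_NAMES, PREDICTOR_HH,
                   PREDICTOR_IND, default_config, generate_households)
from mlsem.msem import (MSEMFit, MSEMSpec, explained_variance, fit_msem,
                        fit_null_model, household_loglik, hypothesis_tests,
                        latent_icc, standardize)


@pytest.fixture(scope="module")
def truth_spec(small_dataset):
    return MSEMSpec.from_truth(small_dataset.ground_truth)


@pytest.fixture(scope="module")
def small_fit(small_dataset, truth_spec):
    return fit_msem(small_dataset, truth_spec, n_nodes=9)


def _two_item_spec(spec):
    return MSEMSpec(loadings=spec.loadings[:2], thresholds=spec.thresholds[:2],
                    theta=spec.theta[:2], categories=spec.categories[:2],
                    item_names=ITEM_NAMES[:2])


class TestHouseholdLoglik:
    def test_no_latent_contribution_gives_marginal_probabilities(
            self, small_dataset, truth_spec):
        """With the structural part and both variance components zeroed
        the latent factor vanishes and the log-likelihood reduces to the
        sum of threshold-implied category log-probabilities."""
        block = small_dataset.df[small_dataset.df.household_id == 1]
        ll = household_loglik(block, truth_spec, np.zeros(8), np.zeros(2),
                              0.0, 0.0)
        expected = 0.0
        for _, row in block.iterrows():
            for j, item in enumerate(ITEM_NAMES):
                tau = np.concatenate(([-np.inf], truth_spec.thresholds[j],
                                      [np.inf]))
                c = int(row[item]) - 1
                sd = np.sqrt(truth_spec.theta[j])
                expected += np.log(norm.cdf(tau[c + 1] / sd)
                                   - norm.cdf(tau[c] / sd))
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_matches_monte_carlo_integration(self, small_dataset, truth_spec):
        """Nested quadrature agrees with brute-force Monte-Carlo
        integration on a two-member, two-item household."""
        block = small_dataset.df[small_dataset.df.household_id == 1].iloc[:2]
        spec2 = _two_item_spec(truth_spec)
        ll_q = household_loglik(block, spec2, DEFAULT_BETA, DEFAULT_GAMMA,
                                0.013, 0.003, n_nodes=21)
        rng = np.random.default_rng(12345)
        n_draws = 10**6
        m = (block[PREDICTOR_IND].to_numpy() @ DEFAULT_BETA
             + block[PREDICTOR_HH].to_numpy() @ DEFAULT_GAMMA)
        u = rng.normal(0, np.sqrt(0.003), n_draws)
        tot = np.ones(n_draws)
        for i in range(len(block)):
            e = rng.normal(0, np.sqrt(0.013), n_draws)
            eta = m[i] + u + e
            for j in range(2):
                tau = np.concatenate(([-30], spec2.thresholds[j], [30]))
                c = int(block.iloc[i][ITEM_NAMES[j]]) - 1
                lam, sd = spec2.loadings[j], np.sqrt(spec2.theta[j])
                tot *= (ndtr((tau[c + 1] - lam * eta) / sd)
                        - ndtr((tau[c] - lam * eta) / sd))
        assert ll_q == pytest.approx(np.log(tot.mean()), abs=1e-3)

    def test_psi_hh_zero_factorizes_over_individuals(self, small_dataset,
                                                     truth_spec):
        """With no household variance the household likelihood is the
        product of independent per-individual likelihoods."""
        df = small_dataset.df
        block = df[df.household_id == 2]
        ll_joint = household_loglik(block, truth_spec, DEFAULT_BETA,
                                    DEFAULT_GAMMA, 0.013, 0.0)
        ll_split = 0.0
        for pid in block["person_id"]:
            solo = block[block.person_id == pid].copy()
            solo["household_id"] = 999  # lone pseudo-household
            ll_split += household_loglik(solo, truth_spec, DEFAULT_BETA,
                                         DEFAULT_GAMMA, 0.013, 0.0)
        assert ll_joint == pytest.approx(ll_split, abs=1e-8)

    def test_requires_seven_nodes(self, small_dataset, truth_spec):
        block = small_dataset.df[small_dataset.df.household_id == 1]
        with pytest.raises(ValueError, match="at least 7"):
            household_loglik(block, truth_spec, DEFAULT_BETA, DEFAULT_GAMMA,
                             0.01, 0.01, n_nodes=5)


class TestFitMSEM:
    def test_quadrature_convergence(self, small_dataset, truth_spec):
        """Doubling the node count leaves the optimum essentially
        unchanged."""
        a = fit_msem(small_dataset, truth_spec, n_nodes=15, compute_se=False)
        b = fit_msem(small_dataset, truth_spec, n_nodes=25, compute_se=False)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-3)
        assert a.beta == pytest.approx(b.beta, abs=1e-3)

    def test_invariant_to_household_ordering(self, small_dataset, truth_spec):
        df = small_dataset.df
        shuffled = df.sample(frac=1.0, random_state=1)
        a = fit_msem(df, truth_spec, n_nodes=9, compute_se=False)
        b = fit_msem(shuffled, truth_spec, n_nodes=9, compute_se=False)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)
        assert a.beta == pytest.approx(b.beta, abs=1e-6)

    def test_null_nested_in_full(self, small_dataset, truth_spec, small_fit):
        null = fit_null_model(small_dataset, truth_spec, n_nodes=9)
        assert null.fit.loglik <= small_fit.loglik
        assert null.fit.n_params < small_fit.n_params

    def test_boundary_psi_hh_detected(self):
        cfg = default_config(n_households=150, seed=31, psi_hh=0.0,
                             gamma=np.zeros(2))
        ds = generate_households(cfg)
        spec = MSEMSpec.from_truth(ds.ground_truth)
        fit = fit_msem(ds, spec, n_nodes=9, compute_se=False)
        assert fit.psi_hh < 0.002

    def test_recovery_at_study_conditions(self, study_dataset):
        """Structural parameters recovered at survey scale."""
        spec = MSEMSpec.from_truth(study_dataset.ground_truth)
        fit = fit_msem(study_dataset, spec, n_nodes=9)
        est = fit.estimates()
        truth = dict(zip(PREDICTOR_IND, DEFAULT_BETA))
        truth.update(zip(PREDICTOR_HH, DEFAULT_GAMMA))
        truth.update(psi_ind=0.013, psi_hh=0.003)
        for k, v in truth.items():
            se = fit.se[k]
            assert abs(est[k] - v) < 4 * se + 1e-4, k


class TestDerivedQuantities:
    def test_latent_icc_published_values(self):
        # null-model variance components printed in the study
        assert latent_icc(0.008, 0.026) == pytest.approx(0.235, abs=5e-4)

    def test_latent_icc_edge_cases(self):
        assert latent_icc(0.0, 0.4) == 0.0
        assert latent_icc(0.7, 0.7) == 0.5
        with pytest.raises(ValueError):
            latent_icc(0.0, 0.0)

    def test_explained_variance_published_values(self):
        assert explained_variance(0.026, 0.013) == pytest.approx(0.5)
        assert explained_variance(0.008, 0.003) == pytest.approx(0.625)
        assert explained_variance(0.4, 0.4) == 0.0

    def test_explained_variance_errors_and_warnings(self):
        with pytest.raises(ValueError):
            explained_variance(0.0, 0.1)
        with pytest.warns(UserWarning, match="negative"):
            assert explained_variance(0.01, 0.02) == pytest.approx(-1.0)


class TestHypothesisTests:
    def _fit_with(self, estimates, ses, small_fit):
        import copy
        fit = copy.copy(small_fit)
        est = dict(zip(PREDICTOR_IND, fit.beta))
        beta = fit.beta.copy()
        se = dict(fit.se)
        for k, v in estimates.items():
            beta[PREDICTOR_IND.index(k)] = v
        for k, v in ses.items():
            se[k] = v
        fit.beta = beta
        fit.se = se
        return fit

    def test_zero_estimate_gives_half(self, small_fit):
        fit = self._fit_with({"X4_history": 0.0}, {"X4_history": 0.05},
                             small_fit)
        t = hypothesis_tests(fit).set_index("parameter")
        assert t.loc["X4_history", "p_one_sided"] == pytest.approx(0.5)

    def test_z_at_one_percent_boundary(self, small_fit):
        fit = self._fit_with({"X4_history": 2.326 * 0.01},
                             {"X4_history": 0.01}, small_fit)
        t = hypothesis_tests(fit).set_index("parameter")
        assert t.loc["X4_history", "p_one_sided"] == pytest.approx(0.010, abs=2e-4)

    def test_wrong_direction_not_significant(self, small_fit):
        fit = self._fit_with({"X2_male": +0.5}, {"X2_male": 0.01}, small_fit)
        t = hypothesis_tests(fit).set_index("parameter")
        # hypothesis: male < 0, so a large positive estimate yields p ~ 1
        assert t.loc["X2_male", "p_one_sided"] > 0.99
        assert t.loc["X2_male", "tier"] == "ns"

    def test_zero_se_flagged(self, small_fit):
        fit = self._fit_with({}, {"X7_bmi": 0.0}, small_fit)
        t = hypothesis_tests(fit).set_index("parameter")
        assert t.loc["X7_bmi", "tier"] == "undefined"


class TestStandardize:
    def test_scale_invariance(self, small_dataset, truth_spec):
        """Doubling a predictor's scale halves its coefficient but leaves
        the standardized value unchanged."""
        fit1 = fit_msem(small_dataset, truth_spec, n_nodes=9,
                        compute_se=False)
        std1 = standardize(fit1, small_dataset)

        ds2 = small_dataset.copy()
        ds2.df["X7_bmi"] = ds2.df["X7_bmi"] * 2.0
        fit2 = fit_msem(ds2, truth_spec, n_nodes=9, compute_se=False)
        std2 = standardize(fit2, ds2)
        k = PREDICTOR_IND.index("X7_bmi")
        assert fit2.beta[k] == pytest.approx(fit1.beta[k] / 2, rel=0.05)
        assert std2["beta"]["X7_bmi"] == pytest.approx(
            std1["beta"]["X7_bmi"], abs=0.01)

    def test_standardized_loadings_in_unit_interval(self, small_fit,
                                                    small_dataset):
        std = standardize(small_fit, small_dataset)
        vals = np.array(list(std["loadings"].values()))
        assert np.all(np.abs(vals) < 1.0)
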