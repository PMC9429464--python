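"""DWLS measurement model: discrepancy, indices, modification indices."""

import dataclasses

import numpy as np
import pytest

from mlsem import (ITEM_NAMES, DEFAULT_LOADINGS, default_config,
                   generate_households, polychoric_matrix)
from mlsem.cfa import (CFAFit, ModelSpec, fit_baseline, fit_dwls, fit_indices,
                       implied_correlations, modification_indices,
                       stepwise_free_covariances)
from mlsem.synthetic import _resolve_theta


def _stub_fit(chi2, df, discrepancy=1.0, n=1000):
    return CFAFit(spec=ModelSpec(), loadings=np.ones(12), psi=0.02,
                  error_covs={}, se_loadings=np.full(12, np.nan), se_psi=0.0,
                  se_error_covs={}, discrepancy=discrepancy, chi2=chi2, df=df,
                  n=n, converged=True, n_iter=0, heywood=False,
                  residuals=np.zeros(66))


class TestImpliedCorrelations:
    def test_product_rule(self):
        # standardized loadings 0.6 and 0.5 -> implied correlation 0.30
        lam = np.array([1.0, 0.5 / 0.6])
        sigma = implied_correlations(lam, psi=0.36, error_covs={}, n_items=2)
        assert sigma[0, 1] == pytest.approx(0.30)

    def test_zero_loadings_leave_error_covariances(self):
        sigma = implied_correlations(np.zeros(3), 0.5, {(0, 2): 0.2}, 3)
        assert sigma[0, 2] == pytest.approx(0.2)
        assert sigma[0, 1] == 0.0

    def test_diagonal_fixed_to_one(self):
        sigma = implied_correlations(np.ones(4), 0.3, {}, 4)
        assert np.allclose(np.diag(sigma), 1.0)


class TestFitDWLS:
    def test_parameter_recovery_large_sample(self):
        """Standardized loadings recovered from data generated at the
        published loading pattern (n about 19k individuals)."""
        cfg = default_config(n_households=8000, seed=2)
        ds = generate_households(cfg)
        pm = polychoric_matrix(ds.df[ITEM_NAMES])
        fit = fit_dwls(pm, ModelSpec(item_names=list(ITEM_NAMES)))
        from mlsem import structural_moments
        _, vs = structural_moments(cfg)
        var_eta = vs + cfg.psi_ind + cfg.psi_hh
        truth_std = DEFAULT_LOADINGS * np.sqrt(var_eta)
        # 95% Monte-Carlo band: each standardized loading within ~3 SE
        err = np.abs(fit.standardized_loadings - truth_std)
        se = np.where(np.isnan(fit.se_loadings), 0.02,
                      fit.se_loadings * np.sqrt(fit.psi))
        assert np.all(err < np.maximum(3 * se, 0.03))

    def test_discrepancy_zero_iff_saturated_compatible(self, study_polymat):
        """Fitting the implied matrix of a known model returns F = 0."""
        lam = DEFAULT_LOADINGS
        psi = 0.02
        sigma = implied_correlations(lam, psi, {}, 12)
        pm = dataclasses.replace(study_polymat, rho=sigma)
        fit = fit_dwls(pm, ModelSpec(item_names=list(ITEM_NAMES)))
        assert fit.discrepancy == pytest.approx(0.0, abs=1e-12)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.loadings == pytest.approx(lam, abs=1e-5)

    def test_start_point_invariance(self, study_polymat):
        """Two distant optimizer starts reach the same optimum."""
        spec = ModelSpec(item_names=list(ITEM_NAMES))
        a = fit_dwls(study_polymat, spec)
        start = np.concatenate((np.full(11, 2.0), [0.01], []))
        b = fit_dwls(study_polymat, spec, start=start)
        assert a.loadings == pytest.approx(b.loadings, abs=1e-5)
        assert a.psi == pytest.approx(b.psi, rel=1e-5)

    def test_nested_model_monotonicity(self, study_polymat):
        base = fit_dwls(study_polymat, ModelSpec(item_names=list(ITEM_NAMES)))
        freed = fit_dwls(study_polymat,
                         ModelSpec(free_covs=[(0, 1)],
                                   item_names=list(ITEM_NAMES)))
        assert freed.discrepancy <= base.discrepancy + 1e-12

    def test_unidentified_spec_rejected(self, study_polymat):
        pairs = [(a, b) for a in range(12) for b in range(a + 1, 12)]
        with pytest.raises(Exception, match="identified"):
            fit_dwls(study_polymat, ModelSpec(free_covs=pairs))


class TestFitIndices:
    def test_closed_form_hand_calculation(self):
        fit = _stub_fit(chi2=50.0, df=40)
        base = _stub_fit(chi2=500.0, df=66, discrepancy=10.0)
        fi = fit_indices(fit, base, n=1000)
        assert fi.cfi == pytest.approx(1 - 10 / 434, abs=1e-12)
        assert fi.cfi == pytest.approx(0.977, abs=5e-4)
        assert fi.tli == pytest.approx(0.962, abs=5e-4)
        assert fi.rmsea == pytest.approx(np.sqrt(10 / (40 * 999)), abs=1e-12)
        assert fi.rmsea == pytest.approx(0.0158, abs=5e-5)

    def test_perfect_fit_truncation(self):
        fi = fit_indices(_stub_fit(chi2=30.0, df=40),
                         _stub_fit(chi2=500.0, df=66, discrepancy=10.0),
                         n=500)
        assert fi.cfi == 1.0
        assert fi.rmsea == 0.0

    def test_fit_equal_to_baseline_gives_zero_cfi(self):
        fi = fit_indices(_stub_fit(chi2=500.0, df=66, discrepancy=10.0),
                         _stub_fit(chi2=500.0, df=66, discrepancy=10.0),
                         n=500)
        assert fi.cfi == 0.0

    def test_df_zero_reported_not_applicable(self):
        fi = fit_indices(_stub_fit(chi2=0.0, df=0, discrepancy=0.0),
                         _stub_fit(chi2=500.0, df=66, discrepancy=10.0),
                         n=500)
        assert fi.rmsea is None and fi.tli is None


class TestModificationIndices:
    def test_free_parameters_excluded(self, study_polymat):
        spec = ModelSpec(free_covs=[(0, 1)], item_names=list(ITEM_NAMES))
        fit = fit_dwls(study_polymat, spec)
        pairs = [p for p, _, _ in modification_indices(fit, study_polymat)]
        assert (0, 1) not in pairs
        assert all(m >= 0 for _, m, _ in modification_indices(fit, study_polymat))

    def test_true_omitted_covariance_has_largest_mi(self):
        ds = _dataset_with_error_covariance(seed=77)
        pm = polychoric_matrix(ds.df[ITEM_NAMES])
        fit = fit_dwls(pm, ModelSpec(item_names=list(ITEM_NAMES)))
        mis = modification_indices(fit, pm)
        assert mis[0][0] == (1, 3)

    def test_mi_approximates_actual_chi2_drop(self):
        """Score statistic vs likelihood-ratio-style refit drop."""
        ds = _dataset_with_error_covariance(seed=78)
        pm = polychoric_matrix(ds.df[ITEM_NAMES])
        spec = ModelSpec(item_names=list(ITEM_NAMES))
        fit = fit_dwls(pm, spec)
        pair, mi, _ = modification_indices(fit, pm)[0]
        refit = fit_dwls(pm, spec.with_freed(pair))
        drop = fit.chi2 - refit.chi2
        assert mi > 10
        assert mi == pytest.approx(drop, rel=0.15)


class TestStepwise:
    def test_infinite_threshold_returns_start_spec(self, study_polymat):
        spec = ModelSpec(item_names=list(ITEM_NAMES))
        final, trail, _ = stepwise_free_covariances(
            study_polymat, spec, mi_threshold=np.inf)
        assert final.free_covs == []
        assert all("freed" not in t for t in trail)

    def test_type_i_control_under_correct_model(self, study_polymat):
        """With no true error covariances, the default rule frees few."""
        _, trail, _ = stepwise_free_covariances(
            study_polymat, ModelSpec(item_names=list(ITEM_NAMES)))
        assert len([t for t in trail if "freed" in t]) <= 6

    def test_two_true_covariances_freed_in_mi_order(self):
        cfg = default_config(n_households=1500, seed=55)
        th = _resolve_theta(cfg).copy()
        th[1, 3] = th[3, 1] = 0.40 * np.sqrt(th[1, 1] * th[3, 3])
        th[6, 10] = th[10, 6] = 0.25 * np.sqrt(th[6, 6] * th[10, 10])
        ds = generate_households(dataclasses.replace(cfg, theta=th))
        pm = polychoric_matrix(ds.df[ITEM_NAMES])
        _, trail, _ = stepwise_free_covariances(
            pm, ModelSpec(item_names=list(ITEM_NAMES)), max_steps=4)
        freed = [tuple(t["freed"]) for t in trail if "freed" in t]
        assert freed[0] == (1, 3)
        assert (6, 10) in freed[:3]


def _dataset_with_error_covariance(seed, strength=0.35):
    cfg = default_config(n_households=1500, seed=seed)
    th = _resolve_theta(cfg).copy()
    th[1, 3] = th[3, 1] = strength * np.sqrt(th[1, 1] * th[3, 3])
    return generate_households(dataclasses.replace(cfg, theta=th))
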