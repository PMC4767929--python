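"""ML covariance-structure engine: implied moments, discrepancy, fitting,
standard errors and fit indices."""

import math

import numpy as np
import pandas as pd
import pytest

from altsem import (
    AltSpec, FitOptions, MomentData, SemModel, baseline_model, build_alt,
    build_submodel, explained_variance, fit_indices, fit_model,
    implied_moments, ml_discrepancy, moments_from_raw, simulate_alt,
    standard_errors, SimulationConfig, config_to_model,
)
from altsem.exceptions import (
    DegenerateVarianceError, IdentificationError, StructuralError,
)


def saturated_model(md: MomentData) -> SemModel:
    m = SemModel(md.variables, md.variables)
    for i, a in enumerate(md.variables):
        m.set_variance(a, value=1.0, label=f"v_{a}")
        m.set_mean(a, label=f"m_{a}")
        for b in md.variables[:i]:
            m.set_covariance(a, b, label=f"c_{a}_{b}")
    return m


class TestImpliedMoments:
    def test_no_paths_reduces_to_psi_diag(self):
        m = SemModel(["a", "b"], ["a", "b"])
        m.set_variance("a", value=2.0)
        m.set_variance("b", value=3.0)
        sigma, mu = implied_moments(m, {})
        assert np.allclose(sigma, np.diag([2.0, 3.0]))
        assert np.allclose(mu, 0.0)

    def test_chain_hand_path_algebra(self):
        # x -> y with coefficient .5, var(x)=1, residual var(y)=.75:
        # var(y) = .25*1 + .75 = 1, cov = .5
        m = SemModel(["x", "y"], ["x", "y"])
        m.set_variance("x", value=1.0)
        m.set_variance("y", value=0.75)
        m.set_path("x", "y", value=0.5)
        sigma, mu = implied_moments(m, {})
        assert np.allclose(sigma, [[1.0, 0.5], [0.5, 1.0]])

    def test_unit_cycle_raises_structural_error(self):
        m = SemModel(["x", "y"], ["x", "y"])
        m.set_path("x", "y", value=1.0)
        m.set_path("y", "x", value=1.0)
        m.set_variance("x", value=1.0)
        m.set_variance("y", value=1.0)
        with pytest.raises(StructuralError):
            implied_moments(m, {})

    def test_self_loop_rejected(self):
        m = SemModel(["x"], ["x"])
        with pytest.raises(StructuralError):
            m.set_path("x", "x", value=0.5)

    def test_monte_carlo_agreement_large_n(self):
        cfg = SimulationConfig(
            T=4, n_per_cell=120000, covariates=(), intercept_mean=20.0,
            slope_mean=-1.0, icept_sd=4.0, slope_sd=0.5, is_corr=-0.2,
            rho=0.2, error_sd=3.0, seed=3,
        )
        md = moments_from_raw(simulate_alt(cfg))
        model, theta = config_to_model(cfg)
        sigma, mu = implied_moments(model, theta)
        sub = md.subset(model.observed)
        scale = np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
        assert np.max(np.abs(sub.covariance - sigma) / scale) < 0.01


class TestMlDiscrepancy:
    def test_zero_at_saturation(self, small_moments):
        S = small_moments.covariance
        assert ml_discrepancy(S, small_moments.means, S,
                              small_moments.means) == pytest.approx(0.0)

    def test_univariate_closed_form(self):
        S = np.array([[2.0]])
        sigma = np.array([[1.0]])
        x = np.array([0.0])
        assert ml_discrepancy(sigma, x, S, x) == pytest.approx(2 - math.log(2) - 1)

    def test_mean_shift_term(self):
        S = sigma = np.array([[1.0]])
        assert ml_discrepancy(sigma, np.array([0.0]), S,
                              np.array([1.0])) == pytest.approx(1.0)

    def test_nonnegative_everywhere(self, rng):
        for _ in range(20):
            L = rng.standard_normal((3, 3))
            S = L @ L.T + 3 * np.eye(3)
            L2 = rng.standard_normal((3, 3))
            sigma = L2 @ L2.T + 3 * np.eye(3)
            f = ml_discrepancy(sigma, rng.standard_normal(3), S,
                               rng.standard_normal(3))
            assert f >= -1e-12

    def test_non_pd_sigma_raises_not_nan(self):
        with pytest.raises(DegenerateVarianceError):
            ml_discrepancy(np.array([[-1.0]]), np.zeros(1),
                           np.array([[1.0]]), np.zeros(1))


class TestFitModel:
    def test_saturated_fit_is_exact(self, small_moments):
        fit = fit_model(saturated_model(small_moments), small_moments,
                        FitOptions(compute_se=False))
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_self_consistency_recovers_parameters(self):
        cfg = SimulationConfig(
            T=4, n_per_cell=10, covariates=("sex",), intercept_mean=40.0,
            slope_mean=-2.0, gamma_icept={"sex": 1.0},
            gamma_slope={"sex": -0.3}, icept_sd=6.0, slope_sd=0.7,
            is_corr=0.3, rho=0.12, error_sd=4.0, seed=0,
        )
        model, theta = config_to_model(cfg)
        sigma, mu = implied_moments(model, theta)
        pop = MomentData(model.observed, sigma, mu, 500)
        fit = fit_model(model, pop, FitOptions(compute_se=False))
        assert fit.converged
        assert fit.f_min == pytest.approx(0.0, abs=1e-10)
        for lab, true in theta.items():
            assert fit.theta[lab] == pytest.approx(true, abs=1e-6)

    def test_unidentified_model_rejected_before_optimization(self):
        md = MomentData(("a",), np.array([[1.0]]), np.zeros(1), 50)
        m = SemModel(["a", "f"], ["a"])
        m.set_path("f", "a", label="l")
        m.set_variance("f", value=1.0, label="vf")
        m.set_variance("a", value=1.0, label="va")
        m.set_mean("a", label="ma")
        with pytest.raises(IdentificationError):
            fit_model(m, md)

    def test_n_too_small_rejected(self, small_moments):
        tiny = MomentData(small_moments.variables, small_moments.covariance,
                          small_moments.means, small_moments.p)
        with pytest.raises(IdentificationError):
            fit_model(saturated_model(small_moments), tiny)

    def test_deterministic_bit_identical(self, small_moments):
        model = build_alt(AltSpec(T=5, covariates=("stress",)))
        f1 = fit_model(model, small_moments)
        model2 = build_alt(AltSpec(T=5, covariates=("stress",)))
        f2 = fit_model(model2, small_moments)
        assert f1.chi2 == f2.chi2
        assert list(f1.params["estimate"]) == list(f2.params["estimate"])
        assert list(f1.params["se"]) == list(f2.params["se"])

    def test_nested_model_never_fits_better(self, small_moments):
        spec = AltSpec(T=5, covariates=("stress",))
        full = fit_model(build_alt(spec), small_moments,
                         FitOptions(compute_se=False))
        equal_ar = fit_model(
            build_alt(AltSpec(T=5, covariates=("stress",), ar_equal=True)),
            small_moments, FitOptions(compute_se=False))
        no_ar = fit_model(
            build_submodel(AltSpec(T=5, covariates=("stress",), ar=False),
                           "LGM"),
            small_moments, FitOptions(compute_se=False))
        assert full.f_min <= equal_ar.f_min + 1e-10
        assert full.f_min <= no_ar.f_min + 1e-10

    def test_df_accounting_hand_counts(self):
        # AR chain on 3 observed: 2 paths + 3 variances + 3 means = 8 free;
        # moments = 6 + 3 = 9 -> df 1
        model = build_submodel(AltSpec(T=3, ar=True), "AR")
        assert model.n_free == 8
        assert model.degrees_of_freedom() == 1


class TestStandardErrors:
    def test_cr_scale_equivariance(self, small_moments):
        model = build_alt(AltSpec(T=5, covariates=("stress",)))
        fit = fit_model(model, small_moments)
        c = 3.0
        scale = np.array([c] * 5 + [1.0])
        cov2 = small_moments.subset(model.observed).covariance * np.outer(scale, scale)
        md2 = MomentData(model.observed, cov2,
                         small_moments.subset(model.observed).means * scale,
                         small_moments.n)
        fit2 = fit_model(build_alt(AltSpec(T=5, covariates=("stress",))), md2)
        for lab in ("stress_to_icept", "stress_to_slope", "rho_2", "rho_5"):
            assert fit2.cr(lab) == pytest.approx(fit.cr(lab), rel=1e-4)

    def test_wald_p_matches_normal(self, small_moments):
        model = build_alt(AltSpec(T=5, covariates=("stress",)))
        fit = fit_model(model, small_moments)
        row = fit.parameter("stress_to_icept")
        from scipy import stats
        assert row["p"] == pytest.approx(2 * stats.norm.sf(abs(row["cr"])))

    def test_se_close_to_bootstrap(self):
        """Wald SEs from the Hessian agree with bootstrap SEs on a small
        growth model (moderate n, 200 resamples)."""
        cfg = SimulationConfig(
            T=4, n_per_cell=250, covariates=("sex",), intercept_mean=40.0,
            slope_mean=-2.0, gamma_icept={"sex": 2.0},
            gamma_slope={"sex": 0.5}, icept_sd=6.0, slope_sd=0.7,
            is_corr=0.2, rho=0.0, error_sd=4.0, seed=5,
        )
        data = simulate_alt(cfg)
        model = build_submodel(AltSpec(T=4, covariates=("sex",), ar=False),
                               "LGM")
        fit = fit_model(model, moments_from_raw(data))
        rng = np.random.default_rng(99)
        n = data.n
        boot = {lab: [] for lab in ("sex_to_icept", "sex_to_slope",
                                    "mean_icept", "mean_slope")}
        for _ in range(200):
            take = rng.integers(0, n, n)
            resampled = type(data)(
                data.data.iloc[take].reset_index(drop=True),
                data.covariate_names, data.outcome_names, check_bounds=False)
            bfit = fit_model(model, moments_from_raw(resampled),
                             FitOptions(compute_se=False, polish_steps=1))
            if bfit.converged:
                for lab in boot:
                    boot[lab].append(bfit.theta[lab])
        for lab, draws in boot.items():
            se_boot = np.std(draws, ddof=1)
            se_wald = float(fit.parameter(lab)["se"])
            assert se_wald == pytest.approx(se_boot, rel=0.10), lab

    def test_singular_information_reports_missing_ses(self, small_moments):
        # over-parameterized mean structure: free wave intercepts AND free
        # latent means -> flat direction -> SEs reported missing
        model = build_alt(AltSpec(T=5, covariates=("stress",),
                                  free_wave_intercepts=True))
        fit = fit_model(model, small_moments)
        assert any("singular" in w or "identif" in w for w in fit.warnings)
        assert fit.params["se"].isna().all()


class TestBaselineAndIndices:
    def test_baseline_counts(self, table1):
        m = baseline_model(table1)
        assert m.n_free == 26
        assert m.degrees_of_freedom() == 78  # 104 moments - 26 parameters

    def test_baseline_exact_on_diagonal_data(self):
        md = MomentData(("a", "b"), np.diag([2.0, 5.0]),
                        np.array([1.0, -1.0]), 40)
        fit = fit_model(baseline_model(md), md, FitOptions(compute_se=False))
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_baseline_worse_than_alt_on_table1(self, table1):
        alt = fit_model(
            build_alt(AltSpec(T=9, covariates=("sex", "age", "stress",
                                               "genotype"))),
            table1, FitOptions(compute_se=False))
        base = fit_model(baseline_model(table1), table1,
                         FitOptions(compute_se=False))
        assert base.chi2 > alt.chi2
        assert base.chi2 == pytest.approx(alt.baseline_chi2, rel=1e-6)

    def test_exact_fit_limit(self):
        fi = fit_indices(50.0, 50, 500.0, 60, 100)
        assert fi.cfi == 1.0
        assert fi.rmsea == 0.0

    def test_rmsea_hand_value(self):
        fi = fit_indices(100.0, 50, 1000.0, 60, 201)
        assert fi.rmsea == pytest.approx(math.sqrt(50 / (50 * 200)))
        assert fi.rmsea == pytest.approx(0.0707, abs=5e-4)

    def test_indices_clip_when_chi2_below_df(self):
        fi = fit_indices(10.0, 50, 400.0, 60, 100)
        assert fi.cfi == 1.0 and fi.tli <= 1.0 and fi.rmsea == 0.0

    def test_rmsea_ci_brackets_point(self):
        fi = fit_indices(80.0, 50, 800.0, 60, 150)
        lo, hi = fi.rmsea_ci
        assert lo <= fi.rmsea <= hi
        assert 0 <= fi.pclose <= 1

    def test_df_zero_rmsea_not_applicable(self):
        fi = fit_indices(0.0, 0, 100.0, 10, 50)
        assert math.isnan(fi.rmsea)


class TestExplainedVariance:
    def test_latent_without_predictors_r2_zero(self, small_moments):
        model = build_submodel(AltSpec(T=5, ar=False), "LGM")
        fit = fit_model(model, small_moments, FitOptions(compute_se=False))
        # growth factors receive no paths in a covariate-free LGM
        assert "ICEPT" not in fit.r2

    def test_single_predictor_matches_regression(self, small_data):
        # y = day_5, x = stress: SEM R^2 equals OLS r^2
        md = moments_from_raw(small_data, ["day_5", "stress"])
        m = SemModel(["stress", "day_5"], ["stress", "day_5"])
        m.set_variance("stress", value=0.25, label="vx")
        m.set_mean("stress", label="mx")
        m.set_path("stress", "day_5", label="b")
        m.set_variance("day_5", value=1.0, label="ve")
        m.set_mean("day_5", label="my")
        fit = fit_model(m, md, FitOptions(compute_se=False))
        r = np.corrcoef(small_data.data["stress"],
                        small_data.data["day_5"])[0, 1]
        assert fit.r2["day_5"] == pytest.approx(r ** 2, abs=1e-6)


class TestSerialization:
    def test_fit_result_json_round_trip(self, small_moments):
        from altsem.report import FIT_RESULT_SCHEMA, validate_json
        import json
        fit = fit_model(build_alt(AltSpec(T=5, covariates=("stress",))),
                        small_moments)
        obj = json.loads(fit.to_json())
        assert validate_json(obj, FIT_RESULT_SCHEMA) == []
        assert obj["converged"] is True
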