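import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gwrflow.gwr import (
    GWRResults,
    KernelSpec,
    classify_significance,
    correlation_diagnostics,
    fit_global_ols,
    fit_gwr,
    kernel_weights,
    select_bandwidth_aicc,
    summarize_gwr,
)
from gwrflow.preprocess import DEFAULT_COVARIATES, build_model_table
from gwrflow.synthetic import CityConfig, generate_city

from conftest import random_regression_table


class TestGlobalOLS:
    def test_exact_linear_data(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"id": range(10), "u": x, "v": x, "y": 2 + 3 * x, "x1": x})
        fit = fit_global_ols(table, "y", ["x1"])
        assert fit.coefficients["intercept"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["x1"] == pytest.approx(3.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_gives_zero_slopes_and_r2(self, rng):
        table = random_regression_table(rng)
        table["y"] = 5.0
        fit = fit_global_ols(table, "y", ["x0", "x1", "x2"])
        assert fit.r_squared == 0.0
        np.testing.assert_allclose(fit.coefficients[["x0", "x1", "x2"]], 0.0, atol=1e-10)

    def test_matches_pseudoinverse_oracle(self, rng):
        table = random_regression_table(rng, n=20, k=3)
        fit = fit_global_ols(table, "y", ["x0", "x1", "x2"])
        Xd = np.column_stack([np.ones(20), table[["x0", "x1", "x2"]].to_numpy()])
        beta = np.linalg.pinv(Xd) @ table["y"].to_numpy()
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta, rtol=1e-10)

    def test_rank_deficiency_names_offender(self, rng):
        table = random_regression_table(rng)
        table["x_dup"] = 2.0 * table["x0"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_global_ols(table, "y", ["x0", "x1", "x2", "x_dup"])


class TestKernelWeights:
    def test_bisquare_shape(self):
        # 5 sites on a line; adaptive bandwidth 3 at site 0 -> radius is d to 3rd nn (incl self)
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [3.0, 0], [4.0, 0]])
        w = kernel_weights(0, coords, KernelSpec("adaptive", 3))
        assert w[0] == 1.0  # self weight at d = 0
        assert w[2] == 0.0 and w[3] == 0.0  # compact support at and beyond the radius
        assert w[1] == pytest.approx((1 - 0.25) ** 2)  # d = radius/2 -> 0.5625

    def test_fixed_kernel_half_radius_value(self):
        coords = np.array([[0.0, 0], [5.0, 0], [20.0, 0]])
        w = kernel_weights(0, coords, KernelSpec("fixed", 10.0))
        assert w[1] == pytest.approx(0.5625)
        assert w[2] == 0.0

    def test_duplicate_coordinates_rejected(self):
        coords = np.zeros((5, 2))
        with pytest.raises(ValueError, match="jitter"):
            kernel_weights(0, coords, KernelSpec("adaptive", 3))

    def test_uniform_kernel_includes_boundary(self):
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        w = kernel_weights(0, coords, KernelSpec("adaptive", 3, "uniform"))
        np.testing.assert_array_equal(w, [1.0, 1.0, 1.0])


class TestFitGWR:
    def test_uniform_full_bandwidth_reduces_to_ols(self, rng):
        """With no spatial weighting the local model coincides with the global one."""
        for _ in range(5):
            table = random_regression_table(rng, n=25, k=2)
            glob = fit_global_ols(table, "y", ["x0", "x1"])
            res = fit_gwr(table, "y", ["x0", "x1"], KernelSpec("adaptive", 25, "uniform"))
            for name in ("intercept", "x0", "x1"):
                np.testing.assert_allclose(
                    res.local[f"beta_{name}"], glob.coefficients[name], rtol=1e-8
                )
            assert res.local["local_r2"].iloc[0] == pytest.approx(glob.r_squared, abs=1e-10)

    def test_local_fit_matches_wls_oracle_per_site(self, rng):
        """Each local solve equals an independent weighted least-squares fit."""
        table = random_regression_table(rng, n=30, k=2)
        spec = KernelSpec("adaptive", 12)
        res = fit_gwr(table, "y", ["x0", "x1"], spec)
        coords = table[["u", "v"]].to_numpy()
        Xd = np.column_stack([np.ones(30), table[["x0", "x1"]].to_numpy()])
        y = table["y"].to_numpy()
        for i in (0, 7, 29):
            w = kernel_weights(i, coords, spec)
            wls = sm.WLS(y, Xd, weights=w).fit()
            np.testing.assert_allclose(
                res.local.iloc[i][["beta_intercept", "beta_x0", "beta_x1"]].to_numpy().astype(float),
                wls.params,
                rtol=1e-10,
            )
            # sandwich standard errors against an explicit matrix oracle
            A = (Xd.T * w) @ Xd
            C = np.linalg.inv(A) @ (Xd.T * w)
            se_expected = np.sqrt(res.sigma2 * np.diag(C @ C.T))
            np.testing.assert_allclose(
                res.local.iloc[i][["se_intercept", "se_x0", "se_x1"]].to_numpy().astype(float),
                se_expected,
                rtol=1e-10,
            )

    def test_small_explicit_weighted_normal_equations(self):
        """n = 6, one covariate: brute-force solve of the weighted normal equations."""
        table = pd.DataFrame(
            {
                "id": list("abcdef"),
                "u": [0.0, 1, 2, 3, 4, 5],
                "v": [0.0] * 6,
                "y": [1.0, 2.2, 2.9, 4.1, 5.2, 5.8],
                "x1": [0.0, 1, 2, 3, 4, 5],
            }
        )
        spec = KernelSpec("adaptive", 4)
        res = fit_gwr(table, "y", ["x1"], spec)
        coords = table[["u", "v"]].to_numpy()
        Xd = np.column_stack([np.ones(6), table["x1"].to_numpy()])
        y = table["y"].to_numpy()
        for i in range(6):
            w = kernel_weights(i, coords, spec)
            A = (Xd.T * w) @ Xd
            b = (Xd.T * w) @ y
            beta = np.linalg.solve(A, b)
            np.testing.assert_allclose(
                res.local.iloc[i][["beta_intercept", "beta_x1"]].to_numpy().astype(float),
                beta,
                rtol=1e-10,
            )

    def test_recovers_gaussian_bump_surface(self):
        """Spatially varying walkscore effect is recovered at the study bandwidth."""
        city = generate_city(CityConfig(seed=11, noise_sd=10.0))
        table, _ = build_model_table(city.table)
        res = fit_gwr(table, "normalized_obese", DEFAULT_COVARIATES, KernelSpec("adaptive", 50))
        true = city.true_surfaces.set_index("id").loc[table["id"], "beta_obese_walkscore"]
        corr = np.corrcoef(true, res.local["beta_walkscore"])[0, 1]
        assert corr >= 0.7

    def test_constant_coefficients_recovered_without_bias(self):
        """Spatially constant effects are estimated with small noise-relative bias."""
        surfaces = {
            name: {"kind": "constant", "value": v}
            for name, v in [
                ("education_norm", 0.06), ("immigrants_norm", 0.08), ("income", -0.12),
                ("fastfood_exposure", 0.01), ("park_exposure", -0.02),
                ("walkscore", -0.5), ("pathway_km", -1.26),
            ]
        }
        city = generate_city(CityConfig(seed=5, noise_sd=10.0, coefficient_surfaces=surfaces))
        table, _ = build_model_table(city.table)
        res = fit_gwr(table, "normalized_obese", DEFAULT_COVARIATES, KernelSpec("adaptive", 50))
        for name, true_val in [("walkscore", -0.5), ("pathway_km", -1.26)]:
            mean_abs_bias = abs(res.local[f"beta_{name}"].mean() - true_val)
            mean_se = res.local[f"se_{name}"].mean()
            assert mean_abs_bias <= 2 * mean_se

    def test_hat_trace_and_local_r2_bounds(self, model_table, obesity_fit):
        n, p = obesity_fit.nobs, len(obesity_fit.coefficient_names)
        assert p <= obesity_fit.tr_S <= n
        r2 = obesity_fit.local["local_r2"]
        assert ((r2 >= 0) & (r2 <= 1)).all()

    def test_locally_constant_covariate_flagged_not_fatal(self, rng):
        table = random_regression_table(rng, n=20, k=2)
        table["x_const"] = np.where(table.index < 10, 0.0, 1.0)
        # global design full rank, but some kernels see a constant column
        table["u"] = np.arange(20.0) * 10
        table["v"] = 0.0
        res = fit_gwr(table, "y", ["x0", "x1", "x_const"], KernelSpec("adaptive", 6))
        assert res.local["beta_x_const"].isna().any()
        assert res.local["beta_x0"].notna().all()


class TestBandwidthSelection:
    def test_single_candidate(self, model_table):
        bw = select_bandwidth_aicc(model_table, "normalized_obese", DEFAULT_COVARIATES, [50])
        assert bw == 50

    def test_exhaustive_argmin_oracle(self):
        """Chosen bandwidth equals the argmin of an independent full-hat-matrix AICc."""
        city = generate_city(CityConfig(n_neighbourhoods=60, seed=21, noise_sd=15.0))
        table, _ = build_model_table(city.table)
        covs = ["walkscore", "income"]
        candidates = [15, 30, 55]
        chosen = select_bandwidth_aicc(table, "normalized_obese", covs, candidates)
        assert chosen in candidates
        # independent route: build the full smoother matrix S explicitly
        coords = table[["u", "v"]].to_numpy()
        Xd = np.column_stack([np.ones(len(table)), table[covs].to_numpy()])
        y = table["normalized_obese"].to_numpy()
        n = len(y)
        aiccs = {}
        for bw in candidates:
            S = np.empty((n, n))
            for i in range(n):
                w = kernel_weights(i, coords, KernelSpec("adaptive", bw))
                S[i] = Xd[i] @ np.linalg.solve((Xd.T * w) @ Xd, Xd.T * w)
            resid = y - S @ y
            tr = np.trace(S)
            sigma = np.sqrt(resid @ resid / n)
            aiccs[bw] = 2 * n * np.log(sigma) + n * np.log(2 * np.pi) + n * (n + tr) / (n - 2 - tr)
        assert chosen == min(sorted(aiccs), key=lambda b: (aiccs[b], -b))

    def test_empty_candidates_rejected(self, model_table):
        with pytest.raises(ValueError):
            select_bandwidth_aicc(model_table, "normalized_obese", DEFAULT_COVARIATES, [])


class TestSignificance:
    @pytest.mark.parametrize(
        "t,cls",
        [(0.0, 0), (1.5, 0), (1.7, 90), (2.0, 95), (2.5, 95), (3.0, 99), (-3.0, 99), (-2.0, 95)],
    )
    def test_step_function(self, t, cls):
        assert classify_significance(t) == cls

    def test_sign_invariance(self):
        for t in (0.5, 1.8, 2.2, 4.0):
            assert classify_significance(t) == classify_significance(-t)

    def test_non_finite_warns_class_zero(self):
        with pytest.warns(UserWarning):
            assert classify_significance(np.nan) == 0


class TestSummary:
    def _fake_results(self, values):
        local = pd.DataFrame(
            {"beta_walkscore": values, "local_r2": np.linspace(0.1, 0.6, len(values))},
            index=pd.Index([f"N{i}" for i in range(len(values))], name="id"),
        )
        return GWRResults(
            local=local, response="normalized_obese", covariates=("walkscore",),
            spec=KernelSpec(), tr_S=5.0, sigma2=1.0, aicc=0.0, nobs=len(values),
            coefficient_names=("walkscore",),
        )

    def test_range_is_max_minus_min(self):
        res = self._fake_results([-1.59, 0.77, -0.05])
        coef = summarize_gwr(res).coefficients.loc["walkscore"]
        assert coef["range"] == pytest.approx(coef["max"] - coef["min"])
        assert coef["range"] == pytest.approx(2.36)

    def test_constant_collection(self):
        res = self._fake_results([0.4, 0.4, 0.4, 0.4])
        coef = summarize_gwr(res).coefficients.loc["walkscore"]
        assert coef["range"] == 0.0
        assert coef["mean"] == pytest.approx(0.4)


class TestCorrelationDiagnostics:
    def test_identity_and_perfect_negative(self, rng):
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=50)})
        corr, flagged = correlation_diagnostics(table, ["a", "b", "c"])
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert ("a", "b") in {(p[0], p[1]) for p in flagged}

    def test_zero_variance_column_reported_missing(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=20), "z": np.ones(20)})
        corr, _ = correlation_diagnostics(table, ["a", "z"])
        assert np.isnan(corr.loc["a", "z"])

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(99)
        table = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        corr, flagged = correlation_diagnostics(table, list("abcd"), threshold=0.5)
        assert flagged == []
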