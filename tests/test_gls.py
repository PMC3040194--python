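"""GLS fitting, likelihoods, information criteria, F-tests and d estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from phyloancova import (
    SimConfig,
    TraitTable,
    aicc,
    build_design,
    estimate_d,
    fit_gls,
    log_likelihood,
    lrt_signal,
    ou_covariance,
    partial_f_test,
    profiled_lnml,
    bm_covariance,
    simulate_dataset,
    simulate_tree,
    star_covariance,
)
from phyloancova.gls import DesignMatrix, RankDeficiencyError
from phyloancova.synthdata import assign_factors, simulate_traits


def design_from_array(X, names):
    return DesignMatrix(np.asarray(X, dtype=float), tuple(names), (), {})


class TestTraitTable:
    def test_rejects_out_of_range_hct(self):
        df = pd.DataFrame(
            {"species": ["a"], "hct": [120.0], "habitat": ["Marine"], "clade": ["Elapidae"]}
        )
        with pytest.raises(ValueError, match="hct outside"):
            TraitTable(df)
        TraitTable(df, check_range=False)  # relaxed mode for synthetic tables

    def test_unknown_level_error_names_row(self):
        df = pd.DataFrame(
            {
                "species": ["a", "b"],
                "hct": [25.0, 30.0],
                "habitat": ["Terrestrial", "Pelagic"],
                "clade": ["Elapidae", "Elapidae"],
            }
        )
        with pytest.raises(ValueError, match=r"row 1 \(b\)"):
            TraitTable(df)

    def test_duplicate_species_rejected(self):
        df = pd.DataFrame(
            {
                "species": ["a", "a"],
                "hct": [25.0, 30.0],
                "habitat": ["Terrestrial"] * 2,
                "clade": ["Elapidae"] * 2,
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            TraitTable(df)


class TestDesign:
    def test_base_group_row_is_intercept_only(self, small_traits):
        X = build_design(small_traits)
        row = X.matrix[0]  # Terrestrial Colubrinae
        assert row[0] == 1 and not row[1:].any()

    def test_marine_elapid_row(self, small_traits):
        X = build_design(small_traits)
        row = X.matrix[2]
        on = {X.columns[i] for i in np.nonzero(row)[0]}
        assert on == {"Y-intercept", "Marine", "Elapidae"}

    def test_full_design_shape_and_order(self, small_traits):
        X = build_design(small_traits)
        assert X.columns == (
            "Y-intercept",
            "Semi-aquatic",
            "Aquatic",
            "Marine",
            "Boidae",
            "Acrochordidae",
            "Viperidae",
            "Homalopsidae",
            "Elapidae",
            "Natricinae",
        )
        assert X.matrix.shape == (6, 10)

    def test_sixty_seven_species_residual_df(self):
        # a 67-row table covering every level: residual df = 67 - 10 = 57
        rng = np.random.default_rng(0)
        habitats = list(
            rng.permutation(
                np.r_[
                    ["Terrestrial"] * 30, ["Semi-aquatic"] * 15, ["Aquatic"] * 2, ["Marine"] * 20
                ]
            )
        )
        clades = list(
            np.r_[
                ["Colubrinae"] * 20,
                ["Natricinae"] * 8,
                ["Elapidae"] * 19,
                ["Homalopsidae"] * 2,
                ["Viperidae"] * 12,
                ["Acrochordidae"] * 3,
                ["Boidae"] * 3,
            ]
        )
        traits = TraitTable(
            pd.DataFrame(
                {
                    "species": [f"sp{i}" for i in range(67)],
                    "hct": rng.uniform(15, 45, 67),
                    "habitat": habitats,
                    "clade": clades,
                }
            )
        )
        X = build_design(traits)
        assert X.matrix.shape == (67, 10)
        fit = fit_gls(traits.hct, X, star_covariance(traits.species))
        assert fit.n - fit.p == 57

    def test_intercept_only_design(self, small_traits):
        X = build_design(small_traits, ())
        assert X.columns == ("Y-intercept",)


class TestOLSEquivalence:
    def test_intercept_only_recovers_mean(self, small_traits):
        X = build_design(small_traits, ())
        fit = fit_gls(small_traits.hct, X, star_covariance(small_traits.species))
        assert fit.beta[0] == pytest.approx(small_traits.hct.mean(), abs=1e-12)
        assert fit.r2 == 0.0

    def test_longhand_five_point_oracle(self):
        # one dummy regressor; normal equations worked by hand:
        # X'X = [[5, 2], [2, 2]], X'y = [[20], [14]]
        # inv(X'X) = 1/6 [[2, -2], [-2, 5]] -> beta = (2, 5)
        # fitted (2,2,2,7,7), residuals (-1,0,1,-1,1) -> SSE = 4
        y = np.array([1.0, 2.0, 3.0, 6.0, 8.0])
        X = design_from_array(np.c_[np.ones(5), [0, 0, 0, 1, 1]], ["int", "g"])
        fit = fit_gls(y, X, star_covariance(("a", "b", "c", "d", "e")))
        assert fit.beta == pytest.approx([2.0, 5.0], abs=1e-9)
        assert fit.sse == pytest.approx(4.0, abs=1e-9)
        mse = 4.0 / 3.0
        assert fit.mse == pytest.approx(mse, abs=1e-12)
        se = np.sqrt(mse * np.array([2.0 / 6.0, 5.0 / 6.0]))
        assert fit.se_beta == pytest.approx(se, abs=1e-9)

    def test_matches_statsmodels_on_random_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 40
        g = rng.integers(0, 3, n)
        X = np.c_[np.ones(n), g == 1, g == 2].astype(float)
        y = 25 + 3 * (g == 1) - 2 * (g == 2) + rng.normal(0, 2, n)
        res = sm.OLS(y, X).fit()
        fit = fit_gls(y, design_from_array(X, ["int", "g1", "g2"]),
                      star_covariance(tuple(map(str, range(n)))))
        assert fit.beta == pytest.approx(res.params, abs=1e-9)
        assert fit.se_beta == pytest.approx(res.bse, abs=1e-9)
        assert fit.r2 == pytest.approx(res.rsquared, abs=1e-9)

    def test_rank_deficiency_reported_with_columns(self):
        X = design_from_array(np.c_[np.ones(4), [1, 1, 1, 1]], ["int", "dup"])
        with pytest.raises(RankDeficiencyError, match="dup"):
            fit_gls(np.arange(4.0), X, star_covariance(("a", "b", "c", "d")))


class TestLikelihood:
    def test_profiled_formula_reproduces_table_style_identity(self):
        # intercept-only model with MSE 30.71 on 66 df at n = 67
        assert profiled_lnml(30.71 * 66, 67) == pytest.approx(-209.29, abs=0.01)

    def test_habitat_row_identity_within_input_rounding(self):
        # the printed MSE 23.01 is rounded to 2 dp; propagating +-0.005
        # through -(n/2) ln(MSE * (n-p)/n ...) moves lnML by up to ~0.008
        assert profiled_lnml(23.01 * 63, 67) == pytest.approx(-198.05, abs=0.015)

    def test_matches_unprofiled_numeric_maximization(self):
        # small instance: the profiled lnML equals the MVN likelihood
        # maximized numerically over (beta, sigma2)
        tree = simulate_tree(SimConfig(seed=9, n_tips=6, n_clades=2)).rescaled_to_unit_height()
        V = ou_covariance(tree, 0.6)
        rng = np.random.default_rng(2)
        X = design_from_array(np.c_[np.ones(6), [0, 1, 0, 1, 0, 1]], ["int", "g"])
        y = X.matrix @ np.array([25.0, 4.0]) + rng.multivariate_normal(np.zeros(6), 4 * V.matrix)

        Vinv = np.linalg.inv(V.matrix)
        sign, logdetV = np.linalg.slogdet(V.matrix)

        def negll(theta):
            beta, logs2 = theta[:2], theta[2]
            s2 = math.exp(logs2)
            r = y - X.matrix @ beta
            return 0.5 * (6 * math.log(2 * math.pi * s2) + logdetV + r @ Vinv @ r / s2)

        best = optimize.minimize(negll, x0=np.array([20.0, 0.0, 1.0]), method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert log_likelihood(y, X, V) == pytest.approx(-best.fun, abs=1e-6)


class TestAICc:
    def test_habitat_row_values(self):
        aic, aicc_ = aicc(-198.05, 5, 67)
        assert aic == pytest.approx(406.11, abs=0.01)
        assert aicc_ == pytest.approx(407.09, abs=0.01)

    def test_full_model_value(self):
        assert aicc(-183.20, 11, 67)[1] == pytest.approx(393.19, abs=0.01)

    def test_correction_vanishes_for_large_n(self):
        aic, aicc_ = aicc(-100.0, 5, 10**7)
        assert aicc_ - aic == pytest.approx(0.0, abs=1e-4)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_fitresult_identities_hold_exactly(self, default_dataset):
        tree, traits = default_dataset
        X = build_design(traits, ("habitat",), drop_unobserved=True)
        for V in (star_covariance(traits.species), bm_covariance(tree.rescaled_to_unit_height())):
            fit = fit_gls(traits.hct, X, V)
            assert fit.see == pytest.approx(math.sqrt(fit.mse), abs=1e-12)
            assert fit.aic == pytest.approx(-2 * fit.lnml + 2 * fit.k, abs=1e-10)
            assert fit.aicc == pytest.approx(
                fit.aic + 2 * fit.k * (fit.k + 1) / (fit.n - fit.k - 1), abs=1e-10
            )
            assert fit.k == fit.p + 1
            assert 0.0 <= fit.r2 <= 1.0


class TestPartialF:
    def test_single_column_equals_t_squared(self, small_traits):
        X = build_design(small_traits, ("habitat",))
        V = star_covariance(small_traits.species)
        fit = fit_gls(small_traits.hct, X, V)
        i = X.columns.index("Marine")
        ft = partial_f_test(small_traits.hct, X, V, ["Marine"])
        assert ft.f == pytest.approx((fit.beta[i] / fit.se_beta[i]) ** 2, abs=1e-9)
        assert ft.df_num == 1 and ft.df_den == fit.n - fit.p

    def test_matches_brute_force_refit(self):
        rng = np.random.default_rng(11)
        n = 12
        X = np.c_[np.ones(n), rng.integers(0, 2, n), rng.integers(0, 2, n)].astype(float)
        y = X @ [10.0, 2.0, -1.0] + rng.normal(0, 1, n)
        D = design_from_array(X, ["int", "u", "v"])
        V = star_covariance(tuple(map(str, range(n))))
        ft = partial_f_test(y, D, V, ["u", "v"])
        # longhand: residual sums of squares from explicit normal equations
        def sse(M):
            b = np.linalg.solve(M.T @ M, M.T @ y)
            r = y - M @ b
            return r @ r

        sse_full, sse_red = sse(X), sse(X[:, :1])
        f = ((sse_red - sse_full) / 2) / (sse_full / (n - 3))
        assert ft.f == pytest.approx(f, abs=1e-9)

    def test_r2_non_decreasing_with_added_columns(self, default_dataset):
        tree, traits = default_dataset
        V = bm_covariance(tree.rescaled_to_unit_height())
        fits = [
            fit_gls(traits.hct, build_design(traits, fs, drop_unobserved=True), V)
            for fs in [(), ("habitat",), ("habitat", "clade")]
        ]
        assert fits[0].r2 <= fits[1].r2 + 1e-12 <= fits[2].r2 + 1e-12


class TestSignal:
    def test_lrt_on_reported_likelihood_pair(self):
        stat, p = lrt_signal(-208.24, -209.29)
        assert stat == pytest.approx(2.10, abs=1e-9)
        assert p > 0.05

    def test_equal_likelihoods_give_unit_p(self):
        stat, p = lrt_signal(-100.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_quantile_cross_check(self):
        # independent CDF evaluation: chi2(1) upper tail at x is erfc(sqrt(x/2))
        _, p = lrt_signal(-100.0, -100.0 - 3.841 / 2)
        assert p == pytest.approx(math.erfc(math.sqrt(3.841 / 2)), abs=1e-12)
        assert p == pytest.approx(0.050, abs=0.001)

    def test_ml_surface_nesting(self):
        # lnML at the ML-optimal d dominates both endpoint models
        for seed, d_true in [(21, 0.0), (22, 0.5), (23, 1.0)]:
            tree, traits = simulate_dataset(SimConfig(seed=seed, n_tips=40, d_true=d_true))
            unit = tree.rescaled_to_unit_height()
            X = build_design(traits, ("habitat",), drop_unobserved=True)
            _, fit = estimate_d(traits.hct, X, unit, criterion="ml")
            ols = fit_gls(traits.hct, X, star_covariance(traits.species))
            pgls = fit_gls(traits.hct, X, bm_covariance(unit))
            assert fit.lnml >= max(ols.lnml, pgls.lnml) - 1e-6

    def test_flat_profile_prefers_smaller_d(self):
        # a star tree shares no history: V(d) is the identity for every d,
        # so the profile is flat and the smallest maximizing d is returned
        from phyloancova import parse_newick

        star = parse_newick("(A:1,B:1,C:1,D:1);")
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = design_from_array(np.ones((4, 1)), ["int"])
        d_hat, _ = estimate_d(y, X, star, criterion="ml")
        assert d_hat == 0.0


class TestDEstimation:
    def test_regou_k_counts_extra_parameter(self, default_dataset):
        tree, traits = default_dataset
        X = build_design(traits, ("habitat",), drop_unobserved=True)
        d_hat, fit = estimate_d(traits.hct, X, tree.rescaled_to_unit_height())
        assert 0.0 <= d_hat <= 1.0
        assert fit.k == fit.p + 2
        assert fit.d == d_hat

    def test_unbiased_for_fixed_design_mc(self):
        # antithetic residual pairs: the replicate-mean of beta-hat must sit
        # within 2 Monte-Carlo SEs of truth for every estimable coefficient
        cfg = SimConfig(seed=777, n_tips=40, d_true=0.3)
        rng_tree, rng_factors, _ = cfg.rngs(3)
        tree = simulate_tree(cfg, rng_tree)
        factors = assign_factors(tree, cfg, rng_factors)
        unit = tree.rescaled_to_unit_height()
        draws = []
        rng = np.random.default_rng(778)
        V = ou_covariance(unit, cfg.d_true)
        L = np.linalg.cholesky(V.matrix + 1e-12 * np.eye(V.n))
        skeleton = TraitTable(factors.assign(hct=0.0), check_range=False)
        X = build_design(skeleton, ("habitat", "clade"), drop_unobserved=True)
        beta_true = np.array([cfg.beta.get(c, 0.0) for c in X.columns])
        mu = X.matrix @ beta_true
        for _ in range(50):
            z = rng.standard_normal(V.n)
            for sign in (1.0, -1.0):
                y = mu + sign * math.sqrt(cfg.sigma2) * (L @ z)
                fit = fit_gls(y, X, V)
                draws.append(fit.beta)
        draws = np.array(draws)
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / math.sqrt(len(draws))
        assert np.all(np.abs(mean - beta_true) <= 2 * se + 1e-10)
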