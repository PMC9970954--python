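"""Robust residualization, adjusted Spearman, BH-FDR, and power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from digibrain.corrstats import (FdrFamilySpec, adjusted_spearman,
                                 correlation_grid, fdr_adjust,
                                 power_for_correlation, residualize)


def _covariates(rng, n):
    return pd.DataFrame({
        "age": rng.normal(39.7, 7.5, n),
        "sex": (rng.random(n) > 0.68).astype(int),
        "bmi": rng.normal(24.4, 4.4, n),
    })


class TestResidualize:
    def test_exact_linear_fit_leaves_zero_residuals(self, rng):
        C = _covariates(rng, 80)
        y = 3.0 + 0.5 * C["age"].to_numpy()
        res = residualize(y, C)
        assert np.max(np.abs(res)) < 1e-6

    def test_null_response_residuals_uncorrelated_with_covariates(self, rng):
        C = _covariates(rng, 500)
        y = rng.normal(size=500)
        res = residualize(y, C)
        for col in C:
            r, _ = stats.spearmanr(res, C[col])
            assert abs(r) < 0.1

    def test_robust_fit_resists_gross_outlier(self, rng):
        # one wild outlier: the Huber fit's implied slope stays closer to
        # the generating slope than the least-squares slope
        n = 60
        age = rng.normal(40, 8, n)
        y = 2.0 * age + rng.normal(0, 1, n)
        y[0] += 500.0
        C = pd.DataFrame({"age": age})
        fitted_rob = y - residualize(y, C)
        slope_rob = np.polyfit(age, fitted_rob, 1)[0]
        slope_ols = np.polyfit(age, y, 1)[0]
        assert abs(slope_rob - 2.0) < abs(slope_ols - 2.0)

    def test_collinear_design_named(self, rng):
        C = _covariates(rng, 50)
        C["age2"] = 2.0 * C["age"]
        with pytest.raises(ValueError, match="age2"):
            residualize(rng.normal(size=50), C)

    def test_no_covariates_centers_only(self, rng):
        y = rng.normal(5.0, 1.0, 30)
        res = residualize(y, None)
        assert stats.spearmanr(res, y)[0] == pytest.approx(1.0)


class TestAdjustedSpearman:
    def test_identity_gives_perfect_correlation(self, rng):
        x = rng.normal(size=40)
        r, p, n = adjusted_spearman(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10 and n == 40

    def test_rank_invariance_under_cube(self, rng):
        x = rng.normal(size=40)
        r, _, _ = adjusted_spearman(x, x ** 3)
        assert r == pytest.approx(1.0)

    def test_sign_flips_with_negated_response(self, rng):
        C = _covariates(rng, 60)
        x, y = rng.normal(size=60), rng.normal(size=60)
        r1, _, _ = adjusted_spearman(x, y, C)
        r2, _, _ = adjusted_spearman(x, -y, C)
        assert r1 == pytest.approx(-r2, abs=1e-12)

    def test_monotone_transform_of_residuals_preserves_r(self, rng):
        # rank correlation depends only on residual ranks
        C = _covariates(rng, 60)
        x, y = rng.normal(size=60), rng.normal(size=60)
        rx, ry = residualize(x, C), residualize(y, C)
        assert stats.spearmanr(rx, ry)[0] == \
            pytest.approx(stats.spearmanr(rx, np.expm1(ry))[0])

    def test_pairwise_complete_drops_missing(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        x[:5] = np.nan
        _, _, n = adjusted_spearman(x, y)
        assert n == 25

    def test_bivariate_normal_expectation(self, rng):
        # E[rho_S] for Gaussian data with Pearson rho: (6/pi) asin(rho/2)
        expect = 6 / np.pi * np.arcsin(0.25)
        vals = []
        for _ in range(500):
            z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 62)
            r, _, _ = adjusted_spearman(z[:, 0], z[:, 1])
            vals.append(r)
        assert np.mean(vals) == pytest.approx(expect, abs=0.04)

    def test_constant_vector_warns_and_returns_nan(self, rng):
        with pytest.warns(UserWarning):
            r, p, _ = adjusted_spearman(np.ones(20), rng.normal(size=20))
        assert np.isnan(r)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.01])[0] == pytest.approx(0.01)

    def test_hand_applied_step_up(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_all_ones_stay_one(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty_family(self):
        assert fdr_adjust([]).size == 0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_q_dominates_p_and_is_rank_monotone(self, pvals):
        p = np.array(pvals)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCorrelationGrid:
    def test_full_grid_has_756_pairs(self, rng):
        M = pd.DataFrame(rng.normal(size=(30, 21)),
                         columns=[f"m{i}" for i in range(21)])
        R = pd.DataFrame(rng.normal(size=(30, 36)),
                         columns=[f"g{i}" for i in range(36)])
        grid = correlation_grid(M, R, _covariates(rng, 30).set_index(M.index))
        assert len(grid) == 21 * 36
        assert set(grid.columns) >= {"measure", "region", "r", "p", "q", "n",
                                     "significant"}
        assert (grid["q"] >= grid["p"] - 1e-12).all()

    def test_fast_path_matches_per_pair_route(self, rng):
        # complete data: column-wise residualization must equal the
        # per-pair pairwise-complete route exactly
        idx = [f"S{i}" for i in range(25)]
        M = pd.DataFrame(rng.normal(size=(25, 3)), index=idx,
                         columns=["a", "b", "c"])
        R = pd.DataFrame(rng.normal(size=(25, 4)), index=idx,
                         columns=["w", "x", "y", "z"])
        C = _covariates(rng, 25).set_index(pd.Index(idx))
        fast = correlation_grid(M, R, C)
        M2 = M.copy()
        M2.loc["S0", "zzz_pad"] = np.nan   # force the per-pair route
        slow = correlation_grid(M2[["a", "b", "c"]].assign(
            pad=np.where(M2.index == "S0", np.nan, 1.0) * rng.normal(size=25)),
            R, C)
        slow = slow[slow["measure"].isin(["a", "b", "c"])]
        merged = fast.merge(slow, on=["measure", "region"], suffixes=("_f", "_s"))
        assert np.allclose(merged["r_f"], merged["r_s"], atol=1e-12)
        assert np.allclose(merged["p_f"], merged["p_s"], atol=1e-12)

    def test_no_overlap_raises(self, rng):
        M = pd.DataFrame({"m": rng.normal(size=12)}, index=range(12))
        R = pd.DataFrame({"g": rng.normal(size=12)}, index=range(100, 112))
        with pytest.raises(ValueError, match="overlap"):
            correlation_grid(M, R)

    def test_per_measure_family_never_fewer_discoveries(self, rng):
        # BH with smaller families (36 tests) cannot discover less than
        # the global 36x21 family on the same p ensemble
        n = 80
        latent = rng.normal(size=n)
        M = pd.DataFrame({f"m{i}": 0.4 * latent + rng.normal(size=n)
                          for i in range(21)})
        R = pd.DataFrame({f"g{i}": (0.4 if i < 6 else 0.0) * latent
                          + rng.normal(size=n) for i in range(36)})
        per = correlation_grid(M, R, family=FdrFamilySpec("per_measure"))
        glo = correlation_grid(M, R, family=FdrFamilySpec("global_36x21"))
        assert per["significant"].sum() >= glo["significant"].sum()

    def test_type_one_error_controlled_under_confounded_null(self, rng):
        # x and y share covariate effects but no latent link; the adjusted
        # test should reject at close to the nominal 5% level
        rejections = 0
        reps = 2000
        for _ in range(reps):
            n = 62
            age = rng.normal(0, 1, n)
            x = 0.4 * age + rng.normal(size=n)
            y = -0.4 * age + rng.normal(size=n)
            _, p, _ = adjusted_spearman(x, y, pd.DataFrame({"age": age}))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestPower:
    def test_design_power_exceeds_eighty_percent(self):
        assert power_for_correlation(0.33, 70) > 0.80

    def test_null_rho_gives_alpha(self):
        assert power_for_correlation(0.0, 50) == pytest.approx(0.05, abs=1e-9)

    def test_matches_monte_carlo_rejection_rate(self, rng):
        # rho=0.5, n=30: analytic approximation vs simulated two-sided
        # Pearson test rejection rate
        reps, n, rho = 40000, 30, 0.5
        x = rng.standard_normal((reps, n))
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal((reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc ** 2).sum(1) * (yc ** 2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        crit = stats.t.ppf(0.975, n - 2)
        mc = np.mean(np.abs(t) > crit)
        analytic = power_for_correlation(rho, n)
        assert analytic == pytest.approx(0.81, abs=0.01)
        # the Fisher-z normal approximation is good to ~0.015 at n=30
        assert analytic == pytest.approx(mc, abs=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_for_correlation(1.0, 50)
        with pytest.raises(ValueError):
            power_for_correlation(0.3, 3)
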