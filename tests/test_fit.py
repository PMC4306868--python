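"""Estimation: OLS and sandwich oracles, ACE recovery, invariances."""

import numpy as np
import pandas as pd
import pytest

from dftwin import (
    CovariateSpec,
    DeFriesFulkerModel,
    DFModelSpec,
    RankDeficiencyError,
    SimulationConfig,
    cluster_robust_cov,
    decompose_variance,
    fit_df,
    ols_fit,
    simulate_pairs,
)


def _normal_equations(X, y):
    """Independent least-squares oracle: solve X'X b = X'y directly."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def _meat_by_loop(X, u, groups):
    """Independent sandwich-meat oracle: explicit loop over clusters."""
    X = np.asarray(X, float)
    k = X.shape[1]
    meat = np.zeros((k, k))
    for g in np.unique(groups):
        sel = np.asarray(groups) == g
        s = X[sel].T @ u[sel]
        meat += np.outer(s, s)
    return meat


def _sandwich_by_loop(X, u, groups, correction="cr1"):
    X = np.asarray(X, float)
    n, k = X.shape
    bread = np.linalg.inv(X.T @ X)
    cov = bread @ _meat_by_loop(X, u, groups) @ bread
    if correction == "cr1":
        G = len(np.unique(groups))
        cov *= (G / (G - 1)) * ((n - 1) / (n - k))
    return cov


@pytest.fixture
def fixed_system():
    """Fixed 6-row, 3-cluster numeric fixture."""
    X = np.array(
        [
            [1.0, 0.5, 2.0],
            [1.0, -1.0, 0.0],
            [1.0, 2.0, 1.0],
            [1.0, 0.0, -1.0],
            [1.0, 1.5, 0.5],
            [1.0, -0.5, 1.0],
        ]
    )
    y = np.array([1.0, 0.0, 3.0, -1.0, 2.0, 0.5])
    groups = np.array([0, 0, 1, 1, 2, 2])
    return X, y, groups


class TestOLS:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 2))])
        y = rng.standard_normal(50)
        beta, resid, r2 = ols_fit(X, y)
        np.testing.assert_allclose(beta, _normal_equations(X, y), atol=1e-8)
        # residuals orthogonal to the design
        np.testing.assert_allclose(X.T @ resid, 0, atol=1e-8)

    def test_exact_fit_recovers_column(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        beta, _, r2 = ols_fit(X, X[:, 1])
        np.testing.assert_allclose(beta, [0.0, 1.0, 0.0], atol=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_intercept_only_response(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.full(10, 3.5)
        beta, _, r2 = ols_fit(X, y)
        np.testing.assert_allclose(beta, [3.5, 0.0], atol=1e-12)
        assert r2 == pytest.approx(0.0)

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(RankDeficiencyError):
            ols_fit(X, np.arange(10.0))


class TestClusterRobust:
    def test_matches_loop_oracle_on_fixture(self, fixed_system):
        X, y, groups = fixed_system
        beta, resid, _ = ols_fit(X, y)
        for correction in ("cr0", "cr1"):
            cov = cluster_robust_cov(X, resid, groups, correction)
            np.testing.assert_allclose(
                cov, _sandwich_by_loop(X, resid, groups, correction), atol=1e-10
            )

    def test_singleton_clusters_reduce_to_hc0(self, fixed_system):
        X, y, _ = fixed_system
        beta, resid, _ = ols_fit(X, y)
        cov = cluster_robust_cov(X, resid, np.arange(len(y)), "cr0")
        bread = np.linalg.inv(X.T @ X)
        hc0 = bread @ (X * resid[:, None] ** 2).T @ X @ bread
        np.testing.assert_allclose(cov, hc0, atol=1e-12)

    def test_matches_statsmodels_cluster_oracle(self, fixed_system):
        sm = pytest.importorskip("statsmodels.api")
        X, y, groups = fixed_system
        beta, resid, _ = ols_fit(X, y)
        fit = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
        np.testing.assert_allclose(beta, fit.params, atol=1e-10)
        np.testing.assert_allclose(
            cluster_robust_cov(X, resid, groups, "cr1"), fit.cov_params(), atol=1e-12
        )

    def test_cluster_duplication_shrinks_ses_predictably(self, fixed_system):
        # duplicating every cluster leaves estimates unchanged; the sandwich
        # matches the loop oracle recomputed on the duplicated data
        X, y, groups = fixed_system
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        g2 = np.concatenate([groups, groups + 10])
        b1, *_ = ols_fit(X, y)
        b2, resid2, _ = ols_fit(X2, y2)
        np.testing.assert_allclose(b1, b2, atol=1e-10)
        cov2 = cluster_robust_cov(X2, resid2, g2, "cr0")
        np.testing.assert_allclose(cov2, _sandwich_by_loop(X2, resid2, g2, "cr0"), atol=1e-12)
        cov1 = cluster_robust_cov(X, y - X @ b1, groups, "cr0")
        np.testing.assert_allclose(cov2, cov1 / 2, atol=1e-12)

    def test_single_cluster_rejected(self, fixed_system):
        X, y, _ = fixed_system
        _, resid, _ = ols_fit(X, y)
        with pytest.raises(ValueError):
            cluster_robust_cov(X, resid, np.zeros(len(y)), "cr1")


class TestDecomposeVariance:
    def test_baseline_shares_sum_to_one(self):
        out = decompose_variance({"K2_centered": 0.44, "R_x_K2_centered": 0.27})
        assert out == {"c2": 0.44, "h2": 0.27, "residual": pytest.approx(0.29)}

    def test_pure_nonshared_world(self):
        out = decompose_variance({"K2_centered": 0.0, "R_x_K2_centered": 0.0})
        assert out["residual"] == 1.0

    def test_out_of_range_passed_through_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            out = decompose_variance({"K2_centered": 0.6, "R_x_K2_centered": 0.5})
        assert out["residual"] == pytest.approx(-0.1)

    def test_eq1_routes_heritability_from_interaction(self):
        out = decompose_variance({"K2": 0.4, "R": 5.0, "R_x_K2": 0.3}, variant="eq1")
        assert out == {"c2": 0.4, "h2": 0.3, "residual": pytest.approx(0.3)}


class TestFitDF:
    def test_recovers_ace_shares_and_falconer_agreement(self, ace_sample):
        res = DeFriesFulkerModel(ace_sample).fit()
        assert res.variance_components["h2"] == pytest.approx(0.3, abs=0.07)
        assert res.variance_components["c2"] == pytest.approx(0.4, abs=0.07)
        wide = ace_sample.pivot_table(
            index=["pair_id", "zygosity"], columns="twin_index", values="outcome"
        ).reset_index()
        r = {z: wide[wide.zygosity == z][[1, 2]].corr().iloc[0, 1] for z in ("MZ", "DZ")}
        falconer_h2 = 2 * (r["MZ"] - r["DZ"])
        assert res.variance_components["h2"] == pytest.approx(falconer_h2, abs=0.04)

    def test_nobs_counts_twins_and_pairs(self, ace_sample):
        res = DeFriesFulkerModel(ace_sample).fit()
        assert res.nobs == 2 * res.n_pairs == 2 * ace_sample["pair_id"].nunique()
        assert res.df_resid == res.n_pairs - 1

    def test_location_scale_invariance_of_shares(self, ace_sample):
        base = DeFriesFulkerModel(ace_sample).fit()
        shifted = ace_sample.assign(outcome=ace_sample.outcome * 17.0 + 100.0)
        other = DeFriesFulkerModel(shifted).fit()
        assert other.variance_components["c2"] == pytest.approx(
            base.variance_components["c2"], abs=1e-10
        )
        assert other.variance_components["h2"] == pytest.approx(
            base.variance_components["h2"], abs=1e-10
        )
        assert other.params["intercept"] != pytest.approx(base.params["intercept"])

    def test_row_shuffle_and_member_order_invariance(self, ace_sample):
        base = DeFriesFulkerModel(ace_sample).fit()
        rng = np.random.default_rng(0)
        shuffled = ace_sample.sample(frac=1.0, random_state=3)
        swap = rng.random(len(ace_sample) // 2) < 0.5
        swapped = ace_sample.copy()
        idx = np.repeat(swap, 2)
        swapped.loc[idx, "twin_index"] = swapped.loc[idx, "twin_index"].map({1: 2, 2: 1})
        for variant in (shuffled, swapped):
            res = DeFriesFulkerModel(variant).fit()
            pd.testing.assert_series_equal(res.params, base.params, atol=1e-10, rtol=0)
            pd.testing.assert_series_equal(res.bse, base.bse, atol=1e-10, rtol=0)

    def test_envdif_coefficient_recovery(self):
        cfg = SimulationConfig(
            n_mz_pairs=2000, n_dz_pairs=2000, h2=0.3, c2=0.4, e2=0.3,
            covariates=(CovariateSpec("x", "count", {"n": 7, "p": 0.3}, beta=-1.0),),
            percentile_output=False, seed=77,
        )
        res = DeFriesFulkerModel(simulate_pairs(cfg), envdif=("x",)).fit()
        assert res.params["envdif_x"] == pytest.approx(-1.0, abs=0.15)
        assert res.pvalues["envdif_x"] < 0.01

    def test_single_zygosity_not_identifiable(self, ace_sample):
        mz = ace_sample[ace_sample.zygosity == "MZ"]
        with pytest.raises(ValueError, match="single-zygosity"):
            DeFriesFulkerModel(mz)

    def test_fit_df_functional_interface_matches_class(self, ace_sample):
        a = fit_df(ace_sample, DFModelSpec("eq2"))
        b = DeFriesFulkerModel(ace_sample, equation="eq2").fit()
        pd.testing.assert_series_equal(a.params, b.params)

    def test_summary_reports_stars_and_counts(self, ace_sample):
        res = DeFriesFulkerModel(ace_sample).fit()
        text = res.summary()
        assert "K2_centered" in text and "R_x_K2_centered" in text
        assert f"N = {res.nobs} twins ({res.n_pairs} pairs)" in text
        assert "* p<=0.05, ** p<=0.01" in text

    def test_eq1_and_eq2_agree_on_heritability(self, ace_sample):
        eq1 = DeFriesFulkerModel(ace_sample, equation="eq1").fit()
        eq2 = DeFriesFulkerModel(ace_sample).fit()
        # both parameterizations estimate the same h2 up to centering effects
        assert eq1.variance_components["h2"] == pytest.approx(
            eq2.variance_components["h2"], abs=0.05
        )
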