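"""Co-inertia/RV, Brownian covariance, PGLS, PERMANOVA, dispersal axis and
path model."""

import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import f_oneway

from reefdisparity.comparative import (
    PGLS,
    bm_covariance,
    build_paired_tables,
    coinertia,
    dispersal_axis,
    ols_fit,
    path_model,
    permanova,
    pgls_fit,
    rv_coefficient,
)
from reefdisparity.simulate import simulate_tree


def _random_orthogonal(d, rng):
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    return q


class TestRV:
    def test_self_congruence(self, rng):
        X = rng.standard_normal((10, 4))
        assert rv_coefficient(X, X) == pytest.approx(1.0)

    def test_rotation_and_scale_invariance(self, rng):
        X = rng.standard_normal((12, 5))
        Q = _random_orthogonal(5, rng)
        assert rv_coefficient(X, X @ Q) == pytest.approx(1.0, abs=1e-10)
        Y = rng.standard_normal((12, 3))
        assert rv_coefficient(X, Y) == pytest.approx(
            rv_coefficient(3.7 * X, 0.2 * Y), abs=1e-10
        )

    def test_orthogonal_cross_covariance_gives_zero(self):
        X = np.array([[1.0, 0], [-1, 0], [1, 0], [-1, 0]])
        Y = np.array([[1.0], [1], [-1], [-1]])
        assert rv_coefficient(X, Y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_table_errors(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(ValueError, match="variance"):
            rv_coefficient(X, np.ones((6, 3)))


class TestCoInertia:
    def test_singular_values_decompose_rv_numerator(self, rng):
        X, Y = rng.standard_normal((15, 4)), rng.standard_normal((15, 3))
        res = coinertia(X, Y, n_perm=9, seed=0)
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        num = np.trace((Xc.T @ Yc) @ (Yc.T @ Xc))
        assert np.sum(res.axis_covariances**2) == pytest.approx(num, rel=1e-10)

    def test_deterministic_permutation_p(self, rng):
        X, Y = rng.standard_normal((10, 3)), rng.standard_normal((10, 3))
        p1 = coinertia(X, Y, n_perm=49, seed=7).perm_p
        p2 = coinertia(X, Y, n_perm=49, seed=7).perm_p
        assert p1 == p2

    def test_invalid_n_perm(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(ValueError):
            coinertia(X, X, n_perm=0, seed=0)


class TestPairedTables:
    def _tables(self, rng):
        intra = pd.DataFrame(
            rng.uniform(0.5, 2, (4, 3)),
            index=["s1", "s2", "s3", "s4"],
            columns=["t1", "t2", "t3"],
        )
        inter = pd.DataFrame(
            rng.uniform(0.5, 2, (2, 3)), index=["fA", "fB"], columns=["t1", "t2", "t3"]
        )
        fam = pd.Series({"s1": "fA", "s2": "fA", "s3": "fB", "s4": "fC"})
        return intra, inter, fam

    def test_family_rows_replicated_and_orphans_dropped(self, rng):
        intra, inter, fam = self._tables(rng)
        with pytest.warns(UserWarning, match="s4"):
            X, Y = build_paired_tables(intra, inter, fam, mode="raw")
        assert list(X.index) == ["s1", "s2", "s3"]
        np.testing.assert_allclose(Y.loc["s1"], Y.loc["s2"])

    def test_pcoa_mode_preserves_rv(self, rng):
        intra, inter, fam = self._tables(rng)
        with pytest.warns(UserWarning):
            Xr, Yr = build_paired_tables(intra, inter, fam, mode="raw")
        with pytest.warns(UserWarning):
            Xp, Yp = build_paired_tables(intra, inter, fam, mode="pcoa")
        assert rv_coefficient(Xp.to_numpy(), Yp.to_numpy()) == pytest.approx(
            rv_coefficient(Xr.to_numpy(), Yr.to_numpy()), abs=1e-8
        )

    def test_pcoa_scores_reproduce_distances(self, rng):
        from scipy.spatial.distance import pdist

        from reefdisparity.comparative import _pcoa_scores

        tab = pd.DataFrame(rng.standard_normal((6, 4)))
        scores = _pcoa_scores(tab)
        np.testing.assert_allclose(
            pdist(scores.to_numpy()), pdist(tab.to_numpy()), atol=1e-8
        )


class TestBMCovariance:
    def test_star_tree_is_diagonal(self):
        nwk = "(a:2.0,b:2.0,c:2.0);"
        C = bm_covariance(nwk, ["a", "b", "c"])
        np.testing.assert_allclose(C.to_numpy(), 2.0 * np.eye(3), atol=1e-12)

    def test_sisters_share_root_to_mrca_path(self):
        # root -> h=1.5 -> two sisters at total depth 4; outgroup depth 4
        nwk = "((a:2.5,b:2.5):1.5,c:4.0);"
        C = bm_covariance(nwk, ["a", "b", "c"])
        assert C.loc["a", "b"] == pytest.approx(1.5)
        assert C.loc["a", "a"] == pytest.approx(4.0)
        assert C.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)

    def test_ultrametric_tree_constant_diagonal(self):
        tree = simulate_tree(8, seed=3)
        C = bm_covariance(tree, [f"sp{i + 1:02d}" for i in range(8)])
        np.testing.assert_allclose(np.diag(C.to_numpy()), 1.0, atol=1e-10)

    def test_missing_tip_listed(self):
        with pytest.raises(ValueError, match="zz"):
            bm_covariance("(a:1,b:1);", ["a", "zz"])


class TestPGLS:
    def test_identity_covariance_reproduces_ols(self, rng):
        for _ in range(10):
            n, p = 20, 3
            X = rng.standard_normal((n, p))
            y = X @ rng.standard_normal(p) + rng.standard_normal(n)
            fit = pgls_fit(y, X, covariance=np.eye(n))
            ols = sm.OLS(y, sm.add_constant(X)).fit()
            np.testing.assert_allclose(
                fit.coefficients["estimate"], ols.params, atol=1e-10
            )
            np.testing.assert_allclose(fit.coefficients["t"], ols.tvalues, atol=1e-10)

    def test_scaled_identity_same_inference(self, rng):
        n = 15
        X = rng.standard_normal((n, 2))
        y = rng.standard_normal(n)
        f1 = pgls_fit(y, X, covariance=np.eye(n))
        f2 = pgls_fit(y, X, covariance=7.3 * np.eye(n))
        np.testing.assert_allclose(
            f1.coefficients["estimate"], f2.coefficients["estimate"], atol=1e-10
        )
        np.testing.assert_allclose(f1.coefficients["t"], f2.coefficients["t"], atol=1e-8)

    def test_collinear_predictors_error(self, rng):
        X = rng.standard_normal((10, 1))
        X2 = np.hstack([X, 2 * X])
        with pytest.raises(ValueError, match="collinear|rank"):
            pgls_fit(rng.standard_normal(10), X2)

    def test_non_positive_definite_covariance_error(self, rng):
        C = np.ones((5, 5))
        with pytest.raises(ValueError, match="positive definite"):
            pgls_fit(rng.standard_normal(5), rng.standard_normal((5, 1)), covariance=C)

    def test_parameter_recovery_under_tree_correlation(self):
        """Estimates are unbiased when noise follows the tree covariance."""
        tree = simulate_tree(30, seed=9)
        tips = [f"sp{i + 1:02d}" for i in range(30)]
        C = bm_covariance(tree, tips).to_numpy()
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(4)
        b_true = 0.8
        ests = []
        for _ in range(100):
            x = rng.standard_normal(30)
            y = b_true * x + L @ rng.standard_normal(30)
            ests.append(pgls_fit(y, x, covariance=C).coef("x1"))
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - b_true) < 4 * se + 1e-3

    def test_lambda_one_is_strict_brownian(self, rng):
        tree = simulate_tree(12, seed=2)
        tips = [f"sp{i + 1:02d}" for i in range(12)]
        C = bm_covariance(tree, tips).to_numpy()
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        f_bm = pgls_fit(y, x, covariance=C)
        f_l1 = pgls_fit(y, x, covariance=C, pagel_lambda=1.0)
        np.testing.assert_allclose(
            f_bm.coefficients["estimate"], f_l1.coefficients["estimate"], atol=1e-12
        )

    def test_lambda_zero_on_ultrametric_tree_matches_ols_inference(self, rng):
        tree = simulate_tree(10, seed=4)
        tips = [f"sp{i + 1:02d}" for i in range(10)]
        C = bm_covariance(tree, tips).to_numpy()
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        f_l0 = pgls_fit(y, x, covariance=C, pagel_lambda=0.0)
        f_ols = pgls_fit(y, x)
        np.testing.assert_allclose(f_l0.coefficients["t"], f_ols.coefficients["t"], atol=1e-8)

    def test_lambda_ml_tracks_signal(self):
        """λ̂ is near 0 for iid residuals and near 1 for Brownian residuals."""
        tree = simulate_tree(40, seed=8)
        tips = [f"sp{i + 1:02d}" for i in range(40)]
        C = bm_covariance(tree, tips).to_numpy()
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(21)
        lam_iid, lam_bm = [], []
        for _ in range(10):
            x = rng.standard_normal(40)
            est_i = PGLS(covariance=C, pagel_lambda="ml").fit(x, rng.standard_normal(40))
            est_b = PGLS(covariance=C, pagel_lambda="ml").fit(
                x, L @ rng.standard_normal(40)
            )
            lam_iid.append(est_i.lambda_)
            lam_bm.append(est_b.lambda_)
        assert np.mean(lam_iid) < 0.3
        assert np.mean(lam_bm) > 0.7

    def test_sklearn_estimator_api(self, rng):
        X = rng.standard_normal((12, 2))
        y = X @ np.array([1.0, -2.0]) + 0.1 * rng.standard_normal(12)
        est = PGLS().fit(X, y)
        assert est.get_params()["covariance"] is None
        pred = est.predict(X)
        assert pred.shape == (12,)
        assert est.score(X, y) > 0.9


class TestPermanova:
    def test_univariate_hand_case(self):
        y = pd.DataFrame({"v": [1.0, 2.0, 3.0, 5.0]})
        pred = pd.DataFrame({"g": ["a", "a", "b", "b"]})
        tab = permanova(y, pred, n_perm=99, seed=0)
        assert tab.loc["g", "pseudo_f"] == pytest.approx(5.0, abs=1e-10)
        assert tab.loc["g", "ss"] == pytest.approx(6.25, abs=1e-10)
        assert tab.loc["Residual", "ss"] == pytest.approx(2.5, abs=1e-10)

    def test_pseudo_f_equals_classical_anova(self, rng):
        for _ in range(20):
            n_groups = rng.integers(2, 5)
            sizes = rng.integers(3, 7, size=n_groups)
            vals = [rng.standard_normal(s) for s in sizes]
            y = pd.DataFrame({"v": np.concatenate(vals)})
            pred = pd.DataFrame(
                {"g": np.repeat([f"g{i}" for i in range(n_groups)], sizes)}
            )
            tab = permanova(y, pred, n_perm=9, seed=0)
            F_ref = f_oneway(*vals).statistic
            assert tab.loc["g", "pseudo_f"] == pytest.approx(F_ref, abs=1e-10)

    def test_r_squared_decomposition_sums_to_one(self, rng):
        y = pd.DataFrame(rng.standard_normal((15, 4)))
        pred = pd.DataFrame(
            {"x": rng.standard_normal(15), "g": rng.choice(["a", "b", "c"], 15)}
        )
        tab = permanova(y, pred, n_perm=9, seed=1)
        terms = tab.drop(index="Total")
        assert terms["r2"].sum() == pytest.approx(1.0, abs=1e-10)
        assert terms["df"].sum() == tab.loc["Total", "df"]
        assert (terms["ss"] >= -1e-10).all()

    def test_sequential_ss_order_dependent(self, rng):
        x1 = rng.standard_normal(20)
        x2 = x1 + 0.3 * rng.standard_normal(20)
        y = pd.DataFrame({"v": x1 + rng.standard_normal(20)})
        t12 = permanova(y, pd.DataFrame({"a": x1, "b": x2}), n_perm=9, seed=0)
        t21 = permanova(y, pd.DataFrame({"b": x2, "a": x1}), n_perm=9, seed=0)
        # first-entered correlated term absorbs the shared SS
        assert t12.loc["a", "ss"] > t21.loc["a", "ss"]

    def test_overparameterized_design_errors(self, rng):
        y = pd.DataFrame({"v": rng.standard_normal(4)})
        pred = pd.DataFrame({"g": ["a", "b", "c", "d"]})
        with pytest.raises(ValueError, match="degrees of freedom"):
            permanova(y, pred, n_perm=9, seed=0)


class TestDispersalAxis:
    def test_perfectly_correlated_traits(self):
        z = np.array([-1.2, -0.3, 0.1, 1.4])
        traits = pd.DataFrame({"body_size_cm": 10 + 3 * z, "pld_days": 20 + 5 * z})
        res = dispersal_axis(traits)
        assert res.explained_variance[0] == pytest.approx(1.0)
        assert res.trait_correlations["body_size_cm"] == pytest.approx(1.0)

    def test_orientation_follows_body_size(self, rng):
        traits = pd.DataFrame(
            {"body_size_cm": rng.uniform(5, 60, 20), "pld_days": rng.uniform(10, 50, 20)}
        )
        res = dispersal_axis(traits)
        assert res.trait_correlations["body_size_cm"] > 0
        flipped = dispersal_axis(traits.assign(body_size_cm=-traits["body_size_cm"]))
        assert flipped.trait_correlations["body_size_cm"] > 0

    def test_two_variable_closed_form_variance(self, rng):
        # for two z-scored traits with correlation r, axis 1 explains (1+|r|)/2
        r = 0.9
        cov = np.array([[1, r], [r, 1]])
        X = rng.multivariate_normal([0, 0], cov, size=400)
        traits = pd.DataFrame(X, columns=["body_size_cm", "pld_days"])
        res = dispersal_axis(traits)
        r_hat = abs(np.corrcoef(X.T)[0, 1])
        assert res.explained_variance[0] == pytest.approx((1 + r_hat) / 2, abs=1e-10)

    def test_zero_variance_trait_errors(self):
        traits = pd.DataFrame({"body_size_cm": [1.0, 1.0, 1.0], "pld_days": [1, 2, 3]})
        with pytest.raises(ValueError, match="body_size_cm"):
            dispersal_axis(traits)


class TestPathModel:
    def test_single_predictor_is_pearson_r(self, rng):
        x = rng.standard_normal(50)
        y = 2 * x + rng.standard_normal(50)
        data = pd.DataFrame({"x": x, "y": y})
        paths = path_model(data, ["y ~ x"])
        r = np.corrcoef(x, y)[0, 1]
        assert paths.loc[0, "std_estimate"] == pytest.approx(r, abs=1e-10)

    def test_chain_recovery_large_n(self):
        rng = np.random.default_rng(12)
        n = 10000
        x = rng.standard_normal(n)
        m = 0.7 * x + np.sqrt(1 - 0.7**2) * rng.standard_normal(n)
        y = 0.5 * m + np.sqrt(1 - 0.5**2) * rng.standard_normal(n)
        paths = path_model(pd.DataFrame({"x": x, "m": m, "y": y}), ["m ~ x", "y ~ m"])
        est = paths.set_index(["response", "predictor"])["std_estimate"]
        assert est[("m", "x")] == pytest.approx(0.7, abs=0.03)
        assert est[("y", "m")] == pytest.approx(0.5, abs=0.03)

    def test_null_predictor_near_zero(self):
        rng = np.random.default_rng(13)
        n = 10000
        data = pd.DataFrame(
            {"x": rng.standard_normal(n), "y": rng.standard_normal(n)}
        )
        paths = path_model(data, ["y ~ x"])
        assert abs(paths.loc[0, "std_estimate"]) < 0.05

    def test_cycle_detected(self, rng):
        data = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="cyclic"):
            path_model(data, ["a ~ b", "b ~ a"])

    def test_missing_variable_reported(self, rng):
        data = pd.DataFrame({"a": rng.standard_normal(5)})
        with pytest.raises(ValueError, match="zz"):
            path_model(data, ["a ~ zz"])
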