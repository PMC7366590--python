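"""Mixed-model engine: design matrix, likelihood oracle, fit, BLUPs, Wald."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import block_diag

from bipanel.model import (
    BudgetImpactLMM,
    EstimationError,
    LMMParams,
    LMMResults,
    ar1_corr,
    neg_log_likelihood,
)
from bipanel.panel import month
from bipanel.simulate import SimulationConfig, simulate_cohort
from bipanel.terms import ModelSpec, ModelTerm, design_matrix

from conftest import make_panel
from test_simulate import flat_config

LEVELS = {"tumor_site": ("breast", "lung"), "molecule_type": ("mab", "small_molecule")}


def dense_mvn_loglik(dataset, spec, params: LMMParams) -> float:
    """Independent oracle: explicit joint covariance + multivariate normal."""
    G = np.asarray(params.re_cov)
    blocks, ys, Xs = [], [], []
    for pid in sorted(dataset.records["product_id"].unique()):
        grp = dataset.records[dataset.records["product_id"] == pid].sort_values(
            "month_index"
        )
        n = len(grp)
        t = grp["month_index"].to_numpy(dtype=float)
        Z = np.column_stack([np.ones(n), t])
        blocks.append(Z @ G @ Z.T + params.sigma2 * ar1_corr(params.phi, n))
        prof = dataset.profiles[dataset.profiles["product_id"] == pid]
        X, _ = design_matrix(
            pd.concat([prof] * n, ignore_index=True), t, spec
        )
        Xs.append(X)
        ys.append(np.log(grp["bi_eur"].to_numpy()))
    V = block_diag(*blocks)
    y = np.concatenate(ys)
    mu = np.vstack(Xs) @ params.beta
    return float(stats.multivariate_normal.logpdf(y, mean=mu, cov=V))


class TestDesignMatrix:
    def test_intercept_only(self):
        spec = ModelSpec.intercept_only(LEVELS)
        frame = pd.DataFrame({"orphan": [0, 1, 0]})
        X, names = design_matrix(frame, [1, 2, 3], spec)
        np.testing.assert_array_equal(X, np.ones((3, 1)))
        assert names == ["intercept"]

    def test_sqrt_interaction_value(self):
        spec = ModelSpec(
            (ModelTerm("intercept"), ModelTerm("orphan", "sqrt")), LEVELS
        )
        X, _ = design_matrix(pd.DataFrame({"orphan": [True]}), [9], spec)
        assert X[0, 1] == 3.0

    def test_indicator_zero_for_non_ce(self):
        spec = ModelSpec((ModelTerm("intercept"), ModelTerm("ce", "t")), LEVELS)
        X, _ = design_matrix(pd.DataFrame({"ce": [False]}), [7], spec)
        assert X[0, 1] == 0.0

    def test_categorical_dummy_coding_against_reference(self):
        spec = ModelSpec(
            (ModelTerm("intercept"), ModelTerm("tumor_site"),
             ModelTerm("tumor_site", "t")),
            LEVELS,
        )
        frame = pd.DataFrame({"tumor_site": ["breast", "lung"]})
        X, names = design_matrix(frame, [5, 5], spec)
        assert names == ["intercept", "tumor_site[lung]", "t:tumor_site[lung]"]
        np.testing.assert_array_equal(X[:, 1], [0.0, 1.0])  # breast = reference
        np.testing.assert_array_equal(X[:, 2], [0.0, 5.0])

    def test_unseen_level_maps_to_reference_with_warning(self):
        spec = ModelSpec((ModelTerm("intercept"), ModelTerm("tumor_site")), LEVELS)
        with pytest.warns(UserWarning, match="unseen"):
            X, _ = design_matrix(pd.DataFrame({"tumor_site": ["pancreas"]}), [1], spec)
        np.testing.assert_array_equal(X, [[1.0, 0.0]])

    def test_single_time_transform_per_covariate_enforced(self):
        with pytest.raises(ValueError, match="two time transforms"):
            ModelSpec(
                (ModelTerm("intercept"), ModelTerm("orphan", "sqrt"),
                 ModelTerm("orphan", "t2")),
                LEVELS,
            )


class TestLikelihood:
    def test_ar1_correlation_definition(self):
        np.testing.assert_allclose(
            ar1_corr(0.5, 3),
            [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]],
        )

    def test_iid_limit_closed_form(self):
        ds = make_panel({"A": ("2010-01", [100.0, 120.0, 90.0, 110.0])}, {})
        spec = ModelSpec.intercept_only(LEVELS)
        params = LMMParams(np.array([np.log(105.0)]), np.zeros((2, 2)), 0.04, 0.0)
        nll = neg_log_likelihood(ds, spec, params)
        y = np.log([100.0, 120.0, 90.0, 110.0])
        expected = -stats.norm.logpdf(y, np.log(105.0), 0.2).sum()
        np.testing.assert_allclose(nll, expected, rtol=1e-12)

    @pytest.mark.parametrize("phi,sigma2", [(0.0, 0.3), (0.5, 0.2), (-0.4, 1.1)])
    def test_matches_dense_mvn_oracle(self, phi, sigma2):
        """Structured likelihood equals brute-force joint-normal density on a
        2-product x 4-month instance (<= 12 observations, 1e-8 relative)."""
        ds = make_panel(
            {"A": ("2010-01", [1e3, 2e3, 1.5e3, 1.8e3]),
             "B": ("2011-01", [5e4, 6e4, 4e4, 7e4])},
            {"A": {"orphan": True}},
        )
        spec = ModelSpec(
            (ModelTerm("intercept"), ModelTerm("time"), ModelTerm("orphan", "sqrt")),
            LEVELS,
        )
        params = LMMParams(
            np.array([8.0, 0.05, 0.2]),
            np.array([[0.4, 0.01], [0.01, 0.002]]),
            sigma2,
            phi,
        )
        ours = -neg_log_likelihood(ds, spec, params)
        oracle = dense_mvn_loglik(ds, spec, params)
        np.testing.assert_allclose(ours, oracle, rtol=1e-8)


@pytest.fixture(scope="module")
def fitted_flat():
    cfg = flat_config(n_products=60, months_range=(15, 30), seed=21)
    ds = simulate_cohort(cfg)
    model = BudgetImpactLMM(ds, cfg.spec)
    return cfg, ds, model, model.fit()


class TestFit:
    def test_refit_is_bit_identical(self, fitted_flat):
        cfg, ds, model, res = fitted_flat
        res2 = BudgetImpactLMM(ds, cfg.spec).fit()
        np.testing.assert_array_equal(res.beta, res2.beta)
        np.testing.assert_array_equal(res.re_cov, res2.re_cov)
        assert res.llf == res2.llf

    def test_aic_identity(self, fitted_flat):
        *_, res = fitted_flat
        assert res.n_params == len(res.beta) + 5
        assert res.aic == 2 * res.n_params - 2 * res.llf

    def test_fit_at_least_matches_truth(self, fitted_flat):
        """The optimised likelihood is never below the likelihood at the
        generating parameters on the same data."""
        cfg, ds, model, res = fitted_flat
        truth = LMMParams(
            np.array(cfg.beta), np.array(cfg.re_cov), cfg.sigma2, cfg.phi
        )
        assert res.llf >= model.loglike(truth) - 1e-6

    def test_collapse_to_ols_when_no_random_structure(self):
        cfg = flat_config(
            n_products=80, re_cov=((0.0, 0.0), (0.0, 0.0)), phi=0.0,
            sigma2=0.25, seed=31,
        )
        ds = simulate_cohort(cfg)
        model = BudgetImpactLMM(ds, cfg.spec)
        res = model.fit()
        beta_ols, *_ = np.linalg.lstsq(model._X, model._y, rcond=None)
        se = res.bse
        assert np.all(np.abs(res.beta - beta_ols) <= 2 * se)
        assert res.re_cov[0, 0] < 0.05 and res.re_cov[1, 1] < 0.01
        assert abs(res.phi) < 0.1

    def test_shift_invariance(self, fitted_flat):
        """Multiplying euros by e (adding 1 to log BI) shifts the intercept
        by 1 and leaves the variance parameters unchanged."""
        cfg, ds, _, res = fitted_flat
        shifted = ds.records.assign(bi_eur=ds.records["bi_eur"] * np.e)
        res2 = BudgetImpactLMM.from_frames(shifted, ds.profiles, cfg.spec).fit()
        assert abs((res2.beta[0] - res.beta[0]) - 1.0) < 1e-5
        np.testing.assert_allclose(res2.beta[1:], res.beta[1:], atol=1e-5)
        np.testing.assert_allclose(res2.re_cov, res.re_cov, rtol=1e-3, atol=1e-6)
        np.testing.assert_allclose(res2.sigma2, res.sigma2, rtol=1e-3)
        np.testing.assert_allclose(res2.phi, res.phi, atol=1e-3)

    def test_degenerate_data_raises(self):
        ds = make_panel({"A": ("2010-01", [100.0])}, {})
        with pytest.raises(EstimationError):
            BudgetImpactLMM(ds, ModelSpec.intercept_only(LEVELS)).fit()


class TestBlupsAndPrediction:
    def test_blup_closed_form(self, fitted_flat):
        """b_i = G Z_i' V_i^-1 (y_i - X_i beta), evaluated independently."""
        cfg, ds, model, res = fitted_flat
        pid = model.product_ids[0]
        grp = ds.records[ds.records["product_id"] == pid].sort_values("month_index")
        n = len(grp)
        t = grp["month_index"].to_numpy(dtype=float)
        Z = np.column_stack([np.ones(n), t])
        prof = ds.profiles[ds.profiles["product_id"] == pid]
        X, _ = design_matrix(pd.concat([prof] * n, ignore_index=True), t, cfg.spec)
        V = Z @ res.re_cov @ Z.T + res.sigma2 * ar1_corr(res.phi, n)
        r = np.log(grp["bi_eur"].to_numpy()) - X @ res.beta
        expected = res.re_cov @ Z.T @ np.linalg.solve(V, r)
        np.testing.assert_allclose(res.blups.loc[pid].to_numpy(), expected, atol=1e-8)

    def test_blups_shrink_to_zero_with_re_cov(self, fitted_flat):
        cfg, ds, model, res = fitted_flat
        pid = model.product_ids[0]
        grp = ds.records[ds.records["product_id"] == pid].sort_values("month_index")
        n = len(grp)
        t = grp["month_index"].to_numpy(dtype=float)
        Z = np.column_stack([np.ones(n), t])
        prof = ds.profiles[ds.profiles["product_id"] == pid]
        X, _ = design_matrix(pd.concat([prof] * n, ignore_index=True), t, cfg.spec)
        r = np.log(grp["bi_eur"].to_numpy()) - X @ res.beta
        norms = []
        for scale in [1.0, 1e-2, 1e-4, 1e-8]:
            G = scale * res.re_cov
            V = Z @ G @ Z.T + res.sigma2 * ar1_corr(res.phi, n)
            norms.append(np.linalg.norm(G @ Z.T @ np.linalg.solve(V, r)))
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-6

    def test_blup_intercept_sign_follows_history_residuals(self, fitted_flat):
        """A product whose log expenditure sits above its population
        prediction gets a positive BLUP intercept (and vice versa)."""
        cfg, ds, model, res = fitted_flat
        merged = ds.records.merge(ds.profiles, on="product_id")
        X, _ = design_matrix(merged, merged["month_index"].to_numpy(), cfg.spec)
        merged["resid"] = np.log(merged["bi_eur"]) - X @ res.beta
        mean_resid = merged.groupby("product_id")["resid"].mean()
        top = mean_resid.idxmax()
        bottom = mean_resid.idxmin()
        assert res.blups.loc[top, "b0"] > 0
        assert res.blups.loc[bottom, "b0"] < 0

    def test_population_prediction_for_unknown_product(self, fitted_flat):
        cfg, ds, _, res = fitted_flat
        profile = ds.profiles.iloc[0]
        pop = res.predict_log_bi(profile, [1, 5, 10])
        known = res.predict_log_bi(profile, [1, 5, 10], product_id="nonexistent")
        np.testing.assert_array_equal(pop, known)

    def test_blup_adds_intercept_and_slope(self, fitted_flat):
        cfg, ds, model, res = fitted_flat
        pid = model.product_ids[0]
        profile = ds.profiles[ds.profiles["product_id"] == pid].iloc[0]
        t = np.array([2.0, 8.0])
        pop = res.predict_log_bi(profile, t)
        cond = res.predict_log_bi(profile, t, product_id=pid)
        b0, b1 = res.blups.loc[pid]
        np.testing.assert_allclose(cond - pop, b0 + b1 * t, atol=1e-10)

    def test_prediction_range_checked(self, fitted_flat):
        *_, res = fitted_flat
        with pytest.raises(ValueError, match=r"\[1, 45\]"):
            res.predict_log_bi(pd.DataFrame({"orphan": [False]}), [46], t_max=45)

    def test_json_round_trip(self, fitted_flat, tmp_path):
        cfg, ds, _, res = fitted_flat
        path = tmp_path / "model.json"
        res.to_json(path)
        back = LMMResults.from_json(path)
        profile = ds.profiles.iloc[3]
        pid = profile["product_id"]
        np.testing.assert_allclose(
            back.predict_log_bi(profile, [1, 4, 9], product_id=pid),
            res.predict_log_bi(profile, [1, 4, 9], product_id=pid),
        )
        assert back.aic == res.aic


class TestWald:
    def _results(self, beta, bse, cov=None, names=None, terms=None):
        names = names or [f"c{i}" for i in range(len(beta))]
        spec = ModelSpec(
            (ModelTerm("intercept"),) + tuple(terms or ()), LEVELS
        )
        return LMMResults(
            spec=spec, column_names=names, column_names_full=names,
            dropped_columns=[], beta=np.asarray(beta, float),
            bse=np.asarray(bse, float),
            cov_beta=cov if cov is not None else np.diag(np.asarray(bse) ** 2),
            re_cov=np.eye(2) * 0.1, sigma2=1.0, phi=0.0, llf=0.0,
            n_obs=10, n_params=len(beta) + 5,
            blups=pd.DataFrame(columns=["b0", "b1"]), converged=True,
        )

    def test_zero_coefficient_p_one(self):
        res = self._results([0.0], [2.0], names=["intercept"])
        assert res.wald_p(ModelTerm("intercept")) == 1.0

    def test_z_196_p_005(self):
        res = self._results([1.96], [1.0], names=["intercept"])
        assert res.wald_p(ModelTerm("intercept")) == pytest.approx(0.05, abs=1e-3)

    def test_joint_zero_vector_p_one(self):
        levels3 = {"tumor_site": ("breast", "colorectal", "lung"),
                   "molecule_type": ("mab",)}
        spec = ModelSpec((ModelTerm("intercept"), ModelTerm("tumor_site")), levels3)
        names = ["intercept", "tumor_site[colorectal]", "tumor_site[lung]"]
        res = LMMResults(
            spec=spec, column_names=names, column_names_full=names,
            dropped_columns=[], beta=np.array([1.0, 0.0, 0.0]),
            bse=np.array([0.5, 1.0, 1.0]), cov_beta=np.diag([0.25, 1.0, 1.0]),
            re_cov=np.eye(2) * 0.1, sigma2=1.0, phi=0.0, llf=0.0,
            n_obs=10, n_params=8,
            blups=pd.DataFrame(columns=["b0", "b1"]), converged=True,
        )
        assert res.wald_p(ModelTerm("tumor_site")) == pytest.approx(1.0)

    def test_absent_term_rejected(self):
        res = self._results([0.0], [1.0], names=["intercept"])
        with pytest.raises(ValueError):
            res.wald_p(ModelTerm("fic"))
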