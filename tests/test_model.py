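"""Fall-risk models: quadratic fits, PCA transform, consensus stepwise
selection, goodness of fit."""

import numpy as np
import pandas as pd
import pytest

import gaitrisk as gr
from gaitrisk.metrics import METRIC_NAMES
from gaitrisk.model import (FallRiskResults, _score_terms, consensus_stepwise,
                            fit_pca, apply_pca, stepwise_select)


class TestIndividualModel:
    def test_exact_quadratic_recovered(self):
        rho = np.linspace(-2, 2, 20)
        y = 1.0 + 2.0 * rho + 3.0 * rho ** 2
        res = gr.IndividualMetricModel(y, rho).fit()
        np.testing.assert_allclose(res.params, [1.0, 2.0, 3.0], atol=1e-8)
        assert res.predict(0.0) == pytest.approx(res.params["beta0"])
        assert res.predict_mfpt(0.0) == pytest.approx(np.exp(1.0))

    def test_noisy_fit_within_ols_sampling_theory(self):
        # planted quadratic + N(0, 0.1): each coefficient error within
        # 3x its closed-form OLS standard error
        rng = np.random.default_rng(8)
        rho = rng.uniform(-1, 1, size=30)
        sigma = 0.1
        y = 1.0 + 2.0 * rho + 3.0 * rho ** 2 + rng.normal(0, sigma, 30)
        res = gr.IndividualMetricModel(y, rho).fit()
        X = np.column_stack([np.ones(30), rho, rho ** 2])
        se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        err = np.abs(res.params.to_numpy() - [1.0, 2.0, 3.0])
        assert np.all(err <= 3 * se)

    def test_constant_metric_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            gr.IndividualMetricModel(np.arange(8.0), np.ones(8)).fit()

    def test_summary_mentions_metric_name(self):
        rho = np.linspace(0, 1, 10)
        res = gr.IndividualMetricModel(rho * 2, rho, name="xcom_mean").fit()
        assert "xcom_mean" in res.summary()


class TestPCA:
    def test_orthogonal_columns_give_signed_permutation(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "a": np.repeat([3.0, -3.0], 10),
            "b": np.tile([1.0, -1.0], 10),
        })
        df += 1e-9 * rng.normal(size=df.shape)  # break exact ties
        pca = fit_pca(df, n_components=2)
        L = pca.loadings.abs().to_numpy()
        assert np.allclose(L.max(axis=0), 1.0, atol=1e-6)
        assert np.allclose(L.sum(axis=0), 1.0, atol=1e-6)
        # sign convention: dominant loading positive
        assert (pca.loadings.to_numpy().max(axis=0) > 0).all()

    def test_score_variances_non_increasing(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 10)) * rng.uniform(0.5, 3, 10))
        pca = fit_pca(df, n_components=8)
        scores = apply_pca(pca, df)
        v = scores.var(axis=0, ddof=1).to_numpy()
        assert np.all(np.diff(v) <= 1e-12)
        np.testing.assert_allclose(v, pca.explained_variance, rtol=1e-10)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(12, 6)))
        pca = fit_pca(df, n_components=6)
        scores = apply_pca(pca, df)
        recon = scores.to_numpy() @ pca.loadings.to_numpy().T \
            + pca.mean.to_numpy()
        np.testing.assert_allclose(recon, df.to_numpy(), atol=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 12)))
        pca = fit_pca(df, n_components=5)
        L = pca.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-8)


class TestStepwise:
    def make_scores(self, seed, n=40, k=10):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, k)),
                            columns=[f"pc{i+1}" for i in range(k)]), rng

    def test_planted_terms_recovered(self):
        scores, rng = self.make_scores(4)
        terms = _score_terms(scores)
        y = (2.0 * scores["pc1"] + 1.5 * scores["pc3"] ** 2
             + rng.normal(0, 0.05, size=40))
        sel, _ = consensus_stepwise(terms, y, list(range(40)), seed=0)
        assert set(sel) == {"pc1", "pc3^2"}
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(terms[sel])).fit()
        assert ols.params["pc1"] == pytest.approx(2.0, rel=0.05)
        assert ols.params["pc3^2"] == pytest.approx(1.5, rel=0.05)

    def test_null_data_yields_intercept_only(self):
        hits = 0
        for seed in range(10):
            scores, rng = self.make_scores(100 + seed, n=30, k=15)
            terms = _score_terms(scores)
            y = rng.normal(size=30)
            sel, _ = consensus_stepwise(terms, y, list(range(30)), seed=seed)
            hits += (len(sel) == 0)
        assert hits >= 9

    def test_same_seed_identical_selection(self):
        scores, rng = self.make_scores(6)
        terms = _score_terms(scores)
        y = scores["pc2"] + rng.normal(0, 0.5, size=40)
        groups = list(np.repeat(np.arange(8), 5))
        s1, v1 = consensus_stepwise(terms, y, groups, seed=3)
        s2, v2 = consensus_stepwise(terms, y, groups, seed=3)
        assert s1 == s2 and v1 == v2

    def test_backward_step_drops_stale_terms(self):
        # x2 = x1 + small noise: once x1 enters, x2 adds nothing
        rng = np.random.default_rng(9)
        x1 = rng.normal(size=50)
        X = pd.DataFrame({"x1": x1, "x2": x1 + 0.01 * rng.normal(size=50)})
        y = x1 + 0.01 * rng.normal(size=50)
        sel = stepwise_select(X, y)
        assert len(sel) == 1


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        y = np.linspace(1, 30, 15)
        g = gr.goodness_of_fit(y, y)
        assert g.rmse == 0 and g.mae == 0 and g.mape == 0 and g.raae == 0
        assert g.pct_in_tolerance == 100.0
        assert g.slope == pytest.approx(1.0)
        assert g.intercept == pytest.approx(0.0, abs=1e-10)
        assert g.re2 == pytest.approx(1.0)

    def test_mape_single_pair_substitution(self):
        # yhat = 2, y = 4 -> 50%
        g = gr.goodness_of_fit(np.array([2.0, 2.0]), np.array([4.0, 4.0001]))
        assert g.mape == pytest.approx(50.0, rel=1e-3)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(12)
        y = rng.normal(10, 5, size=100)
        yhat = y + rng.normal(0, 2, size=100)
        groups = np.repeat(np.arange(10), 10)
        g = gr.goodness_of_fit(yhat, y, groups=groups)
        err = yhat - y
        assert g.rmse == pytest.approx(np.sqrt(np.mean(err ** 2)))
        assert g.mae == pytest.approx(np.mean(np.abs(err)))
        assert g.mape == pytest.approx(100 * np.mean(np.abs(err / y)))
        assert g.raae == pytest.approx(
            np.mean(np.abs(err)) / np.std(yhat, ddof=1))
        assert g.max_abs_err == pytest.approx(np.max(np.abs(err)))
        assert g.pct_in_tolerance == pytest.approx(
            100 * np.mean(np.abs(err) <= 3.3))
        a1, a0 = np.polyfit(y, yhat, 1)
        assert g.slope == pytest.approx(a1)
        assert g.intercept == pytest.approx(a0)
        sds = [np.std(err[groups == k], ddof=1) for k in range(10)]
        assert g.mean_group_sd == pytest.approx(np.mean(sds))

    def test_invariant_to_condition_reordering(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=40)
        yhat = y + rng.normal(0, 1, size=40)
        perm = rng.permutation(40)
        g1 = gr.goodness_of_fit(yhat, y)
        g2 = gr.goodness_of_fit(yhat[perm], y[perm])
        for f in ("rmse", "mae", "mape", "raae", "slope", "re2"):
            assert getattr(g1, f) == pytest.approx(getattr(g2, f))

    def test_zero_truth_excluded_from_mape(self):
        with pytest.warns(UserWarning, match="MAPE"):
            g = gr.goodness_of_fit(np.array([1.0, 2.0]), np.array([0.0, 4.0]))
        assert g.n_mape_excluded == 1
        assert g.mape == pytest.approx(50.0)


class TestFallRiskResults:
    def make_results(self, terms, params):
        norm = gr.NormalizationRecord(
            pd.Series(0.0, index=METRIC_NAMES),
            pd.Series(1.0, index=METRIC_NAMES))
        k = 15
        loadings = pd.DataFrame(np.eye(len(METRIC_NAMES), k),
                                index=METRIC_NAMES,
                                columns=[f"pc{i+1}" for i in range(k)])
        pca = gr.PCATransform(loadings=loadings,
                              mean=pd.Series(0.0, index=METRIC_NAMES),
                              explained_variance=np.ones(k))
        return FallRiskResults(model=None, normalization=norm, pca=pca,
                               terms=terms, params=pd.Series(params),
                               variant="no_lyap")

    def metric_vec(self, first=3.0):
        vals = pd.Series(0.0, index=METRIC_NAMES)
        vals.iloc[0] = first  # projects onto pc1 with identity loadings
        return gr.MetricVector(vals)

    def test_intercept_only_prediction(self):
        res = self.make_results([], {"const": 1.0})
        assert res.predict(self.metric_vec(123.0)) == pytest.approx(1.0)

    def test_linear_term_substitution(self):
        # const 1, beta_{1,1} = 2 at X_PCA,1 = 3 -> yhat = 7
        res = self.make_results(["pc1"], {"const": 1.0, "pc1": 2.0})
        assert res.predict(self.metric_vec(3.0)) == pytest.approx(7.0)

    def test_batch_equals_per_item(self):
        res = self.make_results(["pc1", "pc1^2"],
                                {"const": 0.5, "pc1": 2.0, "pc1^2": -0.25})
        vecs = [self.metric_vec(v) for v in (0.0, 1.0, -2.0)]
        batch = res.predict(gr.metric_table(vecs))
        singles = [res.predict(v) for v in vecs]
        np.testing.assert_allclose(batch.to_numpy(), singles)

    def test_json_round_trip(self, tmp_path):
        res = self.make_results(["pc1"], {"const": 1.0, "pc1": 2.0})
        path = tmp_path / "model.json"
        res.to_json(path)
        back = FallRiskResults.from_json(path)
        assert back.terms == res.terms
        assert back.variant == res.variant
        assert back.predict(self.metric_vec(3.0)) == pytest.approx(7.0)

    def test_missing_required_metric_named(self):
        res = self.make_results([], {"const": 0.0})
        vals = pd.Series(0.0, index=METRIC_NAMES)
        vals["fri_mean"] = np.nan
        with pytest.raises(ValueError, match="fri_mean"):
            res.predict(gr.MetricVector(vals))


class TestFallRiskModelFit:
    def test_variant_column_selection(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(12, 49)), columns=METRIC_NAMES)
        y = rng.normal(size=12)
        m = gr.FallRiskModel(df, y, variant="with_lyap")
        assert "lyap_long_q1" in m.metrics.columns
        assert not any(c.startswith("lyap_short") for c in m.metrics.columns)
        m2 = gr.FallRiskModel(df, y, variant="no_lyap")
        assert not any(c.startswith("lyap") for c in m2.metrics.columns)

    def test_missing_lyapunov_blocks_with_lyap_variant(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(12, 49)), columns=METRIC_NAMES)
        df["lyap_long_q1"] = np.nan
        with pytest.raises(ValueError, match="lyap"):
            gr.FallRiskModel(df, rng.normal(size=12), variant="with_lyap")

    def test_fit_deterministic_in_seed(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 49)), columns=METRIC_NAMES)
        y = df["xcom_mean"] * 3 + rng.normal(0, 0.1, size=20)
        m = gr.FallRiskModel(df, y, variant="no_lyap")
        r1, r2 = m.fit(seed=5), m.fit(seed=5)
        assert r1.terms == r2.terms
        pd.testing.assert_series_equal(r1.params, r2.params)
        assert "quadratic fall-risk model" in r1.summary().lower()
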