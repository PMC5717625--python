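"""The mixed-model engine: GLM limit, closed forms, deviance, rates."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import norm

import desertsem as d
from desertsem.glmm_engine import fit_node, deviance_explained, standardize_predictors
from desertsem.model_graph import NodeSpec


def _poisson_frame(seed=3, n=150, n_trips=8, sd=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
        "trip": rng.integers(1, n_trips + 1, size=n),
        "effort": rng.integers(50, 200, size=n).astype(float),
    })
    u = rng.normal(0, sd, size=n_trips + 1)
    eta = -1.0 + 0.4 * df.x1 - 0.6 * df.x2 + np.log(df.effort) + u[df.trip]
    df["y"] = rng.poisson(np.exp(eta))
    return df


POIS_SPEC = NodeSpec(name="toy", family="poisson", response="y",
                     predictors=("x1", "x2"), offset="effort")


class TestGlmLimit:
    """With the random-intercept SD constrained to zero the engine must
    reproduce an independent IRLS GLM fit to at least six significant
    figures."""

    def test_poisson_matches_statsmodels(self):
        df = _poisson_frame()
        fit = fit_node(POIS_SPEC, df, constrain_sd=0.0)
        oracle = sm.GLM(
            df.y, sm.add_constant(df[["x1", "x2"]]),
            family=sm.families.Poisson(), offset=np.log(df.effort),
        ).fit()
        np.testing.assert_allclose(fit.coefficients, oracle.params.values, rtol=1e-8)
        np.testing.assert_allclose(fit.std_errors, oracle.bse.values, rtol=1e-6)

    def test_binomial_matches_statsmodels(self):
        rng = np.random.default_rng(9)
        df = _poisson_frame(seed=9)
        df["score"] = rng.binomial(100, 1 / (1 + np.exp(-(-0.5 + 0.3 * df.x1))))
        spec = NodeSpec(name="toyb", family="binomial", response="score",
                        predictors=("x1",), binomial_denominator=100)
        fit = fit_node(spec, df, constrain_sd=0.0)
        oracle = sm.GLM(
            np.column_stack([df.score, 100 - df.score]),
            sm.add_constant(df[["x1"]]), family=sm.families.Binomial(),
        ).fit()
        np.testing.assert_allclose(fit.coefficients, oracle.params.values, rtol=1e-8)

    def test_intercept_only_closed_form(self):
        """With a constant offset E the intercept is log(mean(y)/E)."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "y": rng.poisson(4.0, size=200),
            "trip": rng.integers(1, 5, size=200),
            "effort": 108.0,
        })
        spec = NodeSpec(name="i", family="poisson", response="y",
                        predictors=(), offset="effort")
        fit = fit_node(spec, df, constrain_sd=0.0)
        assert fit.coefficients[0] == pytest.approx(np.log(df.y.mean() / 108.0), rel=1e-10)


class TestMixedFit:
    def test_wald_p_is_two_sided_normal_tail(self):
        df = _poisson_frame(sd=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_node(POIS_SPEC, df)
        np.testing.assert_allclose(
            fit.p_values, 2.0 * norm.sf(np.abs(fit.z_values)), rtol=0, atol=0)

    def test_sd_estimated_positive_when_truth_positive(self):
        df = _poisson_frame(seed=21, n=600, n_trips=20, sd=0.5)
        fit = fit_node(POIS_SPEC, df)
        assert 0.2 < fit.random_intercept_sd < 0.9
        assert fit.converged

    def test_singular_fit_warns_and_reports_zero_sd(self):
        df = _poisson_frame(seed=3, sd=0.0)
        with pytest.warns(UserWarning, match="singular"):
            fit = fit_node(POIS_SPEC, df)
        assert fit.random_intercept_sd == 0.0

    def test_needs_two_random_factor_levels(self):
        df = _poisson_frame().assign(trip=1)
        with pytest.raises(ValueError, match="levels"):
            fit_node(POIS_SPEC, df)

    def test_loglik_not_worse_than_glm_limit(self):
        """The mixed fit maximises over a superset of the GLM family."""
        df = _poisson_frame(seed=21, n=600, n_trips=20, sd=0.5)
        mixed = fit_node(POIS_SPEC, df)
        glm = fit_node(POIS_SPEC, df, constrain_sd=0.0)
        assert mixed.loglik >= glm.loglik - 1e-6


class TestDeviance:
    def test_arithmetic_from_cited_formula(self, fits):
        fit = fits["spinifex_cover"]
        fit2 = type(fit)(**{**fit.__dict__, "deviance": 40.0, "null_deviance": 100.0})
        assert deviance_explained(fit2) == pytest.approx(0.60)

    def test_no_improvement_gives_zero(self, fits):
        fit = fits["rodents"]
        fit2 = type(fit)(**{**fit.__dict__, "deviance": 100.0, "null_deviance": 100.0})
        assert deviance_explained(fit2) == 0.0

    def test_undefined_when_null_nonpositive(self, fits):
        fit = fits["rodents"]
        fit2 = type(fit)(**{**fit.__dict__, "null_deviance": 0.0})
        with pytest.raises(ValueError, match="undefined"):
            deviance_explained(fit2)

    def test_bounded_on_every_canonical_fit(self, fits):
        for name, fit in fits.items():
            val = deviance_explained(fit)
            assert 0.0 <= val <= 1.0, name
            assert fit.null_deviance >= fit.deviance - 1e-6, name


class TestStandardizePredictors:
    def test_captures_per_100_trap_nights(self):
        spec = NodeSpec(name="m", family="poisson", response="mulgara",
                        predictors=("rodents_per_100tn",), offset="trap_nights")
        df = pd.DataFrame({"mulgara": [1], "rodents": [6], "trap_nights": [216.0],
                           "trip": [1]})
        out = standardize_predictors(spec, df)
        assert out["rodents_per_100tn"].iloc[0] == pytest.approx(6 / 216 * 100)

    def test_zero_effort_rejected(self):
        spec = NodeSpec(name="m", family="poisson", response="mulgara",
                        predictors=("rodents_per_100tn",), offset="trap_nights")
        df = pd.DataFrame({"mulgara": [1], "rodents": [6], "trap_nights": [0.0],
                           "trip": [1]})
        with pytest.raises(ValueError, match="non-positive"):
            standardize_predictors(spec, df)

    def test_z_transform_unit_moments(self):
        spec = NodeSpec(name="f", family="poisson", response="fox",
                        predictors=("x",), offset="camera_nights",
                        z_transform_predictors=True)
        df = pd.DataFrame({"fox": [1, 2, 3, 4], "x": [1.0, 2.0, 5.0, 9.0],
                           "camera_nights": 30.0, "trip": [1, 1, 2, 2]})
        out = standardize_predictors(spec, df)
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(1.0)

    def test_z_transform_of_constant_errors(self):
        spec = NodeSpec(name="f", family="poisson", response="fox",
                        predictors=("x",), offset="camera_nights",
                        z_transform_predictors=True)
        df = pd.DataFrame({"fox": [1, 2], "x": [3.0, 3.0],
                           "camera_nights": 30.0, "trip": [1, 2]})
        with pytest.raises(ValueError, match="constant"):
            standardize_predictors(spec, df)


class TestFitPredictions:
    def test_poisson_rates_positive_binomial_scores_bounded(self, fits):
        for name, fit in fits.items():
            pred = fit.predict_response(fit.col_means)
            if fit.family == "poisson":
                assert np.all(pred > 0)
            else:
                assert np.all((pred > 0) & (pred < fit.spec.binomial_denominator))

    def test_simulated_counts_overdispersed_with_random_intercept(self, frames):
        """Trip-level random intercepts induce variance > mean in the
        marginal Poisson counts."""
        y = frames["rodents"]["rodents"].dropna()
        assert y.var(ddof=1) > y.mean()
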