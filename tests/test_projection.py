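"""Scenario propagation: composed-equation oracle, ordering, bounds."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import desertsem as d
from desertsem.cli_io import RunConfig
from desertsem.climate_scenarios import ScenarioSpec, draw_scenario
from desertsem.glmm_engine import FittedNode
from desertsem.projection import (
    SCENARIO_NAMES,
    PredatorScenario,
    ProjectionResult,
    percent_change,
    propagate,
)


def _toy_fit(name, family, columns, coefs, denom=None, resp_obs=None):
    """Hand-built fitted node with known coefficients."""
    from desertsem.model_graph import NodeSpec

    spec = NodeSpec(
        name=name, family=family, response=name,
        predictors=tuple(c for c in columns if c != "(Intercept)"),
        offset="trap_nights" if family == "poisson" else None,
        binomial_denominator=denom,
    )
    k = len(columns)
    coefs = np.asarray(coefs, float)
    return FittedNode(
        name=name, spec=spec, columns=list(columns),
        term_columns={c: [i] for i, c in enumerate(columns) if c != "(Intercept)"},
        coefficients=coefs, cov=np.eye(k), std_errors=np.ones(k),
        z_values=coefs, p_values=np.full(k, 0.5), random_intercept_sd=0.2,
        loglik=0.0, deviance=50.0, null_deviance=100.0, n_obs=100, n_groups=10,
        converged=True, family=family,
        col_means=np.r_[1.0, np.zeros(k - 1)],
        col_mins=np.r_[1.0, -np.ones(k - 1)],
        col_maxs=np.r_[1.0, np.ones(k - 1)],
        response_obs=resp_obs if resp_obs is not None else np.linspace(0.1, 1, 50),
        mean_offset=108.0,
    )


def _toy_sem(cover_coefs, seed_coefs, rodent_coefs):
    fits = {
        "spinifex_cover": _toy_fit(
            "spinifex_cover", "binomial",
            ["(Intercept)", "years_since_fire", "rain_8mo"], cover_coefs,
            denom=100, resp_obs=np.linspace(5, 60, 50)),
        "spinifex_seed": _toy_fit(
            "spinifex_seed", "binomial",
            ["(Intercept)", "spinifex_cover", "rain_8mo"], seed_coefs,
            denom=5, resp_obs=np.linspace(0, 4, 50)),
        "rodents": _toy_fit(
            "rodents", "poisson",
            ["(Intercept)", "seed_index", "cat_per_cn", "fox_per_cn",
             "dingo_per_cn"], rodent_coefs,
            resp_obs=np.linspace(0.01, 0.4, 50)),
    }
    return d.SemResult(paths=[], deviance_explained_pct={}, fits=fits)


@pytest.fixture(scope="module")
def driver_draws():
    rain = draw_scenario(ScenarioSpec("rainfall_8mo", 152, 419, 1.57,
                                      n_draws=400, n_steps=12, seed=21))
    fire = draw_scenario(ScenarioSpec("years_since_fire", 21, 10, 3.34,
                                      n_draws=400, n_steps=12, seed=22))
    return rain, fire


@pytest.fixture(scope="module")
def camera_rates():
    rng = np.random.default_rng(30)
    return pd.DataFrame({
        "cat_per_cn": rng.uniform(0.02, 0.3, 60),
        "fox_per_cn": rng.uniform(0.0, 0.15, 60),
        "dingo_per_cn": rng.uniform(0.02, 0.25, 60),
    })


class TestPredatorScenario:
    def test_zeroing_rules(self, camera_rates):
        intro = PredatorScenario.from_camera_table("introduced_removed",
                                                   camera_rates)
        assert (intro.rates[["cat_per_cn", "fox_per_cn"]] == 0).all().all()
        assert (intro.rates["dingo_per_cn"] > 0).any()
        none_left = PredatorScenario.from_camera_table("all_removed", camera_rates)
        assert (none_left.rates == 0).all().all()

    def test_unzeroed_rates_rejected(self, camera_rates):
        with pytest.raises(ValueError, match="zeroed"):
            PredatorScenario(name="all_removed", rates=camera_rates)

    def test_unknown_name_rejected(self, camera_rates):
        with pytest.raises(ValueError, match="unknown"):
            PredatorScenario(name="no_cats_only", rates=camera_rates)


class TestPropagate:
    def test_matches_composed_equation_oracle(self, driver_draws, camera_rates):
        """Projection means must equal a direct closed-form composition of
        the three equations on the same draws (single predator-rate row so
        resampling is immaterial; no rodent-run subsampling)."""
        rain, fire = driver_draws
        sem = _toy_sem([-1.8, 0.04, 0.001], [-1.9, 0.03, 0.0005],
                       [-2.7, 0.5, -3.0, -2.0, 2.0])
        one_row = pd.DataFrame({"cat_per_cn": [0.1], "fox_per_cn": [0.05],
                                "dingo_per_cn": [0.12]})
        scen = PredatorScenario(name="all_predators", rates=one_row)
        res = propagate(sem, rain, fire, scen, n_runs=400, seed=5,
                        n_runs_rodent=400)

        cover = 100 * expit(-1.8 + 0.04 * fire.values + 0.001 * rain.values)
        seed_idx = 5 * expit(-1.9 + 0.03 * cover + 0.0005 * rain.values)
        rodents = 100 * np.exp(-2.7 + 0.5 * seed_idx - 3.0 * 0.1 - 2.0 * 0.05
                               + 2.0 * 0.12)
        for resp, oracle in (("spinifex_cover", cover),
                             ("seed_index", seed_idx),
                             ("rodents_per_100tn", rodents)):
            got = res.series(resp)["mean"].to_numpy()
            np.testing.assert_allclose(got, oracle.mean(axis=1), rtol=1e-12)

    def test_intercept_only_gives_flat_trajectories(self, driver_draws,
                                                    camera_rates):
        rain, fire = driver_draws
        sem = _toy_sem([-1.0, 0.0, 0.0], [0.5, 0.0, 0.0],
                       [-2.0, 0.0, 0.0, 0.0, 0.0])
        scen = PredatorScenario.from_camera_table("all_predators", camera_rates)
        res = propagate(sem, rain, fire, scen, n_runs=400, seed=5)
        for resp, expect in (("spinifex_cover", 100 * expit(-1.0)),
                             ("seed_index", 5 * expit(0.5)),
                             ("rodents_per_100tn", 100 * np.exp(-2.0))):
            vals = res.series(resp)["mean"]
            np.testing.assert_allclose(vals, expect, rtol=1e-12)
            assert res.series(resp)["se"].max() < 1e-12

    def test_response_scale_bounds(self, sem, driver_draws, frames):
        rain, fire = driver_draws
        scen = PredatorScenario.from_camera_table("all_predators", frames["cat"])
        res = propagate(sem, rain, fire, scen, n_runs=400, seed=1)
        cover = res.series("spinifex_cover")
        seed_idx = res.series("seed_index")
        rodents = res.series("rodents_per_100tn")
        assert cover["mean"].between(0, 100).all()
        assert seed_idx["mean"].between(0, 5).all()
        assert (rodents["mean"] > 0).all()
        assert (res.table["se"] >= 0).all()

    def test_removing_negative_coefficient_predator_never_decreases(
            self, driver_draws, camera_rates):
        rain, fire = driver_draws
        sem = _toy_sem([-1.8, 0.04, 0.001], [-1.9, 0.03, 0.0005],
                       [-2.7, 0.5, -3.0, -2.0, 2.0])
        kwargs = dict(n_runs=400, seed=5, n_runs_rodent=400)
        res = {
            name: propagate(sem, rain, fire,
                            PredatorScenario.from_camera_table(name, camera_rates),
                            **kwargs)
            for name in SCENARIO_NAMES
        }
        base = res["all_predators"].series("rodents_per_100tn")["mean"]
        intro = res["introduced_removed"].series("rodents_per_100tn")["mean"]
        assert (intro >= base).all()  # cat & fox slopes negative
        # dingo slope positive: removing it too must reduce the gain
        allrem = res["all_removed"].series("rodents_per_100tn")["mean"]
        assert (allrem <= intro).all()

    def test_pure_function_of_inputs(self, sem, driver_draws, frames):
        rain, fire = driver_draws
        scen = PredatorScenario.from_camera_table("all_predators", frames["cat"])
        a = propagate(sem, rain, fire, scen, n_runs=300, seed=7)
        b = propagate(sem, rain, fire, scen, n_runs=300, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_missing_node_is_an_error(self, driver_draws, camera_rates):
        rain, fire = driver_draws
        sem = d.SemResult(paths=[], deviance_explained_pct={}, fits={})
        scen = PredatorScenario.from_camera_table("all_predators", camera_rates)
        with pytest.raises(ValueError, match="spinifex_cover"):
            propagate(sem, rain, fire, scen, n_runs=10)

    def test_out_of_support_draws_warn(self, sem, frames):
        rain = draw_scenario(ScenarioSpec("rainfall_8mo", 5000, 5000, 1.57,
                                          n_draws=50, n_steps=2, seed=2))
        fire = draw_scenario(ScenarioSpec("years_since_fire", 21, 10, 3.34,
                                          n_draws=50, n_steps=2, seed=3))
        scen = PredatorScenario.from_camera_table("all_predators", frames["cat"])
        with pytest.warns(UserWarning, match="beyond the fitting range"):
            propagate(sem, rain, fire, scen, n_runs=50, seed=1)


class TestPercentChange:
    @staticmethod
    def _result(name, means):
        rows = [{"step": i + 1, "response": "rodents_per_100tn",
                 "mean": m, "se": 0.1, "n_runs": 342}
                for i, m in enumerate(means)]
        return ProjectionResult(scenario=name, table=pd.DataFrame(rows))

    def test_identical_results_give_zero(self):
        a = self._result("all_predators", [2.0] * 12)
        assert percent_change(a, a) == 0.0

    def test_ten_percent_increase(self):
        a = self._result("all_predators", [2.0] * 12)
        b = self._result("introduced_removed", [2.2] * 12)
        assert percent_change(a, b) == pytest.approx(10.0)

    def test_zero_baseline_is_an_error(self):
        a = self._result("all_predators", [0.0] * 12)
        b = self._result("introduced_removed", [1.0] * 12)
        with pytest.raises(ValueError, match="baseline"):
            percent_change(a, b)


class TestRunFullProjection:
    def test_bundle_shapes_and_determinism(self, sem, frames, tmp_path):
        cfg = RunConfig(out_dir=str(tmp_path / "a"), seed=3, n_draws=400,
                        n_runs_rodent=100)
        bundle = d.run_full_projection(sem, frames["cat"], cfg)
        t = bundle["table"]
        assert set(t["scenario"]) == set(SCENARIO_NAMES)
        for name in SCENARIO_NAMES:
            for resp in ("spinifex_cover", "seed_index", "rodents_per_100tn"):
                assert ((t.scenario == name) & (t.response == resp)).sum() == 12
        cfg2 = RunConfig(out_dir=str(tmp_path / "b"), seed=3, n_draws=400,
                         n_runs_rodent=100)
        bundle2 = d.run_full_projection(sem, frames["cat"], cfg2)
        pd.testing.assert_frame_equal(bundle["table"], bundle2["table"])
        assert (tmp_path / "a" / "projection.csv").read_bytes() == \
            (tmp_path / "b" / "projection.csv").read_bytes()
        assert (tmp_path / "a" / "projection.svg").exists()
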