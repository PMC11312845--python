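import math

import numpy as np
import pandas as pd
import pytest

import arealrisk as ar
from arealrisk import model, standardize
from arealrisk.errors import ValidationError
from arealrisk.graph import build_adjacency, grid_polygons, icar_structure

from conftest import full_grid_counts


class TestSummarizeCoefficient:
    def test_constant_zero_draws(self):
        s = ar.summarize_coefficient(np.zeros(200), "x")
        assert s.mean == 0 and s.rr == 1.0 and not s.significant

    def test_rr_is_exponential_of_mean(self):
        s = ar.summarize_coefficient(np.full(200, 3.311))
        assert s.rr == pytest.approx(27.412, abs=0.005)
        s = ar.summarize_coefficient(np.full(200, -8.274))
        assert round(s.rr, 3) == 0.000

    def test_significance_requires_shared_ci_sign(self):
        rng = np.random.default_rng(0)
        pos = ar.summarize_coefficient(rng.normal(5, 0.1, 1000))
        straddle = ar.summarize_coefficient(rng.normal(0, 1, 1000))
        assert pos.significant and not straddle.significant
        assert pos.ci_low <= pos.mean <= pos.ci_high

    def test_empty_draws_rejected(self):
        with pytest.raises(ValidationError):
            ar.summarize_coefficient(np.array([]))


class TestWAIC:
    def test_single_draw_has_zero_penalty(self):
        ll = np.log(np.array([[0.2, 0.5]]))
        assert ar.waic(ll) == pytest.approx(-2 * ll.sum())

    def test_hand_computed_three_draw_table(self):
        lik = np.array([[0.1, 0.4], [0.2, 0.5], [0.3, 0.6]])
        ll = np.log(lik)
        lppd = sum(math.log(lik[:, j].mean()) for j in range(2))
        p = sum(np.var(ll[:, j], ddof=1) for j in range(2))
        assert ar.waic(ll) == pytest.approx(-2 * (lppd - p), rel=1e-12)

    def test_duplicating_observations_doubles_waic(self):
        rng = np.random.default_rng(3)
        ll = rng.normal(-2, 0.3, size=(50, 7))
        assert ar.waic(np.hstack([ll, ll])) == pytest.approx(2 * ar.waic(ll))

    def test_non_finite_loglik_rejected(self):
        with pytest.raises(ValidationError):
            ar.waic(np.array([[0.0, -np.inf]]))


class TestVifScreen:
    def _poisson_data(self, X, rng):
        mu = np.exp(0.5 + X @ np.full(X.shape[1], 0.1))
        return rng.poisson(mu), np.zeros(len(X))

    def test_orthogonal_design_all_retained(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        design = pd.DataFrame({"a": x1, "b": x2})
        y, off = self._poisson_data(design.to_numpy(),
                                    np.random.default_rng(0))
        res = ar.vif_screen(design, y, off)
        assert set(res.retained) == {"a", "b"}
        # under near-constant weights both VIFs are essentially 1
        assert res.vifs.max() < 1.2

    def test_duplicated_covariate_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        design = pd.DataFrame({"a": x, "b": rng.normal(size=80), "a2": x})
        y, off = self._poisson_data(design.to_numpy(), rng)
        res = ar.vif_screen(design, y, off)
        assert math.isinf(res.vifs["a"]) and math.isinf(res.vifs["a2"])
        assert res.dropped[0][0] == "a2"  # later-listed duplicate goes first
        assert "a" in res.retained and "b" in res.retained
        assert res.warnings

    def test_correlation_09_matches_closed_form(self):
        # two standardized covariates with exact sample correlation 0.9:
        # VIF = 1/(1-0.81) = 5.26..., so one of the pair is dropped
        rng = np.random.default_rng(2)
        z1 = rng.standard_normal(400)
        z2 = rng.standard_normal(400)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 -= z2 @ z1 / 400 * z1
        z2 = (z2 - z2.mean()) / z2.std()
        x2 = 0.9 * z1 + math.sqrt(1 - 0.81) * z2
        design = pd.DataFrame({"a": z1, "b": x2})
        y = np.ones(400)  # constant response -> exactly constant weights
        res = ar.vif_screen(design, y, np.zeros(400))
        assert res.vifs["a"] == pytest.approx(1 / (1 - 0.81), rel=1e-6)
        assert len(res.retained) == 1 and len(res.dropped) == 1

    def test_needs_two_covariates(self):
        with pytest.raises(ValidationError):
            ar.vif_screen(pd.DataFrame({"a": [1.0, 2.0, 3.0]}),
                          np.ones(3), np.zeros(3))


def _degenerate_spec(**kw):
    base = dict(include_spatial=False, include_temporal=False, chains=2,
                iterations=1500, burn_in=700, thin=2, seed=17)
    base.update(kw)
    return ar.RiskModelSpec(**base)


class TestFit:
    def test_prior_sanity_alpha_near_zero(self):
        # observed == expected with a flat design: alpha should sit at 0
        counts = full_grid_counts(["A", "B", "C", "D"], [2010, 2011],
                                  population=10_000, events=25)
        table = ar.sir_table(counts)
        icar = icar_structure(build_adjacency(grid_polygons(2, 2)))
        table["area_id"] = np.repeat(icar.ids, 2)
        spec = _degenerate_spec()
        res = ar.fit(table, None, icar, spec)
        a = res.coefficient("intercept")
        assert abs(a.mean) < 2 * a.sd + 1e-3

    def test_positive_observed_needs_positive_expected(self):
        icar = icar_structure(build_adjacency(grid_polygons(1, 2)))
        table = pd.DataFrame({
            "area_id": list(icar.ids) * 2, "year": [2010] * 2 + [2011] * 2,
            "observed": [3, 0, 1, 0], "expected": [1.0, 0.0, 1.0, 0.0],
        })
        table.loc[1, "observed"] = 5  # O>0 with E=0
        with pytest.raises(ValidationError):
            ar.fit(table, None, icar, _degenerate_spec())

    def test_seeded_determinism(self, small_dataset):
        table = ar.sir_table(small_dataset.counts)
        spec = ar.RiskModelSpec(chains=2, iterations=400, burn_in=200,
                                thin=2, seed=21)
        r1 = ar.fit(table, small_dataset.covariates, small_dataset.icar, spec)
        r2 = ar.fit(table, small_dataset.covariates, small_dataset.icar, spec)
        for key in r1.draws:
            np.testing.assert_array_equal(r1.draws[key], r2.draws[key])

    def test_structured_effect_sums_to_zero(self, small_fit):
        u = small_fit.draws["u"]
        assert np.abs(u.sum(axis=-1)).max() < 1e-8

    def test_cached_loglik_matches_recomputation(self, small_fit):
        for chain, draw in ((0, 0), (1, 5)):
            ll = small_fit.pointwise_loglik(chain, draw)
            np.testing.assert_allclose(ll, small_fit.loglik[chain, draw],
                                       atol=1e-8)

    def test_theta_positive_and_ci_ordering(self, small_fit):
        assert (small_fit.theta_mean > 0).all()
        for name in small_fit.coef_names:
            c = small_fit.coefficient(name)
            assert c.ci_low <= c.ci_high

    def test_island_structured_effect_fixed_at_zero(self):
        # one isolated area: its u must stay 0; v absorbs its deviation
        edges = [("A", "B"), ("B", "C"), ("A", "C")]
        graph = build_adjacency(edges, ids=["A", "B", "C", "Z"])
        icar = icar_structure(graph)
        rng = np.random.default_rng(5)
        rows = []
        for a in icar.ids:
            for y in (2010, 2011, 2012):
                rows.append({"area_id": a, "year": y,
                             "observed": rng.poisson(20), "expected": 20.0})
        table = pd.DataFrame(rows)
        spec = ar.RiskModelSpec(include_temporal=False, chains=1,
                                iterations=300, burn_in=100, thin=1, seed=3)
        res = ar.fit(table, None, icar, spec)
        z = list(icar.ids).index("Z")
        assert np.all(res.draws["u"][..., z] == 0.0)

    def test_variant_and_delta_prior_options_run(self, small_dataset):
        table = ar.sir_table(small_dataset.counts)
        for kw in ({"spatial_variant": "scaled_bym"}, {"delta_prior": "iid"}):
            spec = ar.RiskModelSpec(chains=1, iterations=200, burn_in=100,
                                    thin=1, seed=2, **kw)
            res = ar.fit(table, small_dataset.covariates,
                         small_dataset.icar, spec)
            assert np.isfinite(res.waic)


class TestFittedRR:
    def _result_with_theta(self, theta, ids, years):
        return model.FitResult(ids=tuple(ids), years=tuple(years),
                               coef_names=("intercept",),
                               spec=_degenerate_spec(), draws={},
                               loglik=np.zeros((1, 1, 1)),
                               theta_mean=theta,
                               mask=np.ones_like(theta, dtype=bool))

    def test_unit_theta_every_aggregation_is_one(self):
        res = self._result_with_theta(np.ones((4, 3)), list("ABCD"),
                                      [2010, 2011, 2012])
        regions = {a: "R" for a in "ABCD"}
        assert (ar.fitted_rr(res, "area_period")["rr"] == 1).all()
        assert (ar.fitted_rr(res, "area_mean")["rr"] == 1).all()
        assert (ar.fitted_rr(res, "region_year_mean", regions)["mean_rr"]
                == 1).all()

    def test_region_mean_of_half_and_three_halves(self):
        theta = np.array([[0.5, 0.5], [1.5, 1.5]])
        res = self._result_with_theta(theta, ["A", "B"], [2010, 2011])
        out = ar.fitted_rr(res, "region_year_mean", {"A": "R", "B": "R"})
        assert np.allclose(out["mean_rr"], 1.0)

    def test_region_year_matches_brute_force(self, small_dataset, small_fit):
        regions = small_dataset.counts[["area_id", "region_id"]] \
            .drop_duplicates()
        out = ar.fitted_rr(small_fit, "region_year_mean", regions)
        area = ar.fitted_rr(small_fit, "area_period")
        area = area.merge(regions, on="area_id")
        for _, row in out.sample(5, random_state=0).iterrows():
            sel = area[(area["region_id"] == row["region_id"]) &
                       (area["year"] == row["year"])]["rr"]
            assert row["mean_rr"] == pytest.approx(sel.mean(), rel=1e-12)

    def test_unknown_region_is_error(self, small_fit):
        with pytest.raises(ValidationError):
            ar.fitted_rr(small_fit, "region_year_mean",
                         {small_fit.ids[0]: "R"})


class TestSpecConfig:
    def test_iterations_must_exceed_burn_in(self):
        with pytest.raises(ValueError):
            ar.RiskModelSpec(iterations=100, burn_in=100)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "model.yaml"
        p.write_text("chains: 2\niterations: 500\nburn_in: 200\nseed: 4\n")
        spec = ar.RiskModelSpec.from_yaml(p)
        assert spec.chains == 2 and spec.seed == 4

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "model.yaml"
        p.write_text("chainz: 2\n")
        with pytest.raises(ValueError, match="chainz"):
            ar.RiskModelSpec.from_yaml(p)
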