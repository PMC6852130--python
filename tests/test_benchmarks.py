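"""Benchmark grids, cell distributions, quantile tables, and comparisons."""

import numpy as np
import pandas as pd
import pytest

import arviz as az

from vegbench.benchmarks import (
    GridConfig,
    RAINFALL_LEVELS,
    benchmark_quantiles,
    build_benchmark_table,
    cell_distribution,
    compare_to_elicited,
    enumerate_grid,
)
from vegbench.errors import ConfigurationError, DataError
from vegbench.floristic import GROWTH_FORMS, CovariateScaling
from vegbench.model.fit import PosteriorDraws, _default_coords
from vegbench.model.spec import G
from vegbench.simulate import SimulationScenario, draw_true_params

_STATIC_VARS = (
    "alpha", "beta", "theta", "delta", "iota", "eps", "zeta", "eta",
    "sigma_v", "sigma_f", "sigma_r", "sigma_y", "sigma_p", "sigma_s",
    "phi", "gamma_b", "kappa", "sigma_b", "sigma_m",
)


def make_draws(params, spec, n_samples=400, jitter=0.0, seed=0):
    """Synthetic PosteriorDraws: a ParamSet replicated (optionally jittered)."""
    rng = np.random.default_rng(seed)
    store = {}
    for name in _STATIC_VARS:
        base = np.asarray(getattr(params, name), dtype=float)
        arr = np.broadcast_to(base, (1, n_samples) + base.shape).copy()
        if jitter and name not in ("phi",):
            arr += jitter * rng.standard_normal(arr.shape)
        if name.startswith("sigma"):
            arr = np.abs(arr) + 1e-6
        store[name] = arr
    idata = az.from_dict(posterior=store)
    scaling = CovariateScaling(r_mean=600.0, r_sd=200.0, e_mean=8.0, e_sd=6.0)
    return PosteriorDraws(idata, spec, scaling, _default_coords(spec), {})


@pytest.fixture(scope="module")
def scenario():
    return SimulationScenario(n_classes=2, n_formations=1, n_bioregions=2,
                              n_years=2, n_plots=4, n_surveys=10)


@pytest.fixture(scope="module")
def params(scenario):
    return draw_true_params(scenario, 7, "richness")


@pytest.fixture(scope="module")
def levels(scenario):
    rows = []
    for b in range(scenario.n_bioregions):
        for v in range(scenario.n_classes):
            base = 400.0 + 150 * b + 30 * v
            rows.append({"bioregion": f"bioregion_{b}", "veg_class": f"class_{v}",
                         "q10": base - 100, "q50": base, "q90": base + 150})
    return pd.DataFrame(rows)


def _config(scenario, levels, **kw):
    return GridConfig(
        bioregions=[f"bioregion_{b}" for b in range(scenario.n_bioregions)],
        veg_classes=[f"class_{v}" for v in range(scenario.n_classes)],
        rainfall_levels=levels,
        **kw,
    )


class TestEnumerateGrid:
    def test_full_study_grid_counts(self, levels):
        config = GridConfig(
            bioregions=[f"b{i}" for i in range(18)],
            veg_classes=[f"c{i}" for i in range(95)],
            rainfall_levels=levels,
        )
        _, static = enumerate_grid(config, "static")
        assert static["cells"] == 1710
        assert static["grand_total_both_responses"] == 20520
        _, dyn = enumerate_grid(config, "dynamic")
        assert dyn["cells"] == 20520
        assert dyn["grand_total_both_responses"] == 738720

    def test_single_cell_monthly_expansion(self, levels):
        config = GridConfig(bioregions=["b"], veg_classes=["c"],
                            rainfall_levels=levels)
        cells, counts = enumerate_grid(config, "dynamic")
        assert len(cells) == 12 and counts["cells"] == 12

    def test_duplicate_labels_rejected(self, levels):
        with pytest.raises(ConfigurationError):
            GridConfig(bioregions=["b"], veg_classes=["c", "c"],
                       rainfall_levels=levels)


class TestBenchmarkQuantiles:
    def test_constant_sample(self):
        sample = np.full((200, 6), 3.5)
        q = benchmark_quantiles(sample)
        assert np.allclose(q, 3.5)

    def test_matches_sort_interpolation_oracle(self):
        sample = np.tile(np.arange(1.0, 101.0)[:, None], (1, 6))
        q = benchmark_quantiles(sample, (0.55, 0.65, 0.75))
        for row, prob in zip(q, (0.55, 0.65, 0.75)):
            x = np.arange(1.0, 101.0)
            h = (len(x) - 1) * prob
            lo = int(h)
            expected = x[lo] + (h - lo) * (x[lo + 1] - x[lo])
            assert np.allclose(row, expected)

    def test_quantiles_nondecreasing(self):
        rng = np.random.default_rng(0)
        sample = rng.lognormal(1.0, 1.0, (500, 6))
        q = benchmark_quantiles(sample)
        assert np.all(np.diff(q, axis=0) >= 0)

    def test_sample_floor_enforced(self):
        with pytest.raises(DataError, match="floor"):
            benchmark_quantiles(np.ones((50, 6)))


class TestCellDistribution:
    def test_point_mass_draws_give_exp_mu(self, scenario, params, levels):
        draws = make_draws(params, scenario.build_spec("richness"), 200)
        config = _config(scenario, levels, include_sigma=False)
        cell = {"bioregion": "bioregion_0", "veg_class": "class_1"}
        sample = cell_distribution(draws, cell, config, 600.0, np.random.default_rng(0))
        mu = (params.alpha + params.beta[1] + params.gamma_b[0]
              + draws.scaling.standardize_r(600.0) * params.delta[0]
              + draws.scaling.e0_std * params.eps)
        assert np.allclose(sample, np.exp(mu)[None, :])

    def test_alpha_only_cell_is_constant_rate(self, scenario, levels):
        params = draw_true_params(
            SimulationScenario(
                n_classes=2, n_formations=1, n_bioregions=2, n_years=2,
                n_plots=4, n_surveys=10,
                sigma_v=1e-12, sigma_f=1e-12, sigma_b=1e-12, sigma_m=1e-12,
                sigma_r=1e-12, sigma_y=1e-12, sigma_p=1e-12, sigma_s=1e-12,
            ),
            0, "richness",
        )
        params.alpha = np.full(G, np.log(5.0))
        params.iota = np.zeros(G)
        params.eps = np.zeros(G)
        spec = SimulationScenario(n_classes=2, n_formations=1, n_bioregions=2,
                                  n_years=2, n_plots=4,
                                  n_surveys=10).build_spec("richness")
        draws = make_draws(params, spec, 200)
        config = _config(
            SimulationScenario(n_classes=2, n_formations=1, n_bioregions=2,
                               n_years=2, n_plots=4, n_surveys=10),
            levels, include_sigma=False,
        )
        cell = {"bioregion": "bioregion_0", "veg_class": "class_0"}
        sample = cell_distribution(
            draws, cell, config, draws.scaling.r_mean, np.random.default_rng(0)
        )
        # rainfall at its mean standardizes to 0; nonnative slope is zero
        assert np.allclose(sample, 5.0, rtol=1e-9)

    def test_overdispersion_flag_increases_spread(self, scenario, params, levels):
        spec = scenario.build_spec("richness")
        draws = make_draws(params, spec, 600, jitter=0.05, seed=1)
        cell = {"bioregion": "bioregion_1", "veg_class": "class_0"}
        off = cell_distribution(
            draws, cell, _config(scenario, levels, include_sigma=False),
            500.0, np.random.default_rng(2),
        )
        on = cell_distribution(
            draws, cell, _config(scenario, levels, include_sigma=True),
            500.0, np.random.default_rng(2),
        )
        assert np.all(np.log(on).var(axis=0) > np.log(off).var(axis=0))

    def test_unknown_cell_rejected(self, scenario, params, levels):
        draws = make_draws(params, scenario.build_spec("richness"), 200)
        config = _config(scenario, levels)
        with pytest.raises(DataError, match="unknown"):
            cell_distribution(draws, {"bioregion": "bioregion_0",
                                      "veg_class": "class_99"},
                              config, 500.0, np.random.default_rng(0))


class TestBenchmarkTable:
    def test_row_count_formula(self, scenario, params, levels):
        draws = make_draws(params, scenario.build_spec("richness"), 150,
                           jitter=0.02)
        config = _config(scenario, levels)
        static = build_benchmark_table(draws, config, "static")
        assert len(static) == 2 * 2 * len(GROWTH_FORMS) * 3  # cells x gf x quantiles
        dynamic = build_benchmark_table(draws, config, "dynamic")
        assert len(dynamic) == 2 * 2 * 12 * 3 * len(GROWTH_FORMS) * 3

    def test_quantile_monotonicity_within_keys(self, scenario, params, levels):
        draws = make_draws(params, scenario.build_spec("richness"), 300,
                           jitter=0.1, seed=3)
        table = build_benchmark_table(draws, _config(scenario, levels), "dynamic")
        keys = ["bioregion", "veg_class", "month", "rainfall_level", "growth_form"]
        for _, grp in table.groupby(keys):
            vals = grp.sort_values("quantile")["value"].to_numpy()
            assert np.all(np.diff(vals) >= 0)
        assert (table["value"] >= 0).all()

    def test_rainfall_level_monotonicity_with_positive_slopes(
        self, scenario, params, levels
    ):
        positive = draw_true_params(scenario, 7, "richness")
        positive.delta = np.abs(positive.delta) + 0.1
        draws = make_draws(positive, scenario.build_spec("richness"), 200,
                           jitter=0.02, seed=4)
        config = _config(scenario, levels, include_sigma=False)
        table = build_benchmark_table(draws, config, "dynamic")
        wide = table.pivot_table(
            index=["bioregion", "veg_class", "month", "growth_form", "quantile"],
            columns="rainfall_level", values="value",
        )
        assert (wide["below_average"] <= wide["average"]).all()
        assert (wide["average"] <= wide["above_average"]).all()

    def test_missing_rainfall_levels_listed(self, scenario, params, levels):
        draws = make_draws(params, scenario.build_spec("richness"), 150)
        short = levels[levels["veg_class"] != "class_1"]
        with pytest.raises(DataError, match="class_1"):
            build_benchmark_table(draws, _config(scenario, short), "static")

    def test_extrapolated_cells_flagged(self, scenario, params, levels):
        draws = make_draws(params, scenario.build_spec("richness"), 150)
        config = _config(scenario, levels,
                         observed_cells={("bioregion_0", "class_0")})
        table = build_benchmark_table(draws, config, "static")
        seen = table[~table["extrapolated"]]
        assert set(zip(seen["bioregion"], seen["veg_class"])) == {
            ("bioregion_0", "class_0")
        }

    def test_grid_relabeling_permutes_rows_only(self, scenario, params, levels):
        draws = make_draws(params, scenario.build_spec("richness"), 150)
        base = _config(scenario, levels, include_sigma=False)
        flipped = GridConfig(
            bioregions=list(reversed(base.bioregions)),
            veg_classes=list(reversed(base.veg_classes)),
            rainfall_levels=levels,
            include_sigma=False,
        )
        key = ["bioregion", "veg_class", "growth_form", "quantile"]
        a = build_benchmark_table(draws, base, "static").sort_values(key)
        b = build_benchmark_table(draws, flipped, "static").sort_values(key)
        assert np.allclose(a["value"].to_numpy(), b["value"].to_numpy())


class TestCompareToElicited:
    def _table(self, lo, mid, hi):
        rows = []
        for q, v in zip((0.55, 0.65, 0.75), (lo, mid, hi)):
            rows.append({"mode": "static", "response": "richness",
                         "bioregion": "b1", "veg_class": "c1", "month": "",
                         "rainfall_level": "average", "growth_form": "forb",
                         "quantile": q, "value": v, "extrapolated": False})
        return pd.DataFrame(rows)

    def test_identical_bands_overlap_with_zero_difference(self):
        table = self._table(4.0, 5.0, 6.0)
        elicited = pd.DataFrame([{"bioregion": "b1", "veg_class": "c1",
                                  "growth_form": "forb", "mean": 5.0,
                                  "lo10": 4.0, "hi90": 6.0}])
        report, unmatched = compare_to_elicited(table, elicited)
        assert not unmatched
        assert report.iloc[0]["overlap"]
        assert report.iloc[0]["midpoint_diff"] == 0.0

    def test_disjoint_bands_do_not_overlap(self):
        table = self._table(4.0, 5.0, 6.0)
        elicited = pd.DataFrame([{"bioregion": "b1", "veg_class": "c1",
                                  "growth_form": "forb", "mean": 10.0,
                                  "lo10": 8.0, "hi90": 12.0}])
        report, _ = compare_to_elicited(table, elicited)
        assert not report.iloc[0]["overlap"]
        assert report.iloc[0]["midpoint_diff"] == pytest.approx(-5.0)

    def test_unmatched_keys_reported_not_fatal(self):
        table = self._table(4.0, 5.0, 6.0)
        elicited = pd.DataFrame(
            [
                {"bioregion": "b1", "veg_class": "c1", "growth_form": "forb",
                 "mean": 5.0, "lo10": 4.5, "hi90": 7.0},
                {"bioregion": "b9", "veg_class": "c9", "growth_form": "tree",
                 "mean": 2.0, "lo10": 1.0, "hi90": 3.0},
            ]
        )
        report, unmatched = compare_to_elicited(table, elicited)
        assert len(report) == 1
        assert unmatched == [("b9", "c9", "tree")]
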