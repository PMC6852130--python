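"""Best-on-offer benchmark tables from posterior draws.

A benchmark is an upper quantile (by default the 55th, 65th and 75th) of the
posterior distribution of expected species richness or summed cover for a grid
cell, at 0% nonnative cover.  Static benchmarks give one value per
bioregion x vegetation-class cell at that cell's average (50th-quantile)
historical rainfall; dynamic benchmarks give one value per
bioregion x class x month cell at each of three rainfall levels (below
average, average, above average).

By default the cell distribution is the posterior of the expected response for
a new plot in an average year: the linear predictor omits the year and plot
deviations, includes the multivariate-normal overdispersion (a site-level
state, not survey noise), and excludes Poisson / lognormal observation noise.
All four choices are flags on :class:`GridConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .floristic import GROWTH_FORMS
from .model.densities import COVER_OFFSET
from .model.fit import PosteriorDraws

DEFAULT_QUANTILES = (0.55, 0.65, 0.75)
RAINFALL_LEVELS = ("below_average", "average", "above_average")
_LEVEL_COL = {"below_average": "q10", "average": "q50", "above_average": "q90"}


@dataclass
class GridConfig:
    """Benchmark grid: labels, rainfall levels, quantiles, marginalization flags."""

    bioregions: list[str]
    veg_classes: list[str]
    rainfall_levels: pd.DataFrame  # columns: bioregion, veg_class, q10, q50, q90
    months: tuple[int, ...] = tuple(range(1, 13))
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    nonnative_raw: float = 0.0
    include_sigma: bool = True
    include_year: bool = False
    include_plot: bool = False
    include_obs_noise: bool = False
    observed_cells: set | None = None
    min_sample: int = 100

    def __post_init__(self) -> None:
        q = np.asarray(self.quantiles, dtype=float)
        if np.any((q <= 0) | (q >= 1)) or np.any(np.diff(q) <= 0):
            raise ConfigurationError(
                "quantiles must be strictly increasing inside (0, 1)"
            )
        if len(set(self.veg_classes)) != len(self.veg_classes):
            raise ConfigurationError("duplicate vegetation-class labels")
        if len(set(self.bioregions)) != len(self.bioregions):
            raise ConfigurationError("duplicate bioregion labels")


def enumerate_grid(config: GridConfig, mode: str) -> tuple[list[dict], dict]:
    """All benchmark cells plus the combinatorial count summary.

    Static cells are bioregion x class; dynamic cells add month.  The summary
    reports the cell count, the benchmark count per growth form and rainfall
    level (equal to the cell count), the total for one response
    (cells x 6 growth forms x rainfall levels), and the grand total over both
    responses (richness and cover).
    """
    if mode not in ("static", "dynamic"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    cells = []
    for b in config.bioregions:
        for v in config.veg_classes:
            if mode == "static":
                cells.append({"bioregion": b, "veg_class": v})
            else:
                for m in config.months:
                    cells.append({"bioregion": b, "veg_class": v, "month": m})
    n_levels = 3 if mode == "dynamic" else 1
    n_cells = len(cells)
    counts = {
        "cells": n_cells,
        "benchmarks_per_growthform_per_level": n_cells,
        "total_one_response": n_cells * len(GROWTH_FORMS) * n_levels,
        "grand_total_both_responses": n_cells * len(GROWTH_FORMS) * n_levels * 2,
    }
    return cells, counts


def _index_of(label, labels, what: str) -> int:
    try:
        return list(labels).index(label)
    except ValueError:
        raise DataError(f"unknown {what} {label!r}") from None


def cell_distribution(
    draws: PosteriorDraws,
    cell: dict,
    config: GridConfig,
    rainfall_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Posterior sample (n_samples, 6) of response-scale values for one cell.

    ``rainfall_mm`` is raw 12-month rainfall; it and the raw 0% nonnative
    cover are standardized through the scaling stored with the draws.  Cover
    values are back-transformed as exp(log lambda) - 0.001, floored at 0.
    """
    spec = draws.spec
    if draws.scaling is None:
        raise DataError("draws carry no covariate scaling; cannot predict")
    vi = _index_of(cell["veg_class"], draws.coords["veg_class"], "vegetation class")
    bi = _index_of(cell["bioregion"], draws.coords["bioregion"], "bioregion")

    r_std = float(draws.scaling.standardize_r(rainfall_mm))
    e_std = float(draws.scaling.standardize_e(config.nonnative_raw))

    mu = (
        draws.stacked("alpha")
        + draws.stacked("beta")[:, vi, :]
        + r_std * draws.stacked("delta")[:, bi, :]
        + e_std * draws.stacked("eps")
    )
    if spec.variant == "dynamic":
        if "month" not in cell:
            raise DataError("dynamic cells need a month")
        mi = int(cell["month"]) - 1
        mu = mu + draws.stacked("gamma_mb")[:, mi, bi, :]
    else:
        mu = mu + draws.stacked("gamma_b")[:, bi, :]
        # month deviations are zero-mean; static benchmarks use the typical month
    S = mu.shape[0]
    if config.include_year:
        mu = mu + draws.stacked("sigma_y") * rng.standard_normal((S, 6))
    if config.include_plot:
        mu = mu + draws.stacked("sigma_p") * rng.standard_normal((S, 6))
    if config.include_sigma:
        sigma_s = draws.stacked("sigma_s")
        phi = draws.stacked("phi")
        Ls = sigma_s[:, :, None] * np.linalg.cholesky(phi)
        z = rng.standard_normal((S, 6))
        mu = mu + np.einsum("sij,sj->si", Ls, z)
    loglam = mu
    if spec.response == "richness":
        values = np.exp(loglam)
        if config.include_obs_noise:
            values = rng.poisson(values).astype(float)
    else:
        if config.include_obs_noise:
            sigma_o = draws.stacked("sigma_obs")
            loglam = loglam + sigma_o * rng.standard_normal((S, 6))
        values = np.clip(np.exp(loglam) - COVER_OFFSET, 0.0, None)
    return values


def benchmark_quantiles(
    sample: np.ndarray,
    quantiles=DEFAULT_QUANTILES,
    *,
    min_sample: int = 100,
) -> np.ndarray:
    """Marginal empirical quantiles per growth form: returns (n_quantiles, 6).

    Quantiles are taken independently for each growth form; a joint
    multivariate quantile has no single-number-per-growth-form summary.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2 or sample.shape[1] != len(GROWTH_FORMS):
        raise DataError("sample must be (n, 6)")
    if sample.shape[0] < min_sample:
        raise DataError(
            f"sample size {sample.shape[0]} below the floor of {min_sample}"
        )
    return np.quantile(sample, np.asarray(quantiles), axis=0)


def _cell_rainfall(config: GridConfig, bioregion: str, veg_class: str) -> dict:
    lv = config.rainfall_levels
    row = lv[(lv["bioregion"] == bioregion) & (lv["veg_class"] == veg_class)]
    if row.empty:
        return {}
    return {name: float(row.iloc[0][col]) for name, col in _LEVEL_COL.items()}


def build_benchmark_table(
    draws: PosteriorDraws,
    config: GridConfig,
    mode: str,
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Benchmark table over the full grid.

    Static mode emits one row per (bioregion, class, growth form, quantile) at
    the cell's average rainfall; dynamic mode adds month and all three
    rainfall levels.  Cells without observed data are flagged ``extrapolated``.
    """
    cells, _ = enumerate_grid(config, mode)
    rng = np.random.default_rng(seed)
    missing = [
        (c["bioregion"], c["veg_class"])
        for c in cells
        if not _cell_rainfall(config, c["bioregion"], c["veg_class"])
    ]
    if missing:
        raise DataError(f"missing rainfall levels for cells: {sorted(set(missing))}")

    levels = RAINFALL_LEVELS if mode == "dynamic" else ("average",)
    qs = np.asarray(config.quantiles)
    rows = []
    for cell in cells:
        rain = _cell_rainfall(config, cell["bioregion"], cell["veg_class"])
        extrapolated = (
            config.observed_cells is not None
            and (cell["bioregion"], cell["veg_class"]) not in config.observed_cells
        )
        for level in levels:
            sample = cell_distribution(draws, cell, config, rain[level], rng)
            qvals = benchmark_quantiles(sample, qs, min_sample=config.min_sample)
            for qi, q in enumerate(qs):
                for gi, gf in enumerate(GROWTH_FORMS):
                    rows.append(
                        {
                            "mode": mode,
                            "response": draws.spec.response,
                            "bioregion": cell["bioregion"],
                            "veg_class": cell["veg_class"],
                            "month": cell.get("month", ""),
                            "rainfall_level": level,
                            "growth_form": gf,
                            "quantile": float(q),
                            "value": float(qvals[qi, gi]),
                            "extrapolated": extrapolated,
                        }
                    )
    return pd.DataFrame(rows)


def compare_to_elicited(
    table: pd.DataFrame, elicited: pd.DataFrame
) -> tuple[pd.DataFrame, list[tuple]]:
    """Compare modeled benchmark bands to expert-elicited benchmark ranges.

    ``elicited`` has columns (bioregion, veg_class, growth_form, mean, lo10,
    hi90).  For each matched (bioregion, class, growth form) key the report
    gives the modeled 55th-75th quantile band, the elicited mean and 10th-90th
    range, whether the two bands overlap, and the signed difference of
    midpoints (modeled 65th quantile minus elicited mean).  Unmatched elicited
    keys are returned separately, not raised.
    """
    required = {"bioregion", "veg_class", "growth_form", "mean", "lo10", "hi90"}
    if not required.issubset(elicited.columns):
        raise DataError(f"elicited table needs columns {sorted(required)}")
    wide = table.pivot_table(
        index=["bioregion", "veg_class", "growth_form"],
        columns="quantile",
        values="value",
    )
    qs = sorted(wide.columns)
    lo_q, mid_q, hi_q = qs[0], qs[len(qs) // 2], qs[-1]
    rows, unmatched = [], []
    for _, erow in elicited.iterrows():
        key = (erow["bioregion"], erow["veg_class"], erow["growth_form"])
        if key not in wide.index:
            unmatched.append(key)
            continue
        mrow = wide.loc[key]
        lo, mid, hi = float(mrow[lo_q]), float(mrow[mid_q]), float(mrow[hi_q])
        overlap = not (hi < erow["lo10"] or lo > erow["hi90"])
        rows.append(
            {
                "bioregion": key[0],
                "veg_class": key[1],
                "growth_form": key[2],
                "modeled_lo": lo,
                "modeled_mid": mid,
                "modeled_hi": hi,
                "elicited_mean": float(erow["mean"]),
                "elicited_lo10": float(erow["lo10"]),
                "elicited_hi90": float(erow["hi90"]),
                "overlap": overlap,
                "midpoint_diff": mid - float(erow["mean"]),
            }
        )
    return pd.DataFrame(rows), unmatched
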