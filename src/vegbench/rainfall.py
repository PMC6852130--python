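"""Accumulated-rainfall covariates and historical rainfall levels.

Recent rainfall enters the benchmark models as the total rainfall in the 12
months before each survey.  Benchmarks are then reported at three rainfall
levels — below average, average, above average — defined as the 10th, 50th and
90th quantiles of the historical (e.g. 1900-2015) distribution of 12-month
accumulated rainfall anchored at the survey month.  Where a bioregion x
vegetation-class combination has no surveyed location, its levels are imputed
from additive linear regressions of each quantile on bioregion and class.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .errors import DataError

logger = logging.getLogger(__name__)

QUANTILE_LEVELS = (0.10, 0.50, 0.90)
LEVEL_NAMES = {"q10": "below_average", "q50": "average", "q90": "above_average"}


def _check_daily(series: pd.Series) -> pd.Series:
    if not isinstance(series.index, pd.DatetimeIndex):
        raise DataError("rainfall series must be indexed by dates")
    if not series.index.is_monotonic_increasing or series.index.has_duplicates:
        raise DataError("rainfall series dates must be strictly increasing")
    if (series < 0).any():
        raise DataError("rainfall values must be non-negative")
    return series


def accumulate(
    series: pd.Series, survey_date, *, window_months: int = 12
) -> float:
    """Total rainfall over the window ending the day before ``survey_date``.

    The window is calendar-anchored and half-open: it starts on the same
    calendar date ``window_months`` earlier and ends the day before the survey
    (the survey day itself is excluded).  The series must cover every day in
    the window; a gap is an error naming the missing span.
    """
    series = _check_daily(series)
    end = pd.Timestamp(survey_date)
    start = end - pd.DateOffset(months=window_months)
    expected = pd.date_range(start, end - pd.Timedelta(days=1), freq="D")
    window = series.reindex(expected)
    missing = window.index[window.isna()]
    if len(missing):
        raise DataError(
            f"rainfall series does not cover {missing.min().date()} .. "
            f"{missing.max().date()} ({len(missing)} missing days) for window "
            f"[{start.date()}, {end.date()})"
        )
    return float(window.sum())


def accumulate_12mo(series: pd.Series, survey_date) -> float:
    """12-month accumulated rainfall before a survey (the model covariate)."""
    return accumulate(series, survey_date, window_months=12)


def historical_quantiles(
    series: pd.Series,
    month: int,
    years: Iterable[int],
    q: Sequence[float] = QUANTILE_LEVELS,
    *,
    window_months: int = 12,
) -> np.ndarray:
    """Empirical quantiles of historical accumulated rainfall for one month.

    For each year, the accumulation window is anchored at the first day of
    ``month``; years the series does not fully cover are skipped.  Quantiles
    use linear interpolation of order statistics (numpy's default rule).
    """
    if not 1 <= int(month) <= 12:
        raise DataError(f"month {month} not in 1..12")
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise DataError("quantile levels must lie strictly inside (0, 1)")
    totals = []
    for year in years:
        anchor = pd.Timestamp(int(year), int(month), 1)
        try:
            totals.append(accumulate(series, anchor, window_months=window_months))
        except DataError:
            continue  # year not fully covered
    if len(totals) < 2:
        raise DataError(
            f"fewer than 2 usable years for month {month}: got {len(totals)}"
        )
    return np.quantile(np.asarray(totals), q)


def levels_for_series(
    daily: pd.DataFrame,
    month: int,
    years: Iterable[int],
) -> pd.DataFrame:
    """Per-location rainfall levels (q10/q50/q90) for one survey month.

    ``daily`` has columns (location_id, date, mm).
    """
    rows = []
    for loc, grp in daily.groupby("location_id"):
        s = pd.Series(
            grp["mm"].to_numpy(), index=pd.DatetimeIndex(pd.to_datetime(grp["date"]))
        )
        q10, q50, q90 = historical_quantiles(s, month, years)
        rows.append({"location_id": loc, "month": month, "q10": q10, "q50": q50, "q90": q90})
    return pd.DataFrame(rows)


def impute_levels(
    observed: pd.DataFrame,
    targets: list[tuple[str, str]],
) -> pd.DataFrame:
    """Predict rainfall levels for bioregion x class cells by additive regression.

    ``observed`` holds one row per surveyed location (or per observed cell)
    with columns (bioregion, veg_class, q10, q50, q90).  Three separate linear
    regressions — one per quantile — are fitted by least squares with bioregion
    and vegetation class as additive categorical predictors, and predictions
    are returned for every target cell.  Cells present in ``observed`` are
    marked ``source="observed"``, the rest ``source="imputed"``.

    Every bioregion and class appearing in ``targets`` must occur at least
    once in ``observed`` (otherwise its effect is unestimable).  Predicted
    triples that come out inverted (q10 > q50, etc.) are re-sorted and logged.
    """
    required = {"bioregion", "veg_class", "q10", "q50", "q90"}
    if not required.issubset(observed.columns):
        raise DataError(f"observed levels need columns {sorted(required)}")
    obs = observed.copy()
    obs_b = set(obs["bioregion"])
    obs_v = set(obs["veg_class"])
    missing_b = sorted({b for b, _ in targets} - obs_b)
    missing_v = sorted({v for _, v in targets} - obs_v)
    if missing_b or missing_v:
        raise DataError(
            "factor levels absent from observed data: "
            f"bioregions {missing_b}, classes {missing_v}"
        )

    pred = pd.DataFrame(targets, columns=["bioregion", "veg_class"])
    for col in ("q10", "q50", "q90"):
        fit = smf.ols(f"{col} ~ C(bioregion) + C(veg_class)", data=obs).fit()
        pred[col] = fit.predict(pred).to_numpy()

    observed_cells = set(zip(obs["bioregion"], obs["veg_class"]))
    pred["source"] = [
        "observed" if (b, v) in observed_cells else "imputed"
        for b, v in zip(pred["bioregion"], pred["veg_class"])
    ]

    vals = pred[["q10", "q50", "q90"]].to_numpy()
    inverted = np.any(np.diff(vals, axis=1) < 0, axis=1)
    if inverted.any():
        for i in np.flatnonzero(inverted):
            logger.warning(
                "re-sorting inverted rainfall levels for cell (%s, %s): %s",
                pred.iloc[i]["bioregion"],
                pred.iloc[i]["veg_class"],
                vals[i].tolist(),
            )
        vals = np.sort(vals, axis=1)
        pred[["q10", "q50", "q90"]] = vals
    return pred
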