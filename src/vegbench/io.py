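"""CSV dialects for plot records, lookups, rainfall, and benchmark tables.

All files are UTF-8 CSV with a header row; dates are ISO-8601.
"""

from __future__ import annotations

import pandas as pd

from .errors import DataError
from .floristic import (
    GROWTH_FORMS,
    PlotSurvey,
    SpeciesRecord,
    aggregate_survey,
    bbca_to_cover,
)

RECORD_COLUMNS = [
    "survey_id", "plot_id", "veg_class", "formation", "bioregion",
    "month", "year", "rainfall_mm", "species", "native", "growth_form", "cover",
]


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{what} is missing columns {missing}")


def read_growth_form_lookup(path) -> dict[str, str]:
    df = pd.read_csv(path)
    _require(df, ["species", "growth_form"], "growth-form lookup")
    return dict(zip(df["species"].astype(str), df["growth_form"].astype(str)))


def read_plot_records(path, bbca_map: dict[str, float] | None = None) -> list[PlotSurvey]:
    """Read one-record-per-row plot data into PlotSurvey objects.

    The ``cover`` column may mix numeric percents and ordinal cover-class
    labels; labels are converted through ``bbca_map`` (default Braun-Blanquet
    midpoints).
    """
    df = pd.read_csv(path)
    _require(df, [c for c in RECORD_COLUMNS if c != "growth_form"], "plot records")
    surveys = []
    for sid, grp in df.groupby("survey_id", sort=False):
        head = grp.iloc[0]
        records = []
        for _, row in grp.iterrows():
            raw = row["cover"]
            # an explicit ordinal-class map takes precedence over numeric parsing
            # (ordinal class labels are often digits)
            if bbca_map is not None and str(raw) in bbca_map:
                cov = bbca_to_cover(str(raw), bbca_map, survey_id=str(sid))
            else:
                try:
                    cov = float(raw)
                except (TypeError, ValueError):
                    cov = bbca_to_cover(str(raw), bbca_map, survey_id=str(sid))
            records.append(
                SpeciesRecord(
                    survey_id=str(sid),
                    species=str(row["species"]),
                    native=bool(row["native"]),
                    cover=cov,
                    growth_form=(
                        str(row["growth_form"])
                        if "growth_form" in grp.columns and pd.notna(row.get("growth_form"))
                        else None
                    ),
                )
            )
        surveys.append(
            PlotSurvey(
                survey_id=str(sid),
                plot_id=str(head["plot_id"]),
                veg_class=str(head["veg_class"]),
                formation=str(head["formation"]),
                bioregion=str(head["bioregion"]),
                month=int(head["month"]),
                year=int(head["year"]),
                rainfall_12mo=float(head["rainfall_mm"]),
                records=records,
            )
        )
    return surveys


def aggregate_to_frame(surveys: list[PlotSurvey]) -> pd.DataFrame:
    """One row per survey: indices, covariates, and the 12 response columns."""
    rows = []
    for s in surveys:
        richness, cover, nonnative = aggregate_survey(s)
        row = {
            "survey_id": s.survey_id,
            "plot_id": s.plot_id,
            "veg_class": s.veg_class,
            "formation": s.formation,
            "bioregion": s.bioregion,
            "month": s.month,
            "year": s.year,
            "rainfall_mm": s.rainfall_12mo,
            "nonnative_cover": nonnative,
        }
        for gi, gf in enumerate(GROWTH_FORMS):
            row[f"richness_{gf}"] = int(richness.values[gi])
        for gi, gf in enumerate(GROWTH_FORMS):
            row[f"cover_{gf}"] = float(cover.values[gi])
        rows.append(row)
    return pd.DataFrame(rows)


def read_daily_rainfall(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["location_id", "date", "mm"], "daily rainfall")
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_rainfall_levels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["bioregion", "veg_class", "q10", "q50", "q90"], "rainfall levels")
    return df


def read_elicited(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(
        df, ["bioregion", "veg_class", "growth_form", "mean", "lo10", "hi90"],
        "elicited benchmarks",
    )
    return df
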