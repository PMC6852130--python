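"""Bridge from aggregated survey tables to model-ready index arrays."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .floristic import GROWTH_FORMS, CovariateScaling
from .model.spec import ModelSpec, SurveyData


def prepare_model_data(
    agg: pd.DataFrame,
    response: str,
    variant: str,
    *,
    lkj_shape: float = 4.0,
) -> tuple[ModelSpec, SurveyData, CovariateScaling, dict]:
    """Factorize labels and standardize covariates for one model fit.

    Returns the model spec (dimensions inferred from the data), the survey
    data in index form, the covariate scaling (needed again at benchmark
    time), and the label coordinate lists for the posterior draws.
    """
    needed = {"veg_class", "formation", "bioregion", "month", "year", "plot_id",
              "rainfall_mm", "nonnative_cover"}
    if not needed.issubset(agg.columns):
        raise DataError(f"aggregated table is missing {sorted(needed - set(agg.columns))}")

    classes = sorted(agg["veg_class"].unique())
    formations = sorted(agg["formation"].unique())
    bioregions = sorted(agg["bioregion"].unique())
    years = sorted(agg["year"].unique())
    plots = sorted(agg["plot_id"].unique())

    cmap = {c: i for i, c in enumerate(classes)}
    fmap = {f: i for i, f in enumerate(formations)}
    bmap = {b: i for i, b in enumerate(bioregions)}
    ymap = {y: i for i, y in enumerate(years)}
    pmap = {p: i for i, p in enumerate(plots)}

    cf_pairs = agg[["veg_class", "formation"]].drop_duplicates()
    if cf_pairs["veg_class"].duplicated().any():
        dup = cf_pairs[cf_pairs["veg_class"].duplicated()]["veg_class"].tolist()
        raise DataError(f"classes mapped to more than one formation: {dup}")
    class_formation = np.empty(len(classes), dtype=int)
    for _, row in cf_pairs.iterrows():
        class_formation[cmap[row["veg_class"]]] = fmap[row["formation"]]

    spec = ModelSpec(
        response=response,
        variant=variant,
        n_classes=len(classes),
        n_formations=len(formations),
        n_bioregions=len(bioregions),
        n_years=len(years),
        n_plots=len(plots),
        class_formation=class_formation,
        lkj_shape=lkj_shape,
    )

    r = agg["rainfall_mm"].to_numpy(dtype=float)
    e = agg["nonnative_cover"].to_numpy(dtype=float)
    if r.std() == 0 or e.std() == 0:
        raise DataError("constant covariate: cannot standardize")
    scaling = CovariateScaling(float(r.mean()), float(r.std()),
                               float(e.mean()), float(e.std()))

    cols = [f"{response}_{gf}" for gf in GROWTH_FORMS]
    if not set(cols).issubset(agg.columns):
        raise DataError(f"aggregated table is missing response columns {cols}")
    data = SurveyData(
        class_idx=agg["veg_class"].map(cmap).to_numpy(),
        bio_idx=agg["bioregion"].map(bmap).to_numpy(),
        month_idx=agg["month"].to_numpy(dtype=int) - 1,
        year_idx=agg["year"].map(ymap).to_numpy(),
        plot_idx=agg["plot_id"].map(pmap).to_numpy(),
        r=scaling.standardize_r(r),
        e=scaling.standardize_e(e),
        response=agg[cols].to_numpy(dtype=float),
    )
    coords = {
        "growth_form": list(GROWTH_FORMS),
        "growth_form2": list(GROWTH_FORMS),
        "veg_class": [str(c) for c in classes],
        "formation": [str(f) for f in formations],
        "bioregion": [str(b) for b in bioregions],
        "month": list(range(1, 13)),
        "year": [int(y) for y in years],
        "plot": [str(p) for p in plots],
    }
    return spec, data, scaling, coords


def observed_cells(agg: pd.DataFrame) -> set[tuple[str, str]]:
    """The set of (bioregion, veg_class) combinations present in the data."""
    return set(zip(agg["bioregion"].astype(str), agg["veg_class"].astype(str)))
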