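"""Floristic plot ingestion and growth-form aggregation.

A survey of a 400 m^2 floristic plot records every species present with a
visually estimated percent cover (or an ordinal Braun-Blanquet cover-abundance
label).  Every native taxon is allocated to one of six growth forms — fern,
forb, grass (and grass-like), other (not otherwise classified), shrub, tree —
and per-survey responses are built by aggregating within growth forms:

* richness: the number of distinct native species in each growth form;
* cover: the sum of percent covers of native species in each growth form
  (summed cover may exceed 100% because foliage of different species overlaps);
* nonnative cover: the summed percent cover of all nonnative species,
  irrespective of growth form.

The six growth forms are kept in fixed alphabetical order everywhere, so all
six-dimensional response vectors are directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DataError

#: Canonical growth-form order used for every 6-vector in the package.
GROWTH_FORMS: tuple[str, ...] = ("fern", "forb", "grass", "other", "shrub", "tree")

_GF_INDEX = {g: i for i, g in enumerate(GROWTH_FORMS)}


@dataclass
class SpeciesRecord:
    """One species observation within one plot survey."""

    survey_id: str
    species: str
    native: bool
    cover: float
    growth_form: str | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.cover, (int, float)):
            if not (0.0 <= float(self.cover) <= 100.0):
                raise DataError(
                    f"survey {self.survey_id!r}, species {self.species!r}: "
                    f"cover {self.cover} outside [0, 100]"
                )


@dataclass
class PlotSurvey:
    """One survey of one plot, with covariates and its species records."""

    survey_id: str
    plot_id: str
    veg_class: str
    formation: str
    bioregion: str
    month: int
    year: int
    rainfall_12mo: float
    records: list[SpeciesRecord] = field(default_factory=list)
    nonnative_cover: float | None = None
    r_std: float | None = None
    e_std: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.month) <= 12:
            raise DataError(f"survey {self.survey_id!r}: month {self.month} not in 1..12")
        if self.rainfall_12mo < 0:
            raise DataError(f"survey {self.survey_id!r}: negative 12-month rainfall")


@dataclass
class GrowthFormVector:
    """A six-dimensional per-survey response, ordered as GROWTH_FORMS."""

    values: np.ndarray
    kind: str  # "richness" | "cover"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (6,):
            raise DataError("GrowthFormVector requires exactly 6 values")
        if self.kind not in ("richness", "cover"):
            raise ConfigurationError(f"unknown kind {self.kind!r}")
        if np.any(self.values < 0):
            raise DataError("growth-form values must be non-negative")
        if self.kind == "richness" and np.any(self.values != np.round(self.values)):
            raise DataError("richness values must be integers")


@dataclass(frozen=True)
class CovariateScaling:
    """Standardization constants for rainfall and nonnative cover.

    Effects of rainfall and nonnative cover are reported per one standard
    deviation, so the scaling used at fit time must be reapplied verbatim at
    prediction time.  Population (n-denominator) standard deviations are used.
    """

    r_mean: float
    r_sd: float
    e_mean: float
    e_sd: float

    def __post_init__(self) -> None:
        if self.r_sd <= 0 or self.e_sd <= 0:
            raise DataError("covariate sd must be positive")

    def standardize_r(self, r):
        return (np.asarray(r, dtype=float) - self.r_mean) / self.r_sd

    def destandardize_r(self, z):
        return np.asarray(z, dtype=float) * self.r_sd + self.r_mean

    def standardize_e(self, e):
        return (np.asarray(e, dtype=float) - self.e_mean) / self.e_sd

    def destandardize_e(self, z):
        return np.asarray(z, dtype=float) * self.e_sd + self.e_mean

    @property
    def e0_std(self) -> float:
        """Standardized image of raw 0% nonnative cover."""
        return float(self.standardize_e(0.0))

    def to_dict(self) -> dict:
        return {
            "r_mean": self.r_mean,
            "r_sd": self.r_sd,
            "e_mean": self.e_mean,
            "e_sd": self.e_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateScaling":
        return cls(**{k: float(d[k]) for k in ("r_mean", "r_sd", "e_mean", "e_sd")})


def assign_growth_forms(
    records: list[SpeciesRecord], lookup: dict[str, str]
) -> list[SpeciesRecord]:
    """Attribute a growth form to each record from a standardized species list.

    Species absent from the lookup are flagged (``flagged=True``) and excluded
    from aggregation downstream.  Returns new records; the inputs are untouched.
    """
    if not lookup:
        raise ConfigurationError("growth-form lookup is empty")
    bad = sorted({g for g in lookup.values() if g not in _GF_INDEX})
    if bad:
        raise ConfigurationError(
            f"lookup contains categories outside the six growth forms: {bad}"
        )
    out = []
    for rec in records:
        gf = lookup.get(rec.species)
        if gf is None:
            out.append(replace(rec, growth_form=None, flagged=True))
        else:
            out.append(replace(rec, growth_form=gf, flagged=False))
    return out


def count_flagged(records: list[SpeciesRecord]) -> int:
    return sum(1 for r in records if r.flagged)


# Default Braun-Blanquet midpoint map: label -> percent cover.
DEFAULT_BBCA_MAP: dict[str, float] = {
    "1": 2.5,   # <5%, few individuals
    "2": 2.5,   # <5%, many individuals
    "3": 2.5,   # <5%, very many
    "4": 15.0,  # 5-25%
    "5": 37.5,  # 25-50%
    "6": 62.5,  # 50-75%
    "7": 87.5,  # 75-100%
}


def bbca_to_cover(
    class_label: str,
    mapping: dict[str, float] | None = None,
    *,
    survey_id: str | None = None,
) -> float:
    """Convert an ordinal cover-abundance label to percent cover via a table.

    The mapping is a pluggable deterministic table (default: Braun-Blanquet
    class midpoints); a fitted ordinal-to-cover regression can be substituted
    by passing its predictions as the mapping.
    """
    mapping = DEFAULT_BBCA_MAP if mapping is None else mapping
    bad = {k: v for k, v in mapping.items() if not (0.0 <= v <= 100.0)}
    if bad:
        raise ConfigurationError(f"cover-class mapping values outside [0, 100]: {bad}")
    key = str(class_label)
    if key not in mapping:
        where = f" (survey {survey_id!r})" if survey_id else ""
        raise DataError(f"unknown cover-class label {class_label!r}{where}")
    return float(mapping[key])


def aggregate_survey(
    survey: PlotSurvey,
) -> tuple[GrowthFormVector, GrowthFormVector, float]:
    """Aggregate a survey's species records into growth-form responses.

    Richness counts *distinct* native species per growth form; cover sums all
    native cover entries (a species recorded in several strata contributes
    each entry to cover but is counted once for richness).  Nonnative records
    contribute only to the summed nonnative cover.  Flagged records (no growth
    form) are excluded entirely.
    """
    richness_species: list[set[str]] = [set() for _ in GROWTH_FORMS]
    cover = np.zeros(6)
    nonnative = 0.0
    for rec in survey.records:
        if rec.flagged:
            continue
        if not rec.native:
            nonnative += float(rec.cover)
            continue
        if rec.growth_form is None:
            raise DataError(
                f"survey {survey.survey_id!r}: record {rec.species!r} has no "
                "growth form and is not flagged"
            )
        gi = _GF_INDEX[rec.growth_form]
        richness_species[gi].add(rec.species)
        cover[gi] += float(rec.cover)
    richness = np.array([len(s) for s in richness_species], dtype=float)
    return (
        GrowthFormVector(richness, "richness"),
        GrowthFormVector(cover, "cover"),
        nonnative,
    )


def standardize_covariates(
    surveys: list[PlotSurvey],
) -> tuple[list[PlotSurvey], CovariateScaling]:
    """Standardize 12-month rainfall and nonnative cover to mean 0, sd 1.

    Uses population (n-denominator) standard deviations.  Surveys must have
    ``nonnative_cover`` filled (e.g. by :func:`aggregate_survey`).  Returns new
    survey objects with ``r_std``/``e_std`` set, plus the scaling for reuse at
    prediction time.
    """
    if len(surveys) < 2:
        raise DataError("need at least 2 surveys to standardize covariates")
    r = np.array([s.rainfall_12mo for s in surveys], dtype=float)
    e = np.array(
        [s.nonnative_cover if s.nonnative_cover is not None else math.nan for s in surveys]
    )
    if np.any(np.isnan(e)):
        raise DataError("nonnative_cover missing on some surveys; aggregate first")
    r_sd = float(np.std(r))
    e_sd = float(np.std(e))
    if r_sd == 0:
        raise DataError("rainfall covariate is constant (sd = 0)")
    if e_sd == 0:
        raise DataError("nonnative-cover covariate is constant (sd = 0)")
    scaling = CovariateScaling(float(np.mean(r)), r_sd, float(np.mean(e)), e_sd)
    out = [
        replace(
            s,
            r_std=float(scaling.standardize_r(s.rainfall_12mo)),
            e_std=float(scaling.standardize_e(s.nonnative_cover)),
        )
        for s in surveys
    ]
    return out, scaling
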