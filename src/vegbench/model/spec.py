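"""Model specification, parameter containers, and the linear predictor.

Two responses are modelled separately: native species richness (Poisson) and
summed native cover (lognormal via log(z + 0.001)).  Both share a 6-vector
linear predictor on the log scale, with multivariate-normal survey-level
overdispersion inducing residual correlation among growth forms:

    log lambda_i ~ MVN(mu_i, Sigma),      Sigma = diag(sigma_s) Phi diag(sigma_s)

dynamic variant (regionally varying monthly trends):

    mu_i = alpha + beta_v(i) + gamma_[m(i), b(i)] + r_i * delta_b(i)
           + e_i * eps + zeta_y(i) + eta_p(i)

static variant (regionally consistent month effects):

    mu_i = alpha + beta_v(i) + gamma_b(i) + r_i * delta_b(i)
           + e_i * eps + zeta_y(i) + eta_p(i) + kappa_m(i)

All boldface parameters are 6-vectors over growth forms; r_i and e_i are the
standardized 12-month rainfall and nonnative cover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..errors import ConfigurationError, DataError

G = 6  # number of growth forms

#: Seasonal random-walk order: the walk starts in July and steps month-to-month
#: through to May; June is linked afterwards to the mean of May and July.
WALK_ORDER: tuple[int, ...] = (7, 8, 9, 10, 11, 12, 1, 2, 3, 4, 5)
JUNE = 6


@dataclass
class ModelSpec:
    """Dimensions and prior settings for one response/variant."""

    response: str  # "richness" | "cover"
    variant: str   # "dynamic" | "static"
    n_classes: int
    n_formations: int
    n_bioregions: int
    n_years: int
    n_plots: int
    class_formation: np.ndarray  # (n_classes,) formation index of each class
    lkj_shape: float = 4.0       # exponent a in p(Phi) propto |Phi|^a
    scale_prior_sd: float = 2.0  # HalfNormal sd for every scale parameter
    vague_sd: float = 10.0       # sd of the vague Normal(0, 10) priors

    n_months: int = 12
    n_growthforms: int = G

    def __post_init__(self) -> None:
        if self.response not in ("richness", "cover"):
            raise ConfigurationError(f"unknown response {self.response!r}")
        if self.variant not in ("dynamic", "static"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        for name in ("n_classes", "n_formations", "n_bioregions", "n_years", "n_plots"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.lkj_shape < 0:
            raise ConfigurationError("lkj_shape must be >= 0")
        self.class_formation = np.asarray(self.class_formation, dtype=int)
        if self.class_formation.shape != (self.n_classes,):
            raise ConfigurationError("class_formation must map every class")
        if self.class_formation.min() < 0 or self.class_formation.max() >= self.n_formations:
            raise ConfigurationError("class_formation indices out of range")


@dataclass
class ParamSet:
    """One full parameter state for one response/variant.

    Fields not used by a variant/response are ``None`` (``gamma_mb`` and
    ``sigma_rw`` are dynamic-only; ``gamma_b``, ``kappa`` and ``sigma_m`` are
    static-only; ``sigma_obs`` applies to cover only).
    """

    alpha: np.ndarray                 # (6,) grand mean of log richness / log cover
    beta: np.ndarray                  # (n_classes, 6) class deviations
    theta: np.ndarray                 # (n_formations, 6) formation means
    delta: np.ndarray                 # (n_bioregions, 6) rainfall slopes
    iota: np.ndarray                  # (6,) rainfall grand mean
    eps: np.ndarray                   # (6,) nonnative-cover slope
    zeta: np.ndarray                  # (n_years, 6) year deviations
    eta: np.ndarray                   # (n_plots, 6) plot deviations
    sigma_v: np.ndarray               # (6,) class-deviation scale
    sigma_f: np.ndarray               # (6,) formation-mean scale
    sigma_r: np.ndarray               # (6,) rainfall-slope scale
    sigma_y: np.ndarray               # (6,) year scale
    sigma_p: np.ndarray               # (6,) plot scale
    sigma_s: np.ndarray               # (6,) overdispersion scales
    phi: np.ndarray                   # (6, 6) residual correlation matrix
    gamma_mb: Optional[np.ndarray] = None   # (12, n_bioregions, 6) dynamic
    sigma_rw: Optional[np.ndarray] = None   # (n_bioregions, 6) random-walk sd
    gamma_b: Optional[np.ndarray] = None    # (n_bioregions, 6) static
    kappa: Optional[np.ndarray] = None      # (12, 6) static month deviations
    sigma_b: Optional[np.ndarray] = None    # (6,) static bioregion scale
    sigma_m: Optional[np.ndarray] = None    # (6,) static month scale
    sigma_obs: Optional[np.ndarray] = None  # (6,) lognormal observation sd (cover)

    @property
    def Sigma(self) -> np.ndarray:
        """Covariance diag(sigma_s) Phi diag(sigma_s)."""
        return self.sigma_s[:, None] * self.phi * self.sigma_s[None, :]


@dataclass
class SurveyData:
    """Aggregated per-survey data in index form, ready for model fitting."""

    class_idx: np.ndarray   # (n,) 0-based vegetation-class index
    bio_idx: np.ndarray     # (n,) bioregion index
    month_idx: np.ndarray   # (n,) month index, 0..11 for months 1..12
    year_idx: np.ndarray    # (n,) year index
    plot_idx: np.ndarray    # (n,) plot index
    r: np.ndarray           # (n,) standardized 12-month rainfall
    e: np.ndarray           # (n,) standardized nonnative cover
    response: np.ndarray    # (n, 6) richness counts or percent covers

    def __post_init__(self) -> None:
        n = len(self.class_idx)
        for name in ("bio_idx", "month_idx", "year_idx", "plot_idx", "r", "e"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{name} length mismatch")
        if self.response.shape != (n, G):
            raise DataError("response must be (n, 6)")

    @property
    def n(self) -> int:
        return len(self.class_idx)

    def validate_against(self, spec: ModelSpec) -> None:
        checks = [
            ("class_idx", self.class_idx, spec.n_classes),
            ("bio_idx", self.bio_idx, spec.n_bioregions),
            ("month_idx", self.month_idx, 12),
            ("year_idx", self.year_idx, spec.n_years),
            ("plot_idx", self.plot_idx, spec.n_plots),
        ]
        for name, arr, dim in checks:
            arr = np.asarray(arr)
            if arr.min() < 0 or arr.max() >= dim:
                raise DataError(f"{name} outside model dimensions (0..{dim - 1})")
        if spec.response == "richness":
            if np.any(self.response < 0) or np.any(self.response != np.round(self.response)):
                raise DataError("richness responses must be non-negative integers")
        else:
            if np.any(self.response < 0):
                raise DataError("cover responses must be non-negative")


def linear_predictor(
    params: ParamSet,
    spec: ModelSpec,
    class_idx,
    bio_idx,
    month_idx,
    year_idx,
    plot_idx,
    r,
    e,
) -> np.ndarray:
    """Evaluate mu_i for one or many surveys; returns (n, 6).

    ``month_idx`` is 0-based (0 = January ... 11 = December).
    """
    ci = np.atleast_1d(np.asarray(class_idx, dtype=int))
    bi = np.atleast_1d(np.asarray(bio_idx, dtype=int))
    mi = np.atleast_1d(np.asarray(month_idx, dtype=int))
    yi = np.atleast_1d(np.asarray(year_idx, dtype=int))
    pi = np.atleast_1d(np.asarray(plot_idx, dtype=int))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    e = np.atleast_1d(np.asarray(e, dtype=float))
    for name, arr, dim in [
        ("class_idx", ci, spec.n_classes),
        ("bio_idx", bi, spec.n_bioregions),
        ("month_idx", mi, 12),
        ("year_idx", yi, spec.n_years),
        ("plot_idx", pi, spec.n_plots),
    ]:
        if arr.min() < 0 or arr.max() >= dim:
            raise DataError(f"{name} out of range for model dimensions")

    mu = (
        params.alpha[None, :]
        + params.beta[ci]
        + r[:, None] * params.delta[bi]
        + e[:, None] * params.eps[None, :]
        + params.zeta[yi]
        + params.eta[pi]
    )
    if spec.variant == "dynamic":
        mu = mu + params.gamma_mb[mi, bi]
    else:
        mu = mu + params.gamma_b[bi] + params.kappa[mi]
    return mu


def effect_multiplier(coefficient) -> tuple[np.ndarray, np.ndarray]:
    """Convert a log-scale slope to a multiplicative factor and percent change.

    A coefficient c means the response is multiplied by exp(c) per one standard
    deviation increase in the covariate; exp(c)=1.19 is a 19% increase and
    exp(c)=0.95 a 5% decrease.
    """
    factor = np.exp(np.asarray(coefficient, dtype=float))
    percent = (factor - 1.0) * 100.0
    return factor, percent
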