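"""Structured log-density evaluation built from scipy distributions.

This module evaluates each block of the joint density directly on the
constrained parameter values, term by term, using scipy's distribution
objects.  It is the readable reference route; the sampler uses its own
vectorized evaluation on the unconstrained scale (``posterior.py``), and the
two must agree up to the change-of-variables Jacobian.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..errors import DataError
from .spec import G, JUNE, WALK_ORDER, ModelSpec, ParamSet, SurveyData

COVER_OFFSET = 1e-3  # log(z + 0.001): Box-Cox with lambda1 = 0, lambda2 = 0.001


def observation_loglik(values, lam, sigma, kind: str) -> float:
    """Log likelihood of one survey's 6-vector response given rates lambda.

    richness: y ~ Poisson(lambda), summed over growth forms.
    cover:    log(z + 0.001) ~ Normal(log lambda, sigma), summed likewise.
    """
    values = np.asarray(values, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise DataError("lambda must be positive")
    if kind == "richness":
        if np.any(values < 0) or np.any(values != np.round(values)):
            raise DataError("richness must be non-negative integers")
        return float(stats.poisson.logpmf(values.astype(int), lam).sum())
    if kind == "cover":
        if np.any(values < 0):
            raise DataError("cover must be non-negative")
        sigma = np.asarray(sigma, dtype=float)
        t = np.log(values + COVER_OFFSET)
        return float(stats.norm.logpdf(t, np.log(lam), sigma).sum())
    raise DataError(f"unknown response kind {kind!r}")


def lkj_log_density(phi: np.ndarray, a: float) -> float:
    """Unnormalized LKJ log density: a * log det(Phi), p(Phi) propto |Phi|^a.

    Larger a concentrates mass on the identity matrix; a = 0 weights all
    correlation matrices equally.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise DataError("Phi must be square")
    if not np.allclose(phi, phi.T, atol=1e-10):
        raise DataError("Phi must be symmetric")
    if not np.allclose(np.diag(phi), 1.0, atol=1e-10):
        raise DataError("Phi must have unit diagonal")
    sign, logdet = np.linalg.slogdet(phi)
    if sign <= 0:
        raise DataError("Phi must be positive definite")
    try:
        np.linalg.cholesky(phi)
    except np.linalg.LinAlgError as exc:
        raise DataError("Phi must be positive definite") from exc
    return float(a * logdet)


def random_walk_logprior(gamma_12: np.ndarray, sigma_rw) -> float:
    """Seasonal first-order random-walk log prior for one bioregion.

    ``gamma_12`` is (12, 6), indexed by calendar month (row 0 = January).
    The walk starts in July with a zero-mean step, proceeds month-by-month
    August through May, and June is tied to the mean of May and July so the
    seasonal profile closes smoothly.
    """
    gamma_12 = np.asarray(gamma_12, dtype=float)
    if gamma_12.shape != (12, G):
        raise DataError("gamma must be (12, 6): one 6-vector per month")
    sigma_rw = np.broadcast_to(np.asarray(sigma_rw, dtype=float), (G,))
    jul = WALK_ORDER[0] - 1
    total = float(stats.norm.logpdf(gamma_12[jul], 0.0, sigma_rw).sum())
    for prev_m, m in zip(WALK_ORDER[:-1], WALK_ORDER[1:]):
        total += float(
            stats.norm.logpdf(gamma_12[m - 1], gamma_12[prev_m - 1], sigma_rw).sum()
        )
    may, june = WALK_ORDER[-1] - 1, JUNE - 1
    link_mean = 0.5 * (gamma_12[may] + gamma_12[jul])
    total += float(stats.norm.logpdf(gamma_12[june], link_mean, sigma_rw).sum())
    return total


def _vec_norm(x, mean, sd) -> float:
    return float(stats.norm.logpdf(np.asarray(x, dtype=float), mean, sd).sum())


def _halfnorm(x, sd) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    return float(stats.halfnorm.logpdf(x, scale=sd).sum())


def hierarchical_logprior(params: ParamSet, spec: ModelSpec) -> float:
    """Sum of every prior log density of the hierarchical model.

    Includes the vague Normal(0, 10) priors on alpha, iota and eps, the
    hierarchical normal priors on all deviations, HalfNormal(0, 2) priors on
    every scale vector, the LKJ term on the residual correlation, and (dynamic
    variant) the seasonal random-walk prior per bioregion.  Returns -inf when
    any scale parameter is non-positive.
    """
    sds = [params.sigma_v, params.sigma_f, params.sigma_r, params.sigma_y,
           params.sigma_p, params.sigma_s]
    if spec.variant == "dynamic":
        sds.append(params.sigma_rw)
    else:
        sds.extend([params.sigma_b, params.sigma_m])
    if spec.response == "cover":
        sds.append(params.sigma_obs)
    if any(np.any(np.asarray(s) <= 0) for s in sds):
        return -np.inf

    s = spec.scale_prior_sd
    total = 0.0
    total += _vec_norm(params.alpha, 0.0, spec.vague_sd)
    total += _vec_norm(params.iota, 0.0, spec.vague_sd)
    total += _vec_norm(params.eps, 0.0, spec.vague_sd)
    total += _vec_norm(params.theta, 0.0, params.sigma_f)
    total += _vec_norm(params.beta, params.theta[spec.class_formation], params.sigma_v)
    total += _vec_norm(params.delta, params.iota, params.sigma_r)
    total += _vec_norm(params.zeta, 0.0, params.sigma_y)
    total += _vec_norm(params.eta, 0.0, params.sigma_p)
    total += _halfnorm(params.sigma_v, s) + _halfnorm(params.sigma_f, s)
    total += _halfnorm(params.sigma_r, s) + _halfnorm(params.sigma_y, s)
    total += _halfnorm(params.sigma_p, s) + _halfnorm(params.sigma_s, s)
    if spec.variant == "dynamic":
        for b in range(spec.n_bioregions):
            total += random_walk_logprior(params.gamma_mb[:, b, :], params.sigma_rw[b])
        total += _halfnorm(params.sigma_rw, s)
    else:
        total += _vec_norm(params.gamma_b, 0.0, params.sigma_b)
        total += _vec_norm(params.kappa, 0.0, params.sigma_m)
        total += _halfnorm(params.sigma_b, s) + _halfnorm(params.sigma_m, s)
    if spec.response == "cover":
        total += _halfnorm(params.sigma_obs, s)
    total += lkj_log_density(params.phi, spec.lkj_shape)
    return total


def overdispersion_logpdf(loglam: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    """Sum of MVN(mu_i, Sigma) log densities of the latent log rates."""
    total = 0.0
    for i in range(loglam.shape[0]):
        total += float(stats.multivariate_normal.logpdf(loglam[i], mu[i], Sigma))
    return total


def joint_log_density(
    params: ParamSet, loglam: np.ndarray, data: SurveyData, spec: ModelSpec
) -> float:
    """Full joint density on the constrained scale (likelihood + latent + priors)."""
    from .spec import linear_predictor

    mu = linear_predictor(
        params, spec, data.class_idx, data.bio_idx, data.month_idx,
        data.year_idx, data.plot_idx, data.r, data.e,
    )
    lam = np.exp(loglam)
    total = 0.0
    for i in range(data.n):
        total += observation_loglik(
            data.response[i], lam[i],
            params.sigma_obs if spec.response == "cover" else None,
            spec.response,
        )
    total += overdispersion_logpdf(loglam, mu, params.Sigma)
    total += hierarchical_logprior(params, spec)
    return total
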