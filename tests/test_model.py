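"""Linear predictor, observation likelihoods, and prior densities."""

import math

import numpy as np
import pytest
from scipy import stats

from vegbench.errors import DataError
from vegbench.model.densities import (
    hierarchical_logprior,
    lkj_log_density,
    observation_loglik,
    random_walk_logprior,
)
from vegbench.model.spec import (
    G,
    JUNE,
    WALK_ORDER,
    ModelSpec,
    ParamSet,
    effect_multiplier,
    linear_predictor,
)
from vegbench.simulate import SimulationScenario, draw_true_params


def _small_spec(variant="static", response="richness"):
    return ModelSpec(
        response=response, variant=variant, n_classes=2, n_formations=1,
        n_bioregions=2, n_years=2, n_plots=3, class_formation=np.zeros(2, dtype=int),
    )


def _zero_params(spec):
    z = lambda *shape: np.zeros(shape)
    ones = lambda *shape: np.ones(shape)
    kw = {}
    if spec.variant == "dynamic":
        kw = {"gamma_mb": z(12, spec.n_bioregions, G),
              "sigma_rw": ones(spec.n_bioregions, G)}
    else:
        kw = {"gamma_b": z(spec.n_bioregions, G), "kappa": z(12, G),
              "sigma_b": ones(G), "sigma_m": ones(G)}
    if spec.response == "cover":
        kw["sigma_obs"] = ones(G)
    return ParamSet(
        alpha=z(G), beta=z(spec.n_classes, G), theta=z(spec.n_formations, G),
        delta=z(spec.n_bioregions, G), iota=z(G), eps=z(G),
        zeta=z(spec.n_years, G), eta=z(spec.n_plots, G),
        sigma_v=ones(G), sigma_f=ones(G), sigma_r=ones(G), sigma_y=ones(G),
        sigma_p=ones(G), sigma_s=ones(G), phi=np.eye(G), **kw,
    )


class TestLinearPredictor:
    def test_null_case_returns_alpha(self):
        spec = _small_spec()
        ps = _zero_params(spec)
        ps.alpha = np.log(np.arange(1, 7, dtype=float))
        mu = linear_predictor(ps, spec, 0, 0, 0, 0, 0, 0.0, 0.0)
        assert np.allclose(mu[0], ps.alpha)

    def test_matches_hand_arithmetic(self):
        spec = _small_spec()
        ps = _zero_params(spec)
        rng = np.random.default_rng(1)
        for name in ("alpha", "beta", "gamma_b", "kappa", "delta", "iota",
                     "eps", "zeta", "eta"):
            setattr(ps, name, rng.normal(0, 0.5, getattr(ps, name).shape))
        r, e = 0.7, -1.2
        ci, bi, mi, yi, pi = 1, 0, 4, 1, 2
        mu = linear_predictor(ps, spec, ci, bi, mi, yi, pi, r, e)[0]
        expected = (ps.alpha + ps.beta[ci] + ps.gamma_b[bi] + ps.kappa[mi]
                    + r * ps.delta[bi] + e * ps.eps + ps.zeta[yi] + ps.eta[pi])
        assert np.allclose(mu, expected)

    def test_static_nested_in_dynamic(self):
        """With gamma_mb decomposed as gamma_b + kappa_m the two variants agree."""
        sspec = _small_spec("static")
        dspec = _small_spec("dynamic")
        ps = _zero_params(sspec)
        rng = np.random.default_rng(2)
        for name in ("alpha", "beta", "delta", "iota", "eps", "zeta", "eta",
                     "gamma_b", "kappa"):
            setattr(ps, name, rng.normal(0, 0.5, getattr(ps, name).shape))
        pd_ = _zero_params(dspec)
        for name in ("alpha", "beta", "delta", "iota", "eps", "zeta", "eta"):
            setattr(pd_, name, getattr(ps, name))
        pd_.gamma_mb = ps.gamma_b[None, :, :] + ps.kappa[:, None, :]
        n = 10
        ci = rng.integers(0, 2, n)
        bi = rng.integers(0, 2, n)
        mi = rng.integers(0, 12, n)
        yi = rng.integers(0, 2, n)
        pi = rng.integers(0, 3, n)
        r = rng.normal(size=n)
        e = rng.normal(size=n)
        mu_s = linear_predictor(ps, sspec, ci, bi, mi, yi, pi, r, e)
        mu_d = linear_predictor(pd_, dspec, ci, bi, mi, yi, pi, r, e)
        assert np.allclose(mu_s, mu_d)

    def test_index_out_of_range_rejected(self):
        spec = _small_spec()
        ps = _zero_params(spec)
        with pytest.raises(DataError):
            linear_predictor(ps, spec, 5, 0, 0, 0, 0, 0.0, 0.0)


class TestEffectMultiplier:
    def test_zero_coefficient_is_no_change(self):
        factor, percent = effect_multiplier(0.0)
        assert factor == 1.0 and percent == 0.0

    def test_factor_above_one_is_percent_increase(self):
        factor, percent = effect_multiplier(np.log(1.19))
        assert factor == pytest.approx(1.19)
        assert percent == pytest.approx(19.0)

    def test_factor_below_one_is_percent_decrease(self):
        factor, percent = effect_multiplier(np.log(0.95))
        assert factor == pytest.approx(0.95)
        assert percent == pytest.approx(-5.0)


class TestObservationLoglik:
    def test_poisson_unit_rate_at_zero(self):
        ll = observation_loglik(np.zeros(6), np.ones(6), None, "richness")
        assert ll == pytest.approx(-6.0)

    def test_zero_cover_is_finite_via_offset(self):
        z = np.array([0.0, 1.0, 0.0, 2.0, 0.0, 0.0])
        ll = observation_loglik(z, np.ones(6), np.ones(6), "cover")
        assert np.isfinite(ll)

    def test_matches_textbook_densities(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 12, 6).astype(float)
        lam = rng.uniform(0.5, 8.0, 6)
        # independent Poisson pmf written out
        expected = sum(
            yi * math.log(li) - li - math.log(math.factorial(int(yi)))
            for yi, li in zip(y, lam)
        )
        assert observation_loglik(y, lam, None, "richness") == pytest.approx(expected)
        z = rng.uniform(0.0, 80.0, 6)
        sig = rng.uniform(0.3, 1.5, 6)
        expected_c = sum(
            -0.5 * math.log(2 * math.pi) - math.log(s)
            - (math.log(zi + 1e-3) - math.log(li)) ** 2 / (2 * s**2)
            for zi, li, s in zip(z, lam, sig)
        )
        assert observation_loglik(z, lam, sig, "cover") == pytest.approx(expected_c)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DataError):
            observation_loglik(np.full(6, 1.5), np.ones(6), None, "richness")
        with pytest.raises(DataError):
            observation_loglik(np.full(6, -1.0), np.ones(6), np.ones(6), "cover")


class TestLkjDensity:
    def test_identity_has_zero_log_density(self):
        assert lkj_log_density(np.eye(6), 4.0) == 0.0

    def test_2x2_closed_form(self):
        for r in (-0.6, 0.0, 0.3, 0.9):
            phi = np.array([[1.0, r], [r, 1.0]])
            assert lkj_log_density(phi, 4.0) == pytest.approx(4.0 * np.log(1 - r**2))

    def test_zero_shape_weights_all_matrices_equally(self):
        rng = np.random.default_rng(0)
        from vegbench.simulate import sample_lkj
        vals = {lkj_log_density(sample_lkj(4, 2.0, rng), 0.0) for _ in range(5)}
        assert vals == {0.0}

    def test_invalid_matrices_rejected(self):
        with pytest.raises(DataError):
            lkj_log_density(np.array([[1.0, 2.0], [2.0, 1.0]]), 4.0)  # not PD
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(DataError):
            lkj_log_density(bad, 4.0)  # not symmetric


class TestRandomWalkPrior:
    def test_flat_path(self):
        sigma = 0.4
        lp = random_walk_logprior(np.zeros((12, G)), np.full(G, sigma))
        assert lp == pytest.approx(12 * G * stats.norm.logpdf(0.0, 0.0, sigma))

    def test_june_linkage_maximal_at_midpoint(self):
        rng = np.random.default_rng(4)
        gamma = rng.normal(0, 0.3, (12, G))
        may, jul, june = 4, 6, 5
        mid = 0.5 * (gamma[may] + gamma[jul])

        def lp_with_june(value):
            g = gamma.copy()
            g[june] = value
            return random_walk_logprior(g, np.full(G, 0.5))

        best = lp_with_june(mid)
        for shift in (-0.3, 0.2, 0.7):
            assert lp_with_june(mid + shift) < best

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(11)
        gamma = rng.normal(0, 0.5, (12, G))
        sigma = rng.uniform(0.2, 1.0, G)
        # literal month-by-month chain: Jul start, Aug..May walk, June linked
        expected = stats.norm.logpdf(gamma[6], 0, sigma).sum()
        chain = [7, 8, 9, 10, 11, 12, 1, 2, 3, 4, 5]
        for prev, cur in zip(chain[:-1], chain[1:]):
            expected += stats.norm.logpdf(gamma[cur - 1], gamma[prev - 1], sigma).sum()
        expected += stats.norm.logpdf(
            gamma[5], 0.5 * (gamma[4] + gamma[6]), sigma
        ).sum()
        assert random_walk_logprior(gamma, sigma) == pytest.approx(expected)

    def test_walk_order_constant(self):
        assert WALK_ORDER[0] == 7 and WALK_ORDER[-1] == 5 and JUNE == 6
        assert sorted((*WALK_ORDER, JUNE)) == list(range(1, 13))

    def test_wrong_shape_rejected(self):
        with pytest.raises(DataError):
            random_walk_logprior(np.zeros((11, G)), np.ones(G))


class TestHierarchicalLogprior:
    def test_nonpositive_scale_rejected(self):
        sc = SimulationScenario(n_classes=3, n_formations=2, n_bioregions=2,
                                n_years=2, n_plots=4, n_surveys=10)
        spec = sc.build_spec("richness")
        ps = draw_true_params(sc, 0, "richness")
        assert np.isfinite(hierarchical_logprior(ps, spec))
        ps.sigma_v = ps.sigma_v.copy()
        ps.sigma_v[2] = -0.1
        assert hierarchical_logprior(ps, spec) == -np.inf

    @pytest.mark.parametrize("variant", ["static", "dynamic"])
    def test_additivity_of_single_term(self, variant):
        """Perturbing one class deviation changes the prior by exactly that term."""
        sc = SimulationScenario(n_classes=3, n_formations=2, n_bioregions=2,
                                n_years=2, n_plots=4, n_surveys=10, variant=variant)
        spec = sc.build_spec("richness")
        ps = draw_true_params(sc, 5, "richness")
        base = hierarchical_logprior(ps, spec)
        v, g = 1, 3
        old = ps.beta[v, g]
        new = old + 0.37
        mean = ps.theta[spec.class_formation[v], g]
        expected_delta = (
            stats.norm.logpdf(new, mean, ps.sigma_v[g])
            - stats.norm.logpdf(old, mean, ps.sigma_v[g])
        )
        ps.beta = ps.beta.copy()
        ps.beta[v, g] = new
        assert hierarchical_logprior(ps, spec) - base == pytest.approx(expected_delta)
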