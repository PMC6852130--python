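"""Unconstrained log posterior with analytic gradients.

The sampler works on a flat unconstrained vector q.  Hierarchical deviations
use the non-centered parameterization (z ~ N(0,1), deviation = scale * z), all
scale parameters are log-transformed, the residual correlation matrix is
parameterized through the tanh/Cholesky transform used for correlation
matrices in gradient-based samplers, and the survey-level multivariate-normal
overdispersion is non-centered through the Cholesky factor of Sigma:

    log lambda_i = mu_i + diag(sigma_s) L_Phi u_i,   u_i ~ N(0, I).

The layout groups all standard-normal coordinates (the z blocks and u) into
one contiguous region and all log-scales into another, so their prior terms
are single vectorized operations.  Gradients of every block are derived by
hand (reverse accumulation); they are validated against finite differences
and the structured scipy evaluation in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

from .densities import COVER_OFFSET
from .spec import G, JUNE, WALK_ORDER, ModelSpec, ParamSet, SurveyData

LOG2PI = float(np.log(2.0 * np.pi))
_N_CORR = G * (G - 1) // 2
_TINY = 1e-12
_LOGLAM_BOUND = 60.0  # reject states with |log lambda| beyond this as divergent


def _chol_corr_forward(y: np.ndarray):
    """Map unconstrained y (15,) to a Cholesky factor L of a correlation matrix.

    Returns (L, log|J|, cache); log|J| is the log Jacobian determinant of the
    transform, cache holds per-row intermediates for the reverse pass.
    Pure-python scalar arithmetic: the arrays are tiny and loop-bound.
    """
    yl = y.tolist()
    L = np.zeros((G, G))
    L[0, 0] = 1.0
    logJ = 0.0
    cache = []
    k = 0
    for i in range(1, G):
        zi = [math.tanh(v) for v in yl[k : k + i]]
        k += i
        w = [0.0] * (i + 1)
        c = [0.0] * i
        s = 0.0
        for j in range(i):
            cj = math.sqrt(max(1.0 - s, _TINY))
            c[j] = cj
            w[j] = zi[j] * cj
            s += w[j] * w[j]
            logJ += math.log1p(-zi[j] * zi[j]) + math.log(cj)
        w[i] = math.sqrt(max(1.0 - s, _TINY))
        L[i, : i + 1] = w
        cache.append((zi, w, c))
    return L, logJ, cache


def _chol_corr_backward(dL: np.ndarray, dlogJ: float, cache) -> np.ndarray:
    """Reverse pass of the correlation transform: adjoints of (L, log|J|) -> dy."""
    dy = np.empty(_N_CORR)
    k = 0
    for i in range(1, G):
        zi, w, c = cache[i - 1]
        dwi = dL[i, : i + 1].tolist()
        ds = dwi[i] * (-0.5 / w[i])  # adjoint of s_i through the diagonal entry
        for j in range(i - 1, -1, -1):
            dw_j = dwi[j] + ds * 2.0 * w[j]
            dc_j = dw_j * zi[j] + dlogJ / c[j]
            dz_j = dw_j * c[j] + dlogJ * (-2.0 * zi[j] / (1.0 - zi[j] * zi[j]))
            ds = ds + dc_j * (-0.5 / c[j])
            dy[k + j] = dz_j * (1.0 - zi[j] * zi[j])
        k += i
    return dy


class _SegmentSum:
    """Group-wise column sums: (n, G) rows scattered to (dim, G) by an index.

    Equivalent to ``indicator_matrix @ x`` but implemented with a stable sort
    and ``np.add.reduceat``, which avoids per-call sparse-matrix dispatch
    overhead on the small problems this sampler targets.
    """

    def __init__(self, idx: np.ndarray, dim: int):
        idx = np.asarray(idx, dtype=int)
        self.order = np.argsort(idx, kind="stable")
        counts = np.bincount(idx, minlength=dim)
        self.starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        self.empty = counts == 0
        self._pad = self.empty.any()

    def __matmul__(self, x: np.ndarray) -> np.ndarray:
        xs = x[self.order]
        if self._pad:
            # a zero sentinel row keeps start == n valid for trailing empty
            # groups; reduceat still yields xs[start] (not 0) for every empty
            # segment, so those rows are zeroed afterwards
            xs = np.vstack([xs, np.zeros((1, x.shape[1]))])
        out = np.add.reduceat(xs, self.starts, axis=0)
        if self._pad:
            out[self.empty] = 0.0
        return out


def _indicator(idx: np.ndarray, dim: int) -> _SegmentSum:
    return _SegmentSum(idx, dim)


class UnconstrainedPosterior:
    """Log posterior density and gradient on the unconstrained scale."""

    def __init__(self, spec: ModelSpec, data: SurveyData):
        data.validate_against(spec)
        self.spec = spec
        self.data = data
        n = data.n
        self.ci = np.asarray(data.class_idx, dtype=int)
        self.bi = np.asarray(data.bio_idx, dtype=int)
        self.mi = np.asarray(data.month_idx, dtype=int)
        self.yi = np.asarray(data.year_idx, dtype=int)
        self.pi = np.asarray(data.plot_idx, dtype=int)
        self.r = np.asarray(data.r, dtype=float)
        self.e = np.asarray(data.e, dtype=float)
        if spec.response == "richness":
            self.Y = np.asarray(data.response, dtype=float)
            self._lik_const = float(-gammaln(self.Y + 1).sum())
        else:
            self.t = np.log(np.asarray(data.response, dtype=float) + COVER_OFFSET)

        # scatter operators (parameter dim x n)
        self.Pc = _indicator(self.ci, spec.n_classes)
        self.Pcf = _indicator(spec.class_formation, spec.n_formations)
        self.Pb = _indicator(self.bi, spec.n_bioregions)
        self.Py = _indicator(self.yi, spec.n_years)
        self.Pp = _indicator(self.pi, spec.n_plots)
        if spec.variant == "dynamic":
            self.Pmb = _indicator(self.mi * spec.n_bioregions + self.bi,
                                  12 * spec.n_bioregions)
        else:
            self.Pm = _indicator(self.mi, 12)

        # unconstrained layout: vague | standard-normal | log-scales | corr
        self.slices: dict[str, slice] = {}
        pos = 0

        def block(name: str, size: int) -> None:
            nonlocal pos
            self.slices[name] = slice(pos, pos + size)
            pos += size

        nv, nf, nb = spec.n_classes, spec.n_formations, spec.n_bioregions
        ny, npl = spec.n_years, spec.n_plots
        block("alpha", G)
        block("iota", G)
        block("eps", G)
        self.vague_region = slice(0, pos)
        z_start = pos
        block("z_theta", nf * G)
        block("z_beta", nv * G)
        if spec.variant == "dynamic":
            block("z_gamma", 12 * nb * G)
        else:
            block("z_gamma", nb * G)
            block("z_kappa", 12 * G)
        block("z_delta", nb * G)
        block("z_zeta", ny * G)
        block("z_eta", npl * G)
        block("u", n * G)
        self.z_region = slice(z_start, pos)
        ls_start = pos
        block("ls_v", G)
        block("ls_f", G)
        if spec.variant == "dynamic":
            block("ls_rw", nb * G)
        else:
            block("ls_b", G)
            block("ls_m", G)
        block("ls_r", G)
        block("ls_y", G)
        block("ls_p", G)
        block("ls_s", G)
        if spec.response == "cover":
            block("ls_o", G)
        self.ls_region = slice(ls_start, pos)
        block("corr", _N_CORR)
        self.n_params = pos
        self._ls_names = [k for k in self.slices if k.startswith("ls_")]

    # ------------------------------------------------------------------ #

    def _get(self, q: np.ndarray, name: str, shape=None) -> np.ndarray:
        v = q[self.slices[name]]
        return v if shape is None else v.reshape(shape)

    def _gamma_forward(self, sigma_rw: np.ndarray, zg: np.ndarray) -> np.ndarray:
        """Build the seasonal random walk gamma (12, nb, G) from innovations."""
        gamma = np.empty_like(zg)
        jul = WALK_ORDER[0] - 1
        gamma[jul] = sigma_rw * zg[jul]
        for prev_m, m in zip(WALK_ORDER[:-1], WALK_ORDER[1:]):
            gamma[m - 1] = gamma[prev_m - 1] + sigma_rw * zg[m - 1]
        may, june = WALK_ORDER[-1] - 1, JUNE - 1
        gamma[june] = 0.5 * (gamma[may] + gamma[jul]) + sigma_rw * zg[june]
        return gamma

    def _forward(self, q: np.ndarray) -> dict:
        spec = self.spec
        nv, nf, nb = spec.n_classes, spec.n_formations, spec.n_bioregions
        ny, npl, n = spec.n_years, spec.n_plots, self.data.n
        f: dict = {}
        f["alpha"] = self._get(q, "alpha")
        f["iota"] = self._get(q, "iota")
        f["eps"] = self._get(q, "eps")
        f["z_theta"] = self._get(q, "z_theta", (nf, G))
        f["z_beta"] = self._get(q, "z_beta", (nv, G))
        f["z_delta"] = self._get(q, "z_delta", (nb, G))
        f["z_zeta"] = self._get(q, "z_zeta", (ny, G))
        f["z_eta"] = self._get(q, "z_eta", (npl, G))
        for name in self._ls_names:
            f[name] = self._get(q, name)
            f[name.replace("ls_", "sigma_")] = np.exp(f[name])
        f["theta"] = f["sigma_f"] * f["z_theta"]
        f["beta"] = f["theta"][spec.class_formation] + f["sigma_v"] * f["z_beta"]
        f["delta"] = f["iota"] + f["sigma_r"] * f["z_delta"]
        f["zeta"] = f["sigma_y"] * f["z_zeta"]
        f["eta"] = f["sigma_p"] * f["z_eta"]
        if spec.variant == "dynamic":
            f["z_gamma"] = self._get(q, "z_gamma", (12, nb, G))
            f["sigma_rw"] = f["sigma_rw"].reshape(nb, G)
            f["gamma_mb"] = self._gamma_forward(f["sigma_rw"], f["z_gamma"])
        else:
            f["z_gamma"] = self._get(q, "z_gamma", (nb, G))
            f["z_kappa"] = self._get(q, "z_kappa", (12, G))
            f["gamma_b"] = f["sigma_b"] * f["z_gamma"]
            f["kappa"] = f["sigma_m"] * f["z_kappa"]
        L, logJ_corr, cache = _chol_corr_forward(self._get(q, "corr"))
        f["L"], f["logJ_corr"], f["corr_cache"] = L, logJ_corr, cache
        f["Ls"] = f["sigma_s"][:, None] * L
        f["u"] = self._get(q, "u", (n, G))

        mu = (
            f["alpha"][None, :]
            + f["beta"][self.ci]
            + self.r[:, None] * f["delta"][self.bi]
            + self.e[:, None] * f["eps"][None, :]
            + f["zeta"][self.yi]
            + f["eta"][self.pi]
        )
        if spec.variant == "dynamic":
            mu = mu + f["gamma_mb"][self.mi, self.bi]
        else:
            mu = mu + f["gamma_b"][self.bi] + f["kappa"][self.mi]
        f["mu"] = mu
        f["loglam"] = mu + f["u"] @ f["Ls"].T
        return f

    def unpack(self, q: np.ndarray) -> tuple[ParamSet, np.ndarray]:
        """Constrained parameter values and latent log rates at q."""
        f = self._forward(q)
        phi = f["L"] @ f["L"].T
        ps = ParamSet(
            alpha=f["alpha"].copy(),
            beta=f["beta"].copy(),
            theta=f["theta"].copy(),
            delta=f["delta"].copy(),
            iota=f["iota"].copy(),
            eps=f["eps"].copy(),
            zeta=f["zeta"].copy(),
            eta=f["eta"].copy(),
            sigma_v=f["sigma_v"].copy(),
            sigma_f=f["sigma_f"].copy(),
            sigma_r=f["sigma_r"].copy(),
            sigma_y=f["sigma_y"].copy(),
            sigma_p=f["sigma_p"].copy(),
            sigma_s=f["sigma_s"].copy(),
            phi=phi,
            gamma_mb=f.get("gamma_mb"),
            sigma_rw=f.get("sigma_rw"),
            gamma_b=f.get("gamma_b"),
            kappa=f.get("kappa"),
            sigma_b=f.get("sigma_b"),
            sigma_m=f.get("sigma_m"),
            sigma_obs=f.get("sigma_o"),
        )
        return ps, f["loglam"]

    # ------------------------------------------------------------------ #

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        spec = self.spec
        s2 = spec.scale_prior_sd**2
        vague2 = spec.vague_sd**2
        nb, n = spec.n_bioregions, self.data.n
        f = self._forward(q)
        grad = np.zeros_like(q)

        loglam = f["loglam"]
        if not np.all(np.abs(loglam) < _LOGLAM_BOUND):
            # far outside any plausible rate scale; reject as divergent
            return -np.inf, grad

        # ---- fused prior mass over the three regions ----
        zq = q[self.z_region]
        lsq = q[self.ls_region]
        vq = q[self.vague_region]
        n_z = zq.size
        n_v = vq.size
        logp = (
            -0.5 * float(zq @ zq) - 0.5 * LOG2PI * n_z
            - 0.5 * float(vq @ vq) / vague2
            - n_v * (0.5 * LOG2PI + math.log(spec.vague_sd))
        )
        grad[self.z_region] = -zq
        grad[self.vague_region] = -vq / vague2
        # half-normal priors on all scales + exp-transform Jacobian
        sig_all = np.exp(lsq)
        logp += float(
            lsq.sum() - 0.5 * (sig_all @ sig_all) / s2
            + lsq.size * (0.5 * math.log(2.0 / math.pi) - math.log(spec.scale_prior_sd))
        )
        grad[self.ls_region] = 1.0 - sig_all**2 / s2

        # ---- likelihood ----
        if spec.response == "richness":
            lam = np.exp(loglam)
            logp += float((self.Y * loglam - lam).sum()) + self._lik_const
            g = self.Y - lam  # d loglik / d loglam
        else:
            sigma_o = f["sigma_o"]
            resid = self.t - loglam
            rs = resid / sigma_o
            logp += float(
                -0.5 * (rs * rs).sum()
                - n * (f["ls_o"].sum() + 0.5 * LOG2PI * G)
            )
            g = resid / sigma_o**2
            grad[self.slices["ls_o"]] += (rs * rs).sum(axis=0) - n

        # ---- overdispersion: loglam = mu + u Ls^T ----
        u, Ls, L = f["u"], f["Ls"], f["L"]
        grad[self.slices["u"]] += (g @ Ls).ravel()
        dLs = np.tril(g.T @ u)
        dL = f["sigma_s"][:, None] * dLs
        grad[self.slices["ls_s"]] += (dLs * L).sum(axis=1) * f["sigma_s"]

        # ---- LKJ prior and correlation transform ----
        diagL = np.diag(L)
        logp += float(2.0 * spec.lkj_shape * np.log(diagL).sum()) + f["logJ_corr"]
        dL[np.diag_indices(G)] += 2.0 * spec.lkj_shape / diagL
        grad[self.slices["corr"]] = _chol_corr_backward(dL, 1.0, f["corr_cache"])

        # ---- linear predictor backward ----
        dmu = g
        grad[self.slices["alpha"]] += dmu.sum(axis=0)

        def _noncentered(zname, lsname, z, sigma, d_dev):
            """Backprop dev = sigma * z; adds to the z and log-scale gradients."""
            grad[self.slices[zname]] += (sigma * d_dev).ravel()
            grad[self.slices[lsname]] += ((z * d_dev).sum(axis=0) * sigma).ravel()

        dbeta = self.Pc @ dmu  # (nv, G)
        _noncentered("z_beta", "ls_v", f["z_beta"], f["sigma_v"], dbeta)
        dtheta = self.Pcf @ dbeta
        _noncentered("z_theta", "ls_f", f["z_theta"], f["sigma_f"], dtheta)

        if spec.variant == "dynamic":
            dgamma = (self.Pmb @ dmu).reshape(12, nb, G)
            zg, sig_rw = f["z_gamma"], f["sigma_rw"]
            adj = dgamma.copy()
            dzg = np.empty_like(zg)
            dsig_rw = np.zeros((nb, G))
            jul, may, june = WALK_ORDER[0] - 1, WALK_ORDER[-1] - 1, JUNE - 1
            dzg[june] = sig_rw * adj[june]
            dsig_rw += zg[june] * adj[june]
            adj[may] += 0.5 * adj[june]
            adj[jul] += 0.5 * adj[june]
            for prev_m, m in zip(WALK_ORDER[-2::-1], WALK_ORDER[:0:-1]):
                dzg[m - 1] = sig_rw * adj[m - 1]
                dsig_rw += zg[m - 1] * adj[m - 1]
                adj[prev_m - 1] += adj[m - 1]
            dzg[jul] = sig_rw * adj[jul]
            dsig_rw += zg[jul] * adj[jul]
            grad[self.slices["z_gamma"]] += dzg.ravel()
            grad[self.slices["ls_rw"]] += (dsig_rw * sig_rw).ravel()
        else:
            dgb = self.Pb @ dmu
            _noncentered("z_gamma", "ls_b", f["z_gamma"], f["sigma_b"], dgb)
            dkap = self.Pm @ dmu
            _noncentered("z_kappa", "ls_m", f["z_kappa"], f["sigma_m"], dkap)

        ddelta = self.Pb @ (self.r[:, None] * dmu)
        _noncentered("z_delta", "ls_r", f["z_delta"], f["sigma_r"], ddelta)
        grad[self.slices["iota"]] += ddelta.sum(axis=0)
        grad[self.slices["eps"]] += (self.e[:, None] * dmu).sum(axis=0)

        dzeta = self.Py @ dmu
        _noncentered("z_zeta", "ls_y", f["z_zeta"], f["sigma_y"], dzeta)
        deta = self.Pp @ dmu
        _noncentered("z_eta", "ls_p", f["z_eta"], f["sigma_p"], deta)

        return logp, grad

    def logp(self, q: np.ndarray) -> float:
        return self.logp_grad(q)[0]

    # ------------------------------------------------------------------ #

    def log_jacobian(self, q: np.ndarray) -> float:
        """Change-of-variables terms linking this density to the structured one.

        logp(q) = joint_log_density(*unpack(q)) + log_jacobian(q), where the
        structured density is evaluated on the constrained scale by
        ``densities.joint_log_density``.
        """
        spec = self.spec
        f = self._forward(q)
        n = self.data.n
        total = float(q[self.ls_region].sum())  # exp transforms
        total += f["logJ_corr"]
        # overdispersion non-centering: |det diag(sigma_s) L| per survey
        total += n * float(np.log(f["sigma_s"]).sum() + np.log(np.diag(f["L"])).sum())
        # hierarchical non-centering
        total += spec.n_classes * float(np.log(f["sigma_v"]).sum())
        total += spec.n_formations * float(np.log(f["sigma_f"]).sum())
        total += spec.n_bioregions * float(np.log(f["sigma_r"]).sum())
        total += spec.n_years * float(np.log(f["sigma_y"]).sum())
        total += spec.n_plots * float(np.log(f["sigma_p"]).sum())
        if spec.variant == "dynamic":
            total += 12 * float(np.log(f["sigma_rw"]).sum())
        else:
            total += spec.n_bioregions * float(np.log(f["sigma_b"]).sum())
            total += 12 * float(np.log(f["sigma_m"]).sum())
        return total

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.5) -> np.ndarray:
        """Random initial point: data-informed intercepts, jittered elsewhere."""
        q = rng.uniform(-jitter, jitter, self.n_params)
        # start scales moderate and intercepts near the data mean
        q[self.ls_region] = np.log(0.5) + 0.1 * rng.standard_normal(
            self.ls_region.stop - self.ls_region.start
        )
        if self.spec.response == "richness":
            alpha0 = np.log(self.Y.mean(axis=0) + 0.1)
        else:
            alpha0 = self.t.mean(axis=0)
        q[self.slices["alpha"]] = alpha0 + 0.1 * rng.standard_normal(G)
        q[self.slices["u"]] *= 0.2
        return q
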