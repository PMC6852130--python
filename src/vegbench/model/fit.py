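"""Model fitting: run NUTS chains and package labelled posterior draws."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import xarray as xr

from ..errors import ConfigurationError
from ..floristic import GROWTH_FORMS, CovariateScaling
from .nuts import sample_nuts
from .posterior import UnconstrainedPosterior
from .spec import G, ModelSpec, SurveyData


@dataclass
class PosteriorDraws:
    """Labelled MCMC draws plus everything needed to predict from them."""

    idata: az.InferenceData
    spec: ModelSpec
    scaling: CovariateScaling | None = None
    coords: dict = field(default_factory=dict)  # label lists per dimension
    metadata: dict = field(default_factory=dict)

    @property
    def posterior(self) -> xr.Dataset:
        return self.idata.posterior

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one variable with chain/draw flattened into one axis."""
        da = self.posterior[name]
        return da.stack(sample=("chain", "draw")).transpose("sample", ...).to_numpy()

    @property
    def n_samples(self) -> int:
        p = self.posterior
        return p.sizes["chain"] * p.sizes["draw"]

    def save(self, path) -> None:
        """Persist draws (zarr) with the model spec and scaling embedded."""
        path = Path(path)
        ds = self.posterior.copy()
        ds.attrs["vegbench_meta"] = json.dumps(
            {
                "spec": {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in vars(self.spec).items()
                },
                "scaling": self.scaling.to_dict() if self.scaling else None,
                "coords": self.coords,
                "metadata": self.metadata,
            }
        )
        ds.to_zarr(path, mode="w")

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        ds = xr.open_zarr(path).load()
        meta = json.loads(ds.attrs.pop("vegbench_meta"))
        spec_kw = meta["spec"]
        spec_kw["class_formation"] = np.asarray(spec_kw["class_formation"], dtype=int)
        spec = ModelSpec(**spec_kw)
        scaling = (
            CovariateScaling.from_dict(meta["scaling"]) if meta["scaling"] else None
        )
        idata = az.InferenceData(posterior=ds)
        return cls(idata, spec, scaling, meta["coords"], meta["metadata"])


def _default_coords(spec: ModelSpec) -> dict:
    return {
        "growth_form": list(GROWTH_FORMS),
        "growth_form2": list(GROWTH_FORMS),
        "veg_class": [f"class_{i}" for i in range(spec.n_classes)],
        "formation": [f"formation_{i}" for i in range(spec.n_formations)],
        "bioregion": [f"bioregion_{i}" for i in range(spec.n_bioregions)],
        "month": list(range(1, 13)),
        "year": list(range(spec.n_years)),
        "plot": [f"plot_{i}" for i in range(spec.n_plots)],
    }


_VAR_DIMS = {
    "alpha": ("growth_form",),
    "beta": ("veg_class", "growth_form"),
    "theta": ("formation", "growth_form"),
    "delta": ("bioregion", "growth_form"),
    "iota": ("growth_form",),
    "eps": ("growth_form",),
    "zeta": ("year", "growth_form"),
    "eta": ("plot", "growth_form"),
    "sigma_v": ("growth_form",),
    "sigma_f": ("growth_form",),
    "sigma_r": ("growth_form",),
    "sigma_y": ("growth_form",),
    "sigma_p": ("growth_form",),
    "sigma_s": ("growth_form",),
    "phi": ("growth_form", "growth_form2"),
    "gamma_mb": ("month", "bioregion", "growth_form"),
    "sigma_rw": ("bioregion", "growth_form"),
    "gamma_b": ("bioregion", "growth_form"),
    "kappa": ("month", "growth_form"),
    "sigma_b": ("growth_form",),
    "sigma_m": ("growth_form",),
    "sigma_obs": ("growth_form",),
}


def fit(
    spec: ModelSpec,
    data: SurveyData,
    *,
    chains: int = 4,
    warmup: int = 1000,
    iterations: int = 1000,
    seed: int = 0,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    scaling: CovariateScaling | None = None,
    coords: dict | None = None,
    divergence_warn_frac: float = 0.05,
) -> PosteriorDraws:
    """Sample the posterior of one response/variant with NUTS.

    Runs ``chains`` independent chains (sequentially), each with ``warmup``
    adaptation iterations discarded and ``iterations`` retained draws.  Chains
    are seeded deterministically from ``seed``, so a repeated call reproduces
    the draws exactly.
    """
    if chains < 1:
        raise ConfigurationError("need at least one chain")
    post = UnconstrainedPosterior(spec, data)
    seed_seq = np.random.SeedSequence(seed)
    chain_seeds = seed_seq.spawn(chains)

    all_draws = np.empty((chains, iterations, post.n_params))
    stats = {
        "diverging": np.zeros((chains, iterations), dtype=bool),
        "lp": np.zeros((chains, iterations)),
        "tree_depth": np.zeros((chains, iterations), dtype=int),
        "acceptance_rate": np.zeros((chains, iterations)),
    }
    step_sizes = []
    n_div_warm = 0
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        q0 = post.initial_point(rng)
        res = sample_nuts(
            post.logp_grad,
            q0,
            warmup=warmup,
            iterations=iterations,
            rng=rng,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
        )
        all_draws[c] = res.draws
        stats["diverging"][c] = res.diverging
        stats["lp"][c] = res.logp
        stats["tree_depth"][c] = res.treedepth
        stats["acceptance_rate"][c] = res.accept_stat
        step_sizes.append(res.step_size)
        n_div_warm += res.n_divergent_warmup

    # unpack every draw into labelled parameter arrays
    var_names = [
        v for v in _VAR_DIMS
        if not (
            (spec.variant == "static" and v in ("gamma_mb", "sigma_rw"))
            or (spec.variant == "dynamic" and v in ("gamma_b", "kappa", "sigma_b", "sigma_m"))
            or (spec.response == "richness" and v == "sigma_obs")
        )
    ]
    sample_ps, _ = post.unpack(all_draws[0, 0])
    store: dict[str, np.ndarray] = {}
    for v in var_names:
        arr = getattr(sample_ps, v)
        store[v] = np.empty((chains, iterations) + arr.shape)
    for c in range(chains):
        for d in range(iterations):
            ps, _ = post.unpack(all_draws[c, d])
            for v in var_names:
                store[v][c, d] = getattr(ps, v)

    coords = coords or _default_coords(spec)
    idata = az.from_dict(
        posterior=store,
        sample_stats=stats,
        dims={v: list(_VAR_DIMS[v]) for v in var_names},
        coords=coords,
    )

    div_frac = float(stats["diverging"].mean())
    metadata = {
        "chains": chains,
        "warmup": warmup,
        "iterations": iterations,
        "seed": seed,
        "step_sizes": step_sizes,
        "divergent_fraction": div_frac,
        "divergent_warmup": n_div_warm,
        "divergence_warning": div_frac > divergence_warn_frac,
    }
    if metadata["divergence_warning"]:
        warnings.warn(
            f"{div_frac:.1%} divergent transitions exceed the "
            f"{divergence_warn_frac:.0%} threshold; treat results with caution",
            stacklevel=2,
        )
    return PosteriorDraws(idata, spec, scaling, coords, metadata)
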