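"""Convergence diagnostics: split-Rhat and effective sample size per parameter."""

from __future__ import annotations

import warnings

import arviz as az
import numpy as np
import pandas as pd

from .fit import PosteriorDraws

RHAT_THRESHOLD = 1.01
NEFF_FLOOR = 1000.0


def diagnostics(
    draws: PosteriorDraws,
    *,
    rhat_threshold: float = RHAT_THRESHOLD,
    neff_floor: float = NEFF_FLOOR,
    var_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-parameter-element split-Rhat and bulk effective sample size.

    Returns one row per scalar parameter element with pass/fail flags
    (Rhat < threshold and n_eff > floor).  With a single chain Rhat is
    undefined and reported as NaN (its flag is NaN-safe False).
    """
    post = draws.posterior
    if var_names is not None:
        post = post[var_names]
    single_chain = post.sizes["chain"] < 2
    with warnings.catch_warnings():
        # structurally constant elements (e.g. the unit diagonal of a
        # correlation matrix) trigger 0/0 inside the estimators
        warnings.simplefilter("ignore", RuntimeWarning)
        ess = az.ess(post, method="bulk")
        rhat = ess * np.nan if single_chain else az.rhat(post)

    rows = []
    for name in post.data_vars:
        r = np.asarray(rhat[name]).ravel()
        e = np.asarray(ess[name]).ravel()
        da = post[name]
        const = (
            (da.max(("chain", "draw")) - da.min(("chain", "draw")))
            .to_numpy()
            .ravel()
            == 0
        )
        extra_dims = [d for d in da.dims if d not in ("chain", "draw")]
        if extra_dims:
            labels = [
                "[" + ",".join(str(x) for x in tup) + "]"
                for tup in np.array(
                    np.meshgrid(*[da.coords[d].values for d in extra_dims],
                                indexing="ij")
                ).reshape(len(extra_dims), -1).T
            ]
        else:
            labels = [""]
        for lab, rv, ev, cv in zip(labels, r, e, const):
            if cv:
                continue  # no sampling uncertainty to diagnose
            rows.append(
                {
                    "parameter": f"{name}{lab}",
                    "rhat": float(rv),
                    "n_eff": float(ev),
                    "rhat_ok": bool(rv < rhat_threshold) if np.isfinite(rv) else False,
                    "neff_ok": bool(ev > neff_floor),
                }
            )
    table = pd.DataFrame(rows)
    table["pass"] = table["rhat_ok"] & table["neff_ok"]
    return table


def summarize_convergence(table: pd.DataFrame) -> dict:
    """Headline convergence numbers from a diagnostics table."""
    return {
        "max_rhat": float(np.nanmax(table["rhat"])) if len(table) else float("nan"),
        "min_n_eff": float(np.nanmin(table["n_eff"])) if len(table) else float("nan"),
        "all_rhat_ok": bool(table["rhat_ok"].all()),
        "all_neff_ok": bool(table["neff_ok"].all()),
    }
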