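"""Shared fixtures: small synthetic datasets and reusable model fits."""

from __future__ import annotations

import numpy as np
import pytest

from vegbench.model.fit import fit
from vegbench.simulate import (
    SimulationScenario,
    draw_true_params,
    simulate_surveys,
    survey_data_from_aggregated,
)


@pytest.fixture(scope="session")
def tiny_scenario() -> SimulationScenario:
    return SimulationScenario(
        n_classes=3, n_formations=2, n_bioregions=2, n_years=2,
        n_plots=8, n_surveys=25, variant="static",
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_scenario):
    pr = draw_true_params(tiny_scenario, 1, "richness")
    pc = draw_true_params(tiny_scenario, 2, "cover")
    return simulate_surveys(tiny_scenario, pr, pc, 3)


@pytest.fixture(scope="session")
def calibration_fits():
    """Twenty replicate fits on data whose truth is drawn from the model's priors.

    The scenario draws the grand means and every scale hyperparameter from the
    same priors the model uses (at calibration-friendly prior scales), so the
    posterior rank of the truth is uniform for a correct sampler and posterior
    means should fall within 2 posterior sd of the truth at the nominal rate.
    """
    scenario = SimulationScenario(
        n_classes=3, n_formations=2, n_bioregions=2, n_years=2,
        n_plots=10, n_surveys=50, variant="static",
        hypers_from_prior=True, scale_prior_sd=0.25, vague_sd=0.5,
    )
    reps = []
    for rep in range(20):
        truth = draw_true_params(scenario, 1000 + rep, "richness")
        sim = simulate_surveys(scenario, truth, None, 2000 + rep, emit_records=False)
        data, scaling = survey_data_from_aggregated(sim.aggregated, "richness")
        spec = scenario.build_spec("richness")
        draws = fit(
            spec, data, chains=1, warmup=180, iterations=150, seed=rep,
            scaling=scaling, max_treedepth=7,
        )
        rep_result = {"truth": truth}
        for name in ("alpha", "iota", "eps"):
            rep_result[name] = draws.stacked(name)  # (n_draws, 6)
        reps.append(rep_result)
    return reps
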