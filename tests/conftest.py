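"""Shared fixtures: small synthetic designs reused across test modules."""

import math

import pandas as pd
import pytest

from resfish.config import PipelineConfig, SimulationConfig
from resfish.gamm import FishDensityGAMM, ModelSpec, prepare_model_table
from resfish.inventory import clean_inventory
from resfish.pipeline import run_pipeline
from resfish.simulate import simulate_inventory, simulate_surveys, true_summary
from resfish.surveys import link_surveys


def zero_noise_config(**overrides) -> SimulationConfig:
    """A generator config with every stochastic term switched off."""
    base = dict(
        seed=5, n_reservoirs=400, n_ecoregions=3,
        ln_volume_sd=1.0, ln_discharge_sd=1.0,
        ecoregion_volume_shift_sd=0.0, area_noise_sd=0.2,
        class_separation=0.0,
        density_intercept_per_class=(5.5, 5.5, 5.5, 5.5),
        age_curve_alpha=0.0, year_trend_slope=-0.005,
        random_intercept_sd=0.0, gamma_shape=math.inf,
        survey_fraction=0.15, surveys_per_reservoir=3,
        missing_area_fraction=0.0, missing_coord_fraction=0.0,
        missing_discharge_fraction=0.0, duplicate_fraction=0.02,
        n_natural_lakes=2,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def recovery_design():
    """The parameter-recovery design: ~200 sampled reservoirs, ~1,000
    surveys, 4 latent classes, Gamma shape 20, fixed seed.

    The density model is fitted with the generator's true class labels so
    the check isolates the regression model from the clustering step.
    """
    cfg = SimulationConfig(
        seed=11, n_reservoirs=1000, survey_fraction=0.2,
        surveys_per_reservoir=6, gamma_shape=20.0, class_separation=1.0,
        random_intercept_sd=0.3, missing_area_fraction=0.0,
        missing_coord_fraction=0.0, missing_discharge_fraction=0.0,
        duplicate_fraction=0.0, n_natural_lakes=0)
    inv = simulate_inventory(cfg)
    surveys, _ = simulate_surveys(inv, cfg)
    cleaned, _ = clean_inventory(inv)
    linked, _ = link_surveys(surveys, cleaned)
    assignments = pd.DataFrame({
        "reservoir_id": inv["reservoir_id"],
        "schema_id": 3,
        "class_label": inv["_true_class"].map(lambda c: f"C{c}"),
    })
    spec = ModelSpec()
    table, report = prepare_model_table(linked, assignments, spec)
    fit = FishDensityGAMM(table, spec).fit()
    truth, total = true_summary(inv, cfg, year=1993)
    return {"config": cfg, "inventory": inv, "linked": linked,
            "assignments": assignments, "fit": fit,
            "truth": truth.set_index("reservoir_id"), "truth_total": total}


@pytest.fixture(scope="session")
def small_pipeline():
    """A fast five-schema end-to-end run on a modest noisy inventory."""
    sim = SimulationConfig(seed=3, n_reservoirs=1200, n_ecoregions=4,
                           survey_fraction=0.12, surveys_per_reservoir=4,
                           class_separation=1.0)
    cfg = PipelineConfig(seed=3, simulation=sim)
    return run_pipeline(cfg)


@pytest.fixture()
def zero_noise_pipeline():
    cfg = PipelineConfig(seed=5, schemas=(1,), simulation=zero_noise_config())
    return run_pipeline(cfg, until="scaleup")
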