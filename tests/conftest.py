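import numpy as np
import pandas as pd
import pytest

from epidemand import (BayesianPoissonModel, ScenarioConfig, default_priors,
                       generate_geography, generate_seed_dataset,
                       model_registry)
from epidemand.model import DesignMatrix, ModelSpec


def small_scenario(**overrides) -> ScenarioConfig:
    """A cut-down scenario that keeps every structural feature of the
    default study design but runs in well under a second."""
    base = dict(
        n_areas=60, n_regions=12, n_ccgs=8,
        age_bands=["16-17", "18-19", "20-24", "25-29", "30-34", "35-39",
                   "40-44", "45-49", "50-54", "55-59", "60-64"],
        total_person_years=600_000.0, expected_total_cases=600.0,
        rng_seed=11,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return small_scenario()


@pytest.fixture(scope="session")
def small_seed(small_config):
    return generate_seed_dataset(small_config)


@pytest.fixture(scope="session")
def small_fit(small_seed):
    model = BayesianPoissonModel.from_dataframe(
        small_seed.frame, model_registry()[4], default_priors())
    return model.fit(n_draws=500, rng_seed=3)


@pytest.fixture(scope="session")
def small_geography(small_config):
    return generate_geography(small_config)


def intercept_only_design(cases: np.ndarray, person_years: np.ndarray
                          ) -> DesignMatrix:
    """Hand-built single-column design for analytic worked examples."""
    n = len(cases)
    return DesignMatrix(
        X=np.ones((n, 1)), y=np.asarray(cases, float),
        offset=np.log(np.asarray(person_years, float)),
        person_years=np.asarray(person_years, float),
        columns=["intercept"],
        factor_levels={"age_band": ["16-17"], "gender": ["female"],
                       "ethnicity": ["white_british"]},
        standardization={}, spec=ModelSpec(0, ()), n_dropped_zero_py=0)


def make_strata_frame(rows: list[dict]) -> pd.DataFrame:
    """Minimal strata frame with every covariate column present."""
    defaults = dict(area_id="area_000", region_id="region_000",
                    age_band="16-17", gender="female",
                    ethnicity="white_british", cases=0, person_years=1000.0,
                    deprivation=0.0, social_fragmentation=0.0,
                    population_density=100.0, cannabis_prevalence=0.1,
                    ethnic_density=10.0, inequality=0.0)
    return pd.DataFrame([{**defaults, **r} for r in rows])
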