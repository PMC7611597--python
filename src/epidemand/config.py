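"""Scenario and run configuration.

A :class:`ScenarioConfig` fully describes a synthetic study scenario: the
stratification scheme (small areas, regions, age bands, genders, ethnic
groups), the true generative coefficients on the log-relative-risk scale,
the exposure scale, denominator growth, and the observed service-cascade
structure (multipliers and missing-ethnicity fraction).

The default scenario mirrors the scale of the pooled English first-episode
psychosis catchment studies used to seed the incidence model: roughly 750
small areas, 4.5 million person-years at risk and ~1638 expected cases,
stratified by 11 age bands (16-64), gender and 9 ethnic groups.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

DEFAULT_AGE_BANDS = [
    "16-17", "18-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64",
]

DEFAULT_GENDERS = ["female", "male"]

DEFAULT_ETHNIC_GROUPS = [
    "white_british", "white_other", "black_caribbean", "black_african",
    "indian", "pakistani", "bangladeshi", "mixed", "other",
]

#: Approximate share of the 16-64 population in each default age band
#: (England-like age structure; normalised at use).
DEFAULT_AGE_WEIGHTS = {
    "16-17": 0.033, "18-19": 0.040, "20-24": 0.105, "25-29": 0.110,
    "30-34": 0.105, "35-39": 0.100, "40-44": 0.105, "45-49": 0.110,
    "50-54": 0.105, "55-59": 0.098, "60-64": 0.089,
}

#: National-level ethnic composition of the working-age population
#: (England-like; per-area shares vary around these).
DEFAULT_ETHNICITY_SHARES = {
    "white_british": 0.795, "white_other": 0.056, "black_caribbean": 0.012,
    "black_african": 0.018, "indian": 0.026, "pakistani": 0.021,
    "bangladeshi": 0.008, "mixed": 0.022, "other": 0.042,
}

AREA_COVARIATES = [
    "deprivation", "deprivation_sq", "social_fragmentation",
    "cannabis_prevalence", "population_density", "ethnic_density",
    "inequality",
]

DEFAULT_REFERENCE_LEVELS = {
    "age_band": "16-17",
    "gender": "female",
    "ethnicity": "white_british",
}


def default_true_coefficients() -> dict[str, float]:
    """Generative log-relative-risks for the default scenario.

    Age and gender effects follow the canonical first-episode psychosis
    age-incidence curve (peak in the early twenties, male excess at young
    ages that attenuates and reverses with age).  Ethnic-group effects put
    the largest excess risk on Black Caribbean (RR 4.80) and Black African
    (RR 3.33) groups.  Area effects: higher risk with deprivation (convex
    on the log scale), a modest protective fragmentation effect (RR 0.92
    per s.d.) and a positive regional cannabis-prevalence effect (RR 1.41
    per s.d.).  Population density, own-group ethnic density and
    inequality are null in the default scenario, so the four-covariate
    area model is the data-generating model.
    """
    import math

    coefs: dict[str, float] = {}
    age_eff = {
        "18-19": 0.35, "20-24": 0.40, "25-29": 0.15, "30-34": -0.10,
        "35-39": -0.40, "40-44": -0.70, "45-49": -0.90, "50-54": -1.10,
        "55-59": -1.30, "60-64": -1.50,
    }
    for band, b in age_eff.items():
        coefs[f"age[{band}]"] = b
    coefs["gender[male]"] = 0.15
    male_excess = {
        "18-19": 0.45, "20-24": 0.50, "25-29": 0.35, "30-34": 0.15,
        "35-39": 0.00, "40-44": -0.10, "45-49": -0.20, "50-54": -0.25,
        "55-59": -0.30, "60-64": -0.30,
    }
    for band, b in male_excess.items():
        coefs[f"age[{band}]:gender[male]"] = b
    eth_rr = {
        "white_other": 1.30, "black_caribbean": 4.80, "black_african": 3.33,
        "indian": 1.70, "pakistani": 2.00, "bangladeshi": 1.60,
        "mixed": 2.30, "other": 1.50,
    }
    for grp, rr in eth_rr.items():
        coefs[f"eth[{grp}]"] = math.log(rr)
    coefs["deprivation"] = 0.15
    coefs["deprivation_sq"] = 0.05
    coefs["social_fragmentation"] = math.log(0.92)
    coefs["cannabis_prevalence"] = math.log(1.41)
    return coefs


class ScenarioConfig(BaseModel):
    """Complete description of one synthetic study scenario."""

    n_areas: int = Field(default=750, gt=0)
    n_regions: int = Field(default=25, gt=0)
    n_ccgs: int = Field(default=30, gt=0)
    age_bands: list[str] = Field(default_factory=lambda: list(DEFAULT_AGE_BANDS))
    genders: list[str] = Field(default_factory=lambda: list(DEFAULT_GENDERS))
    ethnic_groups: list[str] = Field(
        default_factory=lambda: list(DEFAULT_ETHNIC_GROUPS))
    reference_levels: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS))
    true_coefficients: dict[str, float] = Field(
        default_factory=default_true_coefficients)
    #: Cases per person-year in the reference stratum.  When ``None`` the
    #: generator calibrates it so the scenario's expected total case count
    #: equals ``expected_total_cases``.
    baseline_rate: Optional[float] = None
    expected_total_cases: float = Field(default=1638.0, gt=0)
    total_person_years: float = Field(default=4_515_379.0, ge=0)
    baseline_year: int = 2017
    #: Stratum-pattern -> multiplicative yearly denominator growth factor.
    #: ``"*"`` matches every stratum; other keys are comma-separated
    #: ``field=value`` selectors (e.g. ``"ethnicity=black_african"``).
    annual_growth: dict[str, float] = Field(default_factory=lambda: {"*": 1.005})
    missing_ethnicity_fraction: float = Field(default=0.102, ge=0, lt=1)
    #: (referred, assessed, treated) case-loads per probable case.
    cascade_multipliers: tuple[float, float, float] = (2.8369, 2.5494, 1.1628)
    #: Fraction of treated cases not meeting operational psychosis criteria.
    probable_adjustment: float = Field(default=0.14, ge=0, lt=1)
    #: Fraction of commissioning areas serving ages 16-35 only.
    restricted_age_fraction: float = Field(default=0.2, ge=0, le=1)
    age_weights: Optional[dict[str, float]] = None
    ethnicity_shares: Optional[dict[str, float]] = None
    cannabis_range: tuple[float, float] = (0.06, 0.14)
    area_size_sigma: float = Field(default=0.5, ge=0)
    ethnicity_concentration: float = Field(default=30.0, gt=0)
    rng_seed: int = 0

    @field_validator("cascade_multipliers")
    @classmethod
    def _cascade_ordered(cls, v):
        referred, assessed, treated = v
        if not (referred >= assessed >= treated >= 1.0):
            raise ValueError(
                "cascade multipliers must satisfy referred >= assessed >= treated >= 1; "
                f"got {v}")
        return v

    @field_validator("annual_growth")
    @classmethod
    def _growth_positive(cls, v):
        for pattern, g in v.items():
            if g <= 0:
                raise ValueError(f"growth factor for {pattern!r} must be > 0, got {g}")
        return v

    @model_validator(mode="after")
    def _check_vocabulary(self):
        vocab = self.coefficient_vocabulary()
        unknown = sorted(set(self.true_coefficients) - vocab)
        if unknown:
            raise ValueError(
                f"unknown coefficient name(s) in true_coefficients: {unknown}; "
                "allowed names follow the design-matrix vocabulary "
                "(age[...], gender[...], age[...]:gender[...], eth[...], "
                f"{', '.join(AREA_COVARIATES)})")
        if self.baseline_rate is not None and self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        for factor, levels in (("age_band", self.age_bands),
                               ("gender", self.genders),
                               ("ethnicity", self.ethnic_groups)):
            ref = self.reference_levels.get(factor)
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not among {factor} levels")
        return self

    def coefficient_vocabulary(self) -> set[str]:
        """All admissible generative coefficient names for this scenario."""
        ref = self.reference_levels
        vocab: set[str] = set(AREA_COVARIATES)
        ages = [a for a in self.age_bands if a != ref["age_band"]]
        gens = [g for g in self.genders if g != ref["gender"]]
        vocab.update(f"age[{a}]" for a in ages)
        vocab.update(f"gender[{g}]" for g in gens)
        vocab.update(f"age[{a}]:gender[{g}]" for a in ages for g in gens)
        vocab.update(f"eth[{e}]" for e in self.ethnic_groups
                     if e != ref["ethnicity"])
        return vocab

    def resolved_age_weights(self) -> dict[str, float]:
        w = self.age_weights
        if w is None:
            if set(self.age_bands) == set(DEFAULT_AGE_WEIGHTS):
                w = DEFAULT_AGE_WEIGHTS
            else:
                w = {b: 1.0 for b in self.age_bands}
        total = sum(w[b] for b in self.age_bands)
        return {b: w[b] / total for b in self.age_bands}

    def resolved_ethnicity_shares(self) -> dict[str, float]:
        s = self.ethnicity_shares
        if s is None:
            if set(self.ethnic_groups) == set(DEFAULT_ETHNICITY_SHARES):
                s = DEFAULT_ETHNICITY_SHARES
            else:
                s = {e: 1.0 for e in self.ethnic_groups}
        total = sum(s[e] for e in self.ethnic_groups)
        return {e: s[e] / total for e in self.ethnic_groups}


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (simulate -> fit -> predict ->
    validate -> forecast)."""

    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    model_id: int = 4
    n_draws: int = Field(default=1000, gt=0)
    seeds: dict[str, int] = Field(default_factory=lambda: {
        "simulate": 1, "fit": 2, "cascade": 3, "imputation": 4})
    validation_year: int = 2017
    forecast_years: list[int] = Field(
        default_factory=lambda: list(range(2019, 2026)))
    band_edges: tuple[float, float] = (10.0, 20.0)
    excluded_ccgs: list[str] = Field(default_factory=list)
    excluded_areas: list[str] = Field(default_factory=list)
    prior_overrides: dict[str, tuple[float, float]] = Field(default_factory=dict)
    outdir: str = "output"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()
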