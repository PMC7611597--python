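"""Synthetic study-data generator.

Emulates the four inputs of the forecasting pipeline with the statistical
structure the pipeline assumes:

* a stratified **seed incidence table** — Poisson case counts per small-area
  x age-band x gender x ethnicity stratum, with area-level socio-
  environmental covariates, generated under known log-relative-risks;
* **denominator projections** per forecast year (deterministic multiplicative
  growth applied to the baseline exposures, with population density
  recomputed per year);
* a **geography lookup** mapping small areas to commissioning areas (CCGs)
  together with the age range each commissioning area serves; and
* an **observed service-cascade table** per commissioning area — referred /
  assessed / treated counts with a multiplicative cascade structure,
  stratum-level treated counts, and independently masked ethnicity.

Covariate marginals: deprivation and social fragmentation are standard
normal across areas (so effects per 1 s.d. are directly interpretable),
population density is log-normal, regional cannabis prevalence is uniform
over a plausible prevalence range, and per-area ethnic composition is
Dirichlet around national shares (which also yields the own-group
ethnic-density covariate).  The generative linear predictor is evaluated
through the same design-matrix code used at fit time, so generative
coefficients and fitted coefficients share one vocabulary by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .model import AREA_TERM_NAMES, ModelSpec, build_design

SEED_COLUMNS = [
    "area_id", "region_id", "age_band", "gender", "ethnicity", "cases",
    "person_years", "deprivation", "social_fragmentation",
    "population_density", "cannabis_prevalence", "ethnic_density",
    "inequality",
]


@dataclass
class SeedDataset:
    """A generated seed incidence table plus its generative ground truth."""

    frame: pd.DataFrame
    true_coefficients: dict[str, float]
    baseline_rate: float
    config: ScenarioConfig
    expected_cases: np.ndarray = field(repr=False, default=None)

    @property
    def total_cases(self) -> int:
        return int(self.frame["cases"].sum())

    @property
    def total_person_years(self) -> float:
        return float(self.frame["person_years"].sum())


@dataclass
class ProjectionSet:
    """Projected denominator strata per forecast year."""

    baseline_year: int
    years: dict[int, pd.DataFrame]

    def __getitem__(self, year: int) -> pd.DataFrame:
        if year not in self.years:
            raise KeyError(f"no projection available for year {year}")
        return self.years[year]

    def __contains__(self, year: int) -> bool:
        return year in self.years


@dataclass
class ObservedCascadeRecord:
    """Observed service-cascade counts for one commissioning area."""

    ccg_id: str
    served_age_min: int
    served_age_max: int
    referred: int
    assessed: int
    treated: int
    person_years_served: float
    treated_by_stratum: pd.DataFrame  # columns: age_band, gender, ethnicity, count

    def __post_init__(self):
        if not (self.referred >= self.assessed >= self.treated >= 0):
            raise ValueError(
                f"cascade ordering violated for {self.ccg_id}: "
                f"referred={self.referred}, assessed={self.assessed}, "
                f"treated={self.treated}")
        total = int(self.treated_by_stratum["count"].sum())
        if total != self.treated:
            raise ValueError(
                f"stratum treated counts sum to {total}, expected {self.treated}")


def _mid(lo_hi: str) -> float:
    lo, hi = lo_hi.split("-")
    return (float(lo) + float(hi)) / 2.0


def _age_band_range(band: str) -> tuple[int, int]:
    lo, hi = band.split("-")
    return int(lo), int(hi)


def _structure_frame(config: ScenarioConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    """Areas, regions, covariates and baseline person-years per stratum."""
    n_areas = config.n_areas
    width = max(3, len(str(n_areas)))
    area_ids = np.array([f"area_{i:0{width}d}" for i in range(n_areas)])
    region_idx = (np.arange(n_areas) * config.n_regions) // n_areas
    region_ids = np.array([f"region_{r:03d}" for r in region_idx])

    deprivation = rng.standard_normal(n_areas)
    fragmentation = rng.standard_normal(n_areas)
    density = np.exp(rng.normal(8.0, 1.0, n_areas))  # persons per km^2-ish
    inequality = rng.standard_normal(n_areas)
    lo, hi = config.cannabis_range
    cannabis_region = rng.uniform(lo, hi, config.n_regions)
    cannabis = cannabis_region[region_idx]

    # area exposure shares: log-normal spread around equal shares
    w = np.exp(rng.normal(0.0, config.area_size_sigma, n_areas))
    area_py = config.total_person_years * w / w.sum()

    shares = config.resolved_ethnicity_shares()
    eth_groups = list(config.ethnic_groups)
    alpha = np.array([shares[e] for e in eth_groups]) * config.ethnicity_concentration
    eth_share = rng.dirichlet(alpha, size=n_areas)  # (n_areas, n_eth)
    ref_eth = config.reference_levels["ethnicity"]
    ref_i = eth_groups.index(ref_eth)
    ethnic_density = 100.0 * (1.0 - eth_share[:, ref_i])

    age_w = config.resolved_age_weights()
    bands = list(config.age_bands)
    genders = list(config.genders)

    n_strata = n_areas * len(bands) * len(genders) * len(eth_groups)
    idx = pd.MultiIndex.from_product(
        [np.arange(n_areas), bands, genders, eth_groups],
        names=["_ai", "age_band", "gender", "ethnicity"])
    frame = idx.to_frame(index=False)
    ai = frame["_ai"].to_numpy()
    band_w = frame["age_band"].map(age_w).to_numpy()
    eth_i = frame["ethnicity"].map({e: i for i, e in enumerate(eth_groups)}).to_numpy()
    py = area_py[ai] * band_w * (1.0 / len(genders)) * eth_share[ai, eth_i]

    out = pd.DataFrame({
        "area_id": area_ids[ai],
        "region_id": region_ids[ai],
        "age_band": frame["age_band"].to_numpy(),
        "gender": frame["gender"].to_numpy(),
        "ethnicity": frame["ethnicity"].to_numpy(),
        "person_years": py,
        "deprivation": deprivation[ai],
        "social_fragmentation": fragmentation[ai],
        "population_density": density[ai],
        "cannabis_prevalence": cannabis[ai],
        "ethnic_density": ethnic_density[ai],
        "inequality": inequality[ai],
    })
    assert len(out) == n_strata
    return out


def _generator_spec(config: ScenarioConfig) -> ModelSpec:
    """Model spec covering every area term used by the true coefficients."""
    keys = set(config.true_coefficients)
    area_terms = tuple(t for t in AREA_TERM_NAMES if t in keys
                       or (t == "deprivation" and "deprivation_sq" in keys))
    form = "quadratic" if "deprivation_sq" in keys else "linear"
    return ModelSpec(0, area_terms, form, dict(config.reference_levels))


def expected_rates(config: ScenarioConfig, frame: pd.DataFrame
                   ) -> tuple[np.ndarray, float]:
    """Per-stratum expected counts under the true coefficients.

    Returns ``(lambda, baseline_rate)`` where ``lambda`` aligns with
    ``frame`` rows (zero for zero-exposure strata).  When the config does
    not pin ``baseline_rate``, it is calibrated so the expected total case
    count equals ``config.expected_total_cases``.
    """
    if not (frame["person_years"] > 0).any():
        # zero exposure everywhere forces zero counts
        return np.zeros(len(frame)), (config.baseline_rate or 0.0)
    spec = _generator_spec(config)
    probe = frame.copy()
    probe["cases"] = 0
    design = build_design(probe, spec)
    beta = np.zeros(design.n_params)
    for name, b in config.true_coefficients.items():
        if name in design.columns:
            beta[design.columns.index(name)] = b
    lam0 = np.zeros(len(frame))
    rows = design.row_index
    lam0[frame.index.get_indexer(rows)] = np.exp(
        design.X @ beta + design.offset)
    if config.baseline_rate is not None:
        baseline = config.baseline_rate
    else:
        baseline = config.expected_total_cases / lam0.sum()
    return baseline * lam0, baseline


def generate_seed_dataset(config: ScenarioConfig,
                          rng_seed: int | None = None) -> SeedDataset:
    """Generate one stratified seed incidence data-set.

    Counts are Poisson around ``person_years * baseline * exp(x'beta_true)``;
    zero-exposure strata always have zero cases.  Deterministic under
    ``rng_seed`` (defaults to ``config.rng_seed``).
    """
    if config.total_person_years < 0:
        raise ValueError("total_person_years must be non-negative")
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    frame = _structure_frame(config, rng)
    lam, baseline = expected_rates(config, frame)
    frame = frame.copy()
    frame["cases"] = rng.poisson(lam)
    frame.loc[frame["person_years"] <= 0, "cases"] = 0
    frame = frame[SEED_COLUMNS]
    true = dict(config.true_coefficients)
    true["intercept"] = math.log(baseline)
    return SeedDataset(frame, true, baseline, config, expected_cases=lam)


def _growth_factors(config: ScenarioConfig, frame: pd.DataFrame) -> np.ndarray:
    """Per-stratum yearly growth factor from the pattern map."""
    g = np.ones(len(frame))
    matched_default = "*" in config.annual_growth
    if matched_default:
        g *= config.annual_growth["*"]
    for pattern, factor in config.annual_growth.items():
        if pattern == "*":
            continue
        mask = np.ones(len(frame), dtype=bool)
        for clause in pattern.split(","):
            fld, _, val = clause.partition("=")
            fld, val = fld.strip(), val.strip()
            if fld not in frame.columns:
                raise ValueError(f"unknown growth pattern field {fld!r}")
            mask &= frame[fld].to_numpy() == val
        g[mask] *= factor
    return g


def generate_projections(config: ScenarioConfig, years: list[int],
                         baseline: pd.DataFrame | None = None,
                         rng_seed: int | None = None) -> ProjectionSet:
    """Deterministic denominator projections for the requested years.

    Person-years per stratum grow as ``baseline * growth^(year - baseline
    year)``; population density is recomputed per year in proportion to the
    area's projected person-years, other covariates stay at their baseline
    values.  ``baseline`` defaults to the structural frame of the scenario
    (regenerated from the config seed, so seed and projections share the
    same areas and covariates).
    """
    if not years:
        raise ValueError("years list is empty")
    if list(years) != sorted(set(years)):
        raise ValueError("years must be strictly increasing")
    if baseline is None:
        rng = np.random.default_rng(
            config.rng_seed if rng_seed is None else rng_seed)
        baseline = _structure_frame(config, rng)
    base = baseline.drop(columns=["cases"], errors="ignore").copy()
    growth = _growth_factors(config, base)
    out: dict[int, pd.DataFrame] = {}
    base_area_py = base.groupby("area_id")["person_years"].transform("sum")
    for year in years:
        k = year - config.baseline_year
        f = base.copy()
        f["person_years"] = base["person_years"].to_numpy() * growth ** k
        year_area_py = f.groupby("area_id")["person_years"].transform("sum")
        scale = np.where(base_area_py > 0, year_area_py / base_area_py, 1.0)
        f["population_density"] = base["population_density"].to_numpy() * scale
        f["year"] = year
        out[year] = f
    return ProjectionSet(config.baseline_year, out)


def generate_geography(config: ScenarioConfig,
                       rng_seed: int | None = None) -> pd.DataFrame:
    """Area -> commissioning-area lookup with served age ranges.

    Areas are assigned to CCGs in contiguous blocks; a configurable fraction
    of CCGs serves ages 16-35 only, the rest the full 16-64 range.
    """
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    n_areas, n_ccgs = config.n_areas, config.n_ccgs
    width = max(3, len(str(n_areas)))
    area_ids = [f"area_{i:0{width}d}" for i in range(n_areas)]
    ccg_idx = (np.arange(n_areas) * n_ccgs) // n_areas
    n_restricted = int(round(config.restricted_age_fraction * n_ccgs))
    restricted = set(rng.choice(n_ccgs, size=n_restricted, replace=False))
    rows = []
    for i, a in enumerate(area_ids):
        c = int(ccg_idx[i])
        rows.append({
            "area_id": a,
            "ccg_id": f"ccg_{c:03d}",
            "served_age_min": 16,
            "served_age_max": 35 if c in restricted else 64,
        })
    return pd.DataFrame(rows)


def served_age_mask(age_bands: pd.Series, age_min: int, age_max: int
                    ) -> np.ndarray:
    """True for age bands lying entirely inside [age_min, age_max]."""
    los_his = age_bands.map(_age_band_range)
    return np.array([lo >= age_min and hi <= age_max for lo, hi in los_his])


def generate_observed_cascade(truth: pd.DataFrame, geography: pd.DataFrame,
                              config: ScenarioConfig,
                              rng_seed: int | None = None,
                              noise: bool = True
                              ) -> list[ObservedCascadeRecord]:
    """Generate an observed service-cascade table per commissioning area.

    ``truth`` is a stratified table with ``cases`` interpreted as the true
    probable-case counts for the observation year.  Treated counts are
    drawn around truth x treated-multiplier, assessed and referred add
    Poisson increments so referred >= assessed >= treated holds by
    construction, and each treated case's ethnicity is masked independently
    with probability ``missing_ethnicity_fraction`` (masked cases land in an
    ``unknown`` ethnicity bucket).  ``noise=False`` replaces all sampling by
    deterministic rounding for exact tests.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    m_ref, m_ass, m_trt = config.cascade_multipliers
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4242]))
    merged = truth.merge(geography, on="area_id", validate="many_to_one")
    if len(merged) != len(truth):
        orphans = sorted(set(truth["area_id"]) - set(geography["area_id"]))
        raise ValueError(f"areas missing from geography lookup: {orphans[:5]}")
    records = []
    for ccg_id, g in merged.groupby("ccg_id", sort=True):
        age_min = int(g["served_age_min"].iloc[0])
        age_max = int(g["served_age_max"].iloc[0])
        served = g[served_age_mask(g["age_band"], age_min, age_max)]
        strat = (served.groupby(["age_band", "gender", "ethnicity"],
                                sort=True)["cases"].sum().reset_index())
        truth_total = float(strat["cases"].sum())
        py_served = float(served["person_years"].sum())
        if noise:
            treated = int(rng.poisson(m_trt * truth_total))
            assessed = treated + int(rng.poisson((m_ass - m_trt) * truth_total))
            referred = assessed + int(rng.poisson((m_ref - m_ass) * truth_total))
        else:
            treated = int(round(m_trt * truth_total))
            assessed = int(round(m_ass * truth_total))
            referred = int(round(m_ref * truth_total))
        # distribute treated cases over strata proportional to truth counts
        w = strat["cases"].to_numpy(dtype=float)
        if w.sum() > 0:
            if noise:
                counts = rng.multinomial(treated, w / w.sum())
            else:
                counts = _largest_remainder(treated * w / w.sum())
        else:
            counts = np.zeros(len(strat), dtype=int)
        strat = strat.drop(columns="cases")
        strat["count"] = counts
        # mask ethnicity independently per treated case
        frac = config.missing_ethnicity_fraction
        if frac > 0 and strat["count"].sum() > 0:
            if noise:
                masked = rng.binomial(strat["count"].to_numpy(), frac)
            else:
                masked = _largest_remainder(strat["count"].to_numpy() * frac)
            strat["count"] = strat["count"].to_numpy() - masked
            unk = strat[["age_band", "gender"]].copy()
            unk["ethnicity"] = "unknown"
            unk["count"] = masked
            unk = unk.groupby(["age_band", "gender", "ethnicity"],
                              sort=True)["count"].sum().reset_index()
            strat = pd.concat([strat, unk[unk["count"] > 0]],
                              ignore_index=True)
        strat = strat[strat["count"] > 0].reset_index(drop=True)
        records.append(ObservedCascadeRecord(
            ccg_id=ccg_id, served_age_min=age_min, served_age_max=age_max,
            referred=referred, assessed=assessed, treated=treated,
            person_years_served=py_served, treated_by_stratum=strat))
    return records


def _largest_remainder(quotas: np.ndarray) -> np.ndarray:
    """Integer allocation preserving the rounded total (largest remainder)."""
    floors = np.floor(quotas).astype(int)
    remainder = int(round(quotas.sum())) - floors.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - floors), kind="stable")
        floors[order[:remainder]] += 1
    return floors
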