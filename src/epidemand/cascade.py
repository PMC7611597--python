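"""Care-cascade ratio estimation and multi-year case-load forecasting.

Observed service data form a nested cascade: people *referred* for
suspected psychosis, the subset *assessed*, the subset *treated*, and the
subset of treated meeting probable-case criteria.  Dividing observed
referred/assessed/treated totals by the derived probable total yields
cascade ratios; applying those ratios per posterior draw to probable-case
forecasts produces the four nested case-load forecasts with intervals for
each forecast year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DesignMatrix, PoissonLaplaceResults
from .predict import aggregate_draws, predict_strata, to_rates
from .simulate import ObservedCascadeRecord, ProjectionSet
from .validate import probable_from_treated, round_half_up

LEVELS = ("probable", "treated", "assessed", "referred")


@dataclass
class CascadeRatios:
    """Referred/assessed/treated case-loads per probable case."""

    referred_per_probable: float
    assessed_per_probable: float
    treated_per_probable: float
    level: str = "national"
    source_year: int | None = None

    def __post_init__(self):
        r, a, t = (self.referred_per_probable, self.assessed_per_probable,
                   self.treated_per_probable)
        bad = []
        if not r >= a:
            bad.append("referred < assessed")
        if not a >= t:
            bad.append("assessed < treated")
        if not t >= 1.0:
            bad.append("treated < probable")
        if bad:
            raise ValueError("cascade ordering violated: " + "; ".join(bad))

    def as_dict(self) -> dict[str, float]:
        return {"probable": 1.0, "treated": self.treated_per_probable,
                "assessed": self.assessed_per_probable,
                "referred": self.referred_per_probable}


def estimate_ratios(observed: list[ObservedCascadeRecord],
                    adjustment: float = 0.14, level: str = "national",
                    source_year: int | None = None
                    ) -> "CascadeRatios | pd.DataFrame":
    """Cascade ratios from observed totals.

    National level divides summed referred/assessed/treated totals by the
    probable total (derived from treated via the adjustment fraction);
    per-ccg level returns one ratio set per commissioning area.
    """
    if not observed:
        raise ValueError("no observed cascade records")
    if level == "national":
        referred = sum(r.referred for r in observed)
        assessed = sum(r.assessed for r in observed)
        treated = sum(r.treated for r in observed)
        probable = probable_from_treated(treated, adjustment)
        if probable == 0:
            raise ValueError("probable total is zero; ratios undefined")
        return CascadeRatios(referred / probable, assessed / probable,
                             treated / probable, "national", source_year)
    elif level == "ccg":
        rows = []
        for r in observed:
            probable = probable_from_treated(r.treated, adjustment)
            if probable == 0:
                raise ValueError(
                    f"probable total is zero for {r.ccg_id}; ratios undefined")
            rows.append({"ccg_id": r.ccg_id,
                         "referred_per_probable": r.referred / probable,
                         "assessed_per_probable": r.assessed / probable,
                         "treated_per_probable": r.treated / probable})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown ratio level {level!r}")


def forecast_years(fit: PoissonLaplaceResults, projections: ProjectionSet,
                   ratios: CascadeRatios, years: list[int],
                   geography: pd.DataFrame | None = None,
                   age_range_filter: bool = False,
                   noise: str = "none", rng_seed: int = 0) -> pd.DataFrame:
    """National case-load forecasts per year and cascade level.

    Per posterior draw, the probable-case forecast is multiplied by each
    cascade ratio; means and 2.5%/97.5% quantiles are taken across draws.
    ``noise='poisson'`` additionally samples each level's count as Poisson
    around ratio x probable (sensitivity mode); the default applies the
    ratios as deterministic multipliers.  Level ordering
    referred >= assessed >= treated >= probable holds in every draw.
    """
    missing = [y for y in years if y not in projections]
    if missing:
        raise ValueError(f"no projections for year(s): {missing}")
    rng = np.random.default_rng(rng_seed)
    mult = ratios.as_dict()
    rows = []
    for year in years:
        proj = projections[year]
        cube = predict_strata(fit, proj)
        groups, draws = aggregate_draws(
            cube, geography, level="national",
            age_range_filter=age_range_filter)
        probable = draws[0]
        py = float(groups["person_years"].iloc[0])
        for level in LEVELS:
            if noise == "poisson" and level != "probable":
                lvl = rng.poisson(mult[level] * probable).astype(float)
            else:
                lvl = mult[level] * probable
            rows.append({
                "year": year, "level": level,
                "mean_count": float(lvl.mean()),
                "lower95": float(np.quantile(lvl, 0.025)),
                "upper95": float(np.quantile(lvl, 0.975)),
                "person_years": py,
            })
    return to_rates(pd.DataFrame(rows))


def per_treated_summary(forecast: pd.DataFrame, year: int, base: int = 10
                        ) -> dict[str, int]:
    """People assessed and referred per ``base`` newly treated cases."""
    f = forecast[forecast["year"] == year].set_index("level")["mean_count"]
    for lvl in ("treated", "assessed", "referred"):
        if lvl not in f.index:
            raise ValueError(f"forecast for {year} lacks level {lvl!r}")
    treated = f["treated"]
    if treated == 0:
        raise ValueError("treated forecast is zero; per-treated summary undefined")
    return {
        "assessed_per_base": round_half_up(f["assessed"] / treated * base),
        "referred_per_base": round_half_up(f["referred"] / treated * base),
        "base": base,
    }
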