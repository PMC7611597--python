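"""External validation of predicted case-loads against observed service data.

Observed treated case-loads are deflated to *probable* case counts (by
default 14% of treated individuals do not go on to meet operational
psychosis criteria).  Predictions, age-matched to each commissioning area's
served range, are then compared with observed probable counts:

* nationally — absolute and percentage differences, overall and stratified
  by gender, broad age group and ethnic group;
* per commissioning area — Pearson correlation, r^2, RMSE on counts, and a
  weak-calibration slope (ordinary least squares of observed on predicted,
  with intercept);
* banded rate differences — counts of areas whose observed-minus-predicted
  rate difference per 100 000 person-years falls within +/-10, within
  +/-20 (cumulative) or beyond.

Missing observed ethnicity is handled by allocating the unknown bucket to
ethnic groups proportionally to the within-area observed distribution
(largest-remainder rounding, exactly conserving totals) or by multinomial
sampling for sensitivity analyses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import ObservedCascadeRecord

logger = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def probable_from_treated(treated: int, adjustment: float = 0.14) -> int:
    """Probable cases = treated deflated by the non-caseness fraction.

    ``probable = round(treated * (1 - adjustment))`` with half-up rounding.
    """
    if treated < 0:
        raise ValueError("treated count must be non-negative")
    if not (0 <= adjustment < 1):
        raise ValueError(f"adjustment fraction must be in [0, 1), got {adjustment}")
    return round_half_up(treated * (1.0 - adjustment))


@dataclass
class NationalRow:
    stratum_type: str  # total | gender | broad_age | ethnicity
    stratum: str
    predicted: float
    observed: float
    difference: float
    percent_difference: Optional[float]


@dataclass
class CcgMetrics:
    r: float
    r_squared: float
    rmse: float
    calibration_slope: Optional[float]
    calibration_se: Optional[float]
    calibration_intercept: Optional[float]
    n_ccg: int
    flags: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    national: list[NationalRow]
    ccg: Optional[CcgMetrics]
    band_counts: Optional[dict]
    n_ccg_included: int
    exclusions: list[dict]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "national": [vars(r) for r in self.national],
            "ccg_level": None if self.ccg is None else vars(self.ccg),
            "band_counts": self.band_counts,
            "n_ccg_included": self.n_ccg_included,
            "exclusions": self.exclusions,
            "metadata": self.metadata,
        }


def national_comparison(pairs: Iterable[tuple[str, str, float, float]]
                        ) -> list[NationalRow]:
    """Predicted-vs-observed differences for national totals and strata.

    ``pairs`` yields (stratum_type, stratum, predicted, observed).  Percent
    differences are predicted-minus-observed over observed, reported to two
    decimals; absent when the observed total is zero.
    """
    rows = []
    for stype, stratum, pred, obs in pairs:
        diff = pred - obs
        pct = round(diff / obs * 100.0, 2) if obs != 0 else None
        rows.append(NationalRow(stype, stratum, pred, obs, diff, pct))
    return rows


def ccg_metrics(predicted: np.ndarray, observed: np.ndarray) -> CcgMetrics:
    """Correlation, RMSE and weak-calibration slope at commissioning level.

    The calibration slope regresses observed on predicted counts (with
    intercept); slope 1 indicates perfect weak calibration.  Predictions
    with zero variance leave the slope absent and flagged.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed lengths differ")
    if len(predicted) < 3:
        raise ValueError("need at least 3 commissioning areas after exclusions")
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    flags: list[str] = []
    if predicted.std() == 0 or observed.std() == 0:
        flags.append("zero variance; correlation/slope not estimable")
        return CcgMetrics(np.nan, np.nan, rmse, None, None, None,
                          len(predicted), flags)
    r = float(np.corrcoef(predicted, observed)[0, 1])
    ols = sm.OLS(observed, sm.add_constant(predicted)).fit()
    return CcgMetrics(r, r * r, rmse, float(ols.params[1]),
                      float(ols.bse[1]), float(ols.params[0]),
                      len(predicted), flags)


def band_rate_differences(predicted: np.ndarray, observed: np.ndarray,
                          person_years: np.ndarray,
                          bands: tuple[float, ...] = (10.0, 20.0)) -> dict:
    """Banded observed-minus-predicted rate differences per 100 000 p-y.

    Bands are closed and cumulative: an area within +/-10 also counts
    within +/-20.
    """
    person_years = np.asarray(person_years, dtype=float)
    if np.any(person_years <= 0):
        raise ValueError("person-years must be positive for every included area")
    d = (np.asarray(observed, float) - np.asarray(predicted, float)) \
        / person_years * 100_000.0
    n = len(d)
    out = {"n_ccg": n, "bands": []}
    for b in bands:
        k = int((np.abs(d) <= b).sum())
        out["bands"].append({"band": b, "within": k,
                             "percent": round(k / n * 100.0, 1)})
    beyond = int((np.abs(d) > max(bands)).sum())
    out["beyond"] = beyond
    out["beyond_percent"] = round(beyond / n * 100.0, 1)
    return out


def _allocate(unknown: int, probs: np.ndarray, mode: str,
              rng: np.random.Generator) -> np.ndarray:
    if mode == "proportional":
        quotas = unknown * probs
        floors = np.floor(quotas).astype(int)
        rem = unknown - floors.sum()
        order = np.argsort(-(quotas - floors), kind="stable")
        floors[order[:rem]] += 1
        return floors
    elif mode == "multinomial":
        return rng.multinomial(unknown, probs)
    raise ValueError(f"unknown imputation mode {mode!r}")


def impute_missing_ethnicity(table: pd.DataFrame, mode: str = "proportional",
                             rng_seed: int = 0,
                             granularity: str = "ccg") -> pd.DataFrame:
    """Allocate unknown-ethnicity counts to ethnic groups.

    ``table`` has columns ccg_id, age_band, gender, ethnicity, count, with
    unknowns under ethnicity == 'unknown'.  Proportional mode allocates to
    the within-area known ethnic distribution with largest-remainder
    rounding (deterministic, exactly conserving totals); multinomial mode
    samples the allocation.  Areas with no known-ethnicity cases fall back
    to the national distribution (logged).
    """
    rng = np.random.default_rng(rng_seed)
    known = table[table["ethnicity"] != "unknown"]
    unknown = table[table["ethnicity"] == "unknown"]
    if unknown.empty:
        return table.copy()
    groups = sorted(known["ethnicity"].unique())
    if not groups:
        raise ValueError("no known-ethnicity cases anywhere; cannot impute")
    national = known.groupby("ethnicity")["count"].sum().reindex(
        groups, fill_value=0).to_numpy(dtype=float)
    national_p = national / national.sum()
    add_rows = []
    for ccg_id, u in unknown.groupby("ccg_id"):
        if granularity == "ccg":
            k = known[known["ccg_id"] == ccg_id]
            dist = k.groupby("ethnicity")["count"].sum().reindex(
                groups, fill_value=0).to_numpy(dtype=float)
        else:
            dist = national.copy()
        if dist.sum() == 0:
            logger.info("ccg %s has no known-ethnicity cases; using national "
                        "distribution", ccg_id)
            p = national_p
        else:
            p = dist / dist.sum()
        for _, row in u.iterrows():
            alloc = _allocate(int(row["count"]), p, mode, rng)
            for g, a in zip(groups, alloc):
                if a > 0:
                    add_rows.append({"ccg_id": ccg_id,
                                     "age_band": row["age_band"],
                                     "gender": row["gender"],
                                     "ethnicity": g, "count": int(a)})
    completed = pd.concat([known, pd.DataFrame(add_rows)], ignore_index=True)
    completed = (completed.groupby(["ccg_id", "age_band", "gender",
                                    "ethnicity"], sort=True)["count"]
                 .sum().reset_index())
    assert completed["count"].sum() == table["count"].sum()
    return completed


def exclude_ccgs(records: list[ObservedCascadeRecord],
                 exclusions: dict[str, str] | list[str]
                 ) -> tuple[list[ObservedCascadeRecord], list[dict]]:
    """Filter excluded commissioning areas, keeping an audit trail.

    ``exclusions`` maps ccg_id -> reason (a bare list gets an unspecified
    reason).  Unknown ids raise a warning, not a failure; duplicates apply
    once.
    """
    if not isinstance(exclusions, dict):
        items = [(c, "unspecified") for c in exclusions]
    else:
        items = list(exclusions.items())
    present = {r.ccg_id for r in records}
    audit = []
    seen = set()
    for ccg_id, reason in items:
        if ccg_id in seen:
            warnings.warn(f"duplicate exclusion id {ccg_id!r}; applied once")
            continue
        seen.add(ccg_id)
        if ccg_id not in present:
            warnings.warn(f"exclusion id {ccg_id!r} not found in observed data")
            continue
        audit.append({"ccg_id": ccg_id, "reason": reason})
    excluded_ids = {a["ccg_id"] for a in audit}
    kept = [r for r in records if r.ccg_id not in excluded_ids]
    return kept, audit


def cascade_to_stratum_table(records: list[ObservedCascadeRecord]
                             ) -> pd.DataFrame:
    rows = []
    for r in records:
        t = r.treated_by_stratum.copy()
        t.insert(0, "ccg_id", r.ccg_id)
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def external_validation(pred_ccg: pd.DataFrame,
                        observed: list[ObservedCascadeRecord],
                        exclusions: dict[str, str] | list[str] = (),
                        adjustment: float = 0.14,
                        bands: tuple[float, ...] = (10.0, 20.0),
                        pred_national: Optional[pd.DataFrame] = None,
                        impute: bool = True,
                        impute_mode: str = "proportional",
                        rng_seed: int = 0) -> ValidationReport:
    """Full external validation of age-matched predictions.

    ``pred_ccg`` is a prediction table at commissioning level (columns
    ccg_id, mean_count, person_years), already age-matched to each area's
    served range.  ``pred_national`` optionally carries national stratified
    predictions (columns stratum_type, stratum, mean_count) for the
    stratified national comparison.
    """
    included, audit = exclude_ccgs(observed, exclusions)
    if not included:
        raise ValueError("no commissioning areas left after exclusions")
    obs = pd.DataFrame({
        "ccg_id": [r.ccg_id for r in included],
        "treated": [r.treated for r in included],
        "observed_py": [r.person_years_served for r in included],
    })
    obs["probable"] = [probable_from_treated(t, adjustment)
                       for t in obs["treated"]]
    merged = obs.merge(pred_ccg, on="ccg_id", validate="one_to_one")
    if len(merged) != len(obs):
        missing = sorted(set(obs["ccg_id"]) - set(pred_ccg["ccg_id"]))
        raise ValueError(f"predictions missing for ccgs: {missing[:5]}")

    pairs: list[tuple[str, str, float, float]] = [
        ("total", "16-64", float(merged["mean_count"].sum()),
         float(merged["probable"].sum()))]
    if pred_national is not None:
        stratum_obs = cascade_to_stratum_table(included)
        if impute and (stratum_obs["ethnicity"] == "unknown").any():
            stratum_obs = impute_missing_ethnicity(
                stratum_obs, mode=impute_mode, rng_seed=rng_seed)
        scale = 1.0 - adjustment
        for _, row in pred_national.iterrows():
            stype, stratum = row["stratum_type"], row["stratum"]
            if stype == "gender":
                o = stratum_obs.loc[stratum_obs["gender"] == stratum,
                                    "count"].sum() * scale
            elif stype == "ethnicity":
                o = stratum_obs.loc[stratum_obs["ethnicity"] == stratum,
                                    "count"].sum() * scale
            elif stype == "broad_age":
                from .simulate import served_age_mask
                lo, hi = map(int, stratum.split("-"))
                mask = served_age_mask(stratum_obs["age_band"], lo, hi)
                o = stratum_obs.loc[mask, "count"].sum() * scale
            else:
                continue
            pairs.append((stype, stratum, float(row["mean_count"]),
                          float(round_half_up(o))))
    national = national_comparison(pairs)

    metrics = ccg_metrics(merged["mean_count"].to_numpy(),
                          merged["probable"].to_numpy())
    band = band_rate_differences(merged["mean_count"].to_numpy(),
                                 merged["probable"].to_numpy(),
                                 merged["person_years"].to_numpy(),
                                 bands)
    return ValidationReport(
        national=national, ccg=metrics, band_counts=band,
        n_ccg_included=len(merged), exclusions=audit,
        metadata={"adjustment_fraction": adjustment,
                  "rmse_computed_on": "counts",
                  "calibration_regression": "observed ~ predicted (OLS)"})
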