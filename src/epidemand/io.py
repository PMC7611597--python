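"""CSV readers/writers for all pipeline tables, plus fit archives.

All interchange is plain CSV with documented headers.  Readers validate the
column contract and basic record invariants (non-negative counts, zero
cases wherever exposure is zero) and report dropped/invalid rows by number
rather than silently altering data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SEED_COLUMNS, ObservedCascadeRecord

GEOGRAPHY_COLUMNS = ["area_id", "ccg_id", "served_age_min", "served_age_max"]
CASCADE_COLUMNS = ["ccg_id", "served_age_min", "served_age_max",
                   "person_years_served", "referred", "assessed", "treated",
                   "age_band", "gender", "ethnicity", "treated_count"]


class DataContractError(ValueError):
    """A table does not meet its documented column/record contract."""


def _require_columns(frame: pd.DataFrame, columns: list[str], what: str):
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise DataContractError(
            f"{what}: missing required column(s): {missing}")


def read_strata_table(path: str | Path) -> pd.DataFrame:
    """Read a seed/denominator strata table, enforcing record invariants."""
    frame = pd.read_csv(path)
    _require_columns(frame, SEED_COLUMNS, f"strata table {path}")
    frame["cases"] = frame["cases"].astype(int)
    frame["person_years"] = frame["person_years"].astype(float)
    neg = frame.index[frame["cases"] < 0]
    if len(neg):
        raise DataContractError(
            f"strata table {path}: negative case count at row(s) "
            f"{list(neg[:5])}")
    if (frame["person_years"] < 0).any():
        bad = frame.index[frame["person_years"] < 0]
        raise DataContractError(
            f"strata table {path}: negative person-years at row(s) "
            f"{list(bad[:5])}")
    bad = frame.index[(frame["person_years"] == 0) & (frame["cases"] > 0)]
    if len(bad):
        raise DataContractError(
            f"strata table {path}: cases with zero person-years at row(s) "
            f"{list(bad[:5])}")
    return frame[SEED_COLUMNS]


def write_strata_table(frame: pd.DataFrame, path: str | Path):
    frame[SEED_COLUMNS].to_csv(path, index=False)


def read_projection_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    cols = [c for c in SEED_COLUMNS if c != "cases"]
    _require_columns(frame, cols, f"projection table {path}")
    if (frame["person_years"] < 0).any():
        raise DataContractError(f"projection table {path}: negative person-years")
    return frame


def write_projection_table(frame: pd.DataFrame, path: str | Path):
    cols = [c for c in SEED_COLUMNS if c != "cases"]
    extra = [c for c in ("year",) if c in frame.columns]
    frame[cols + extra].to_csv(path, index=False)


def read_geography(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, GEOGRAPHY_COLUMNS, f"geography lookup {path}")
    dup = frame["area_id"].duplicated()
    if dup.any():
        raise DataContractError(
            f"geography lookup {path}: duplicate area(s) "
            f"{list(frame.loc[dup, 'area_id'][:5])}")
    return frame[GEOGRAPHY_COLUMNS]


def write_geography(frame: pd.DataFrame, path: str | Path):
    frame[GEOGRAPHY_COLUMNS].to_csv(path, index=False)


def write_observed_cascade(records: list[ObservedCascadeRecord],
                           path: str | Path):
    """Long-format cascade table: per-area totals repeated on stratum rows."""
    rows = []
    for r in records:
        strat = r.treated_by_stratum
        if strat.empty:
            strat = pd.DataFrame([{"age_band": "", "gender": "",
                                   "ethnicity": "", "count": 0}])
        for _, s in strat.iterrows():
            rows.append({
                "ccg_id": r.ccg_id, "served_age_min": r.served_age_min,
                "served_age_max": r.served_age_max,
                "person_years_served": r.person_years_served,
                "referred": r.referred, "assessed": r.assessed,
                "treated": r.treated, "age_band": s["age_band"],
                "gender": s["gender"], "ethnicity": s["ethnicity"],
                "treated_count": int(s["count"]),
            })
    pd.DataFrame(rows, columns=CASCADE_COLUMNS).to_csv(path, index=False)


def read_observed_cascade(path: str | Path) -> list[ObservedCascadeRecord]:
    frame = pd.read_csv(path, keep_default_na=False,
                        dtype={"age_band": str, "gender": str,
                               "ethnicity": str})
    _require_columns(frame, CASCADE_COLUMNS, f"observed cascade {path}")
    records = []
    for ccg_id, g in frame.groupby("ccg_id", sort=True):
        head = g.iloc[0]
        strat = g.loc[g["age_band"] != "",
                      ["age_band", "gender", "ethnicity", "treated_count"]]
        strat = strat.rename(columns={"treated_count": "count"})
        records.append(ObservedCascadeRecord(
            ccg_id=str(ccg_id),
            served_age_min=int(head["served_age_min"]),
            served_age_max=int(head["served_age_max"]),
            referred=int(head["referred"]), assessed=int(head["assessed"]),
            treated=int(head["treated"]),
            person_years_served=float(head["person_years_served"]),
            treated_by_stratum=strat.reset_index(drop=True)))
    return records


def write_fit_archive(fit, outdir: str | Path, stem: str = "fit"):
    """Coefficient table CSV + draw matrix CSV + JSON fit report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coef = fit.relative_risks(include_reference=True)
    se = fit.bse()
    mode = pd.DataFrame({"coefficient": fit.columns, "coef": fit.params,
                         "sd": se})
    coef = mode.merge(coef, on="coefficient", how="right")
    coef.to_csv(outdir / f"{stem}_coefficients.csv", index=False)
    draws = pd.DataFrame(fit.draws, columns=fit.columns)
    draws.to_csv(outdir / f"{stem}_draws.csv", index=False)
    report = {
        "model_id": fit.design.spec.model_id,
        "method": fit.method,
        "n_obs": int(len(fit.design.y)),
        "n_params": int(fit.design.n_params),
        "n_draws": int(len(fit.draws)),
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "grad_norm": None if not np.isfinite(fit.grad_norm) else float(fit.grad_norm),
        "dic": float(fit.dic),
        "mean_deviance": float(fit.mean_deviance),
        "deviance_at_mean": float(fit.deviance_at_mean),
        "effective_parameters": float(fit.effective_parameters),
        "dropped_zero_person_year_strata": int(fit.design.n_dropped_zero_py),
    }
    with open(outdir / f"{stem}_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def write_json(obj, path: str | Path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
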