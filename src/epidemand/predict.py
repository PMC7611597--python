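"""Out-of-sample prediction: posterior draws x projected denominators.

Each posterior coefficient draw is applied to the projected person-years of
every stratum, giving a draw cube of expected counts (stratum x draw).
Aggregation to commissioning-area or national level is done *within* each
draw first; means and 2.5%/97.5% quantiles are then taken across draws, so
cross-stratum posterior correlation is preserved and interval bounds refer
to sums, not sums of bounds.  Rates are reported per 100 000 person-years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DesignMatrix, PoissonLaplaceResults
from .simulate import served_age_mask

BROAD_AGE_GROUPS = {"16-64": (16, 64), "16-35": (16, 35), "36-64": (36, 64)}


@dataclass
class DrawCube:
    """Expected-count draws per stratum: ``counts`` has shape (n_strata, S)."""

    strata: pd.DataFrame  # area_id, age_band, gender, ethnicity, person_years
    counts: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.counts.shape[1]


def predict_strata(fit: PoissonLaplaceResults, projections: pd.DataFrame,
                   design: DesignMatrix | None = None) -> DrawCube:
    """Expected counts per stratum per posterior draw.

    ``lambda_js = person_years_j * exp(x_j' beta_s)`` with the projection
    covariates standardised using the seed-data constants stored on the
    design.  Strata with zero person-years yield exactly zero in every draw.
    """
    design = design if design is not None else fit.design
    X, py = design.transform(projections)
    draws = fit.draws
    n, S = X.shape[0], draws.shape[0]
    counts = np.empty((n, S))
    # chunk over draws to bound peak memory at study scale
    step = max(1, min(S, int(2e7 // max(n, 1)) or 1))
    for s0 in range(0, S, step):
        block = np.exp(X @ draws[s0:s0 + step].T)
        block *= py[:, None]
        counts[:, s0:s0 + step] = block
    counts[py <= 0, :] = 0.0
    keys = projections[["area_id", "age_band", "gender", "ethnicity"]].copy()
    keys["person_years"] = py
    return DrawCube(keys.reset_index(drop=True), counts)


def _broad_age_column(age_bands: pd.Series, group: str) -> np.ndarray:
    lo, hi = BROAD_AGE_GROUPS[group]
    return served_age_mask(age_bands, lo, hi)


def _apply_age_filter(cube: DrawCube, geography: pd.DataFrame) -> DrawCube:
    """Drop age bands outside each commissioning area's served range."""
    g = cube.strata.merge(geography, on="area_id", how="left",
                          validate="many_to_one")
    if g["ccg_id"].isna().any():
        orphans = sorted(g.loc[g["ccg_id"].isna(), "area_id"].unique())
        raise ValueError(f"areas missing from geography lookup: {orphans[:5]}")
    keep = np.array([
        lo >= amin and hi <= amax
        for (lo, hi), amin, amax in zip(
            g["age_band"].map(lambda b: tuple(map(int, b.split("-")))),
            g["served_age_min"], g["served_age_max"])
    ])
    if keep.all():
        return cube
    return DrawCube(cube.strata.loc[keep].reset_index(drop=True),
                    cube.counts[keep])


def aggregate_draws(cube: DrawCube, geography: pd.DataFrame | None = None,
                    level: str = "national", by: str | None = None,
                    age_range_filter: bool = False
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sum the draw cube within groups, per draw.

    Returns ``(groups, draws)`` where ``groups`` holds the group keys and
    total person-years and ``draws`` has one row of per-draw summed counts
    per group.  ``level`` is ``national`` | ``ccg`` | ``stratum``;
    ``by`` optionally sub-stratifies by ``gender``, ``broad_age`` or
    ``ethnicity``.  ``age_range_filter`` restricts each commissioning area
    to its served age range before summation.
    """
    if level in ("ccg",) or age_range_filter:
        if geography is None:
            raise ValueError("geography lookup required for ccg level / age filter")
    if age_range_filter:
        cube = _apply_age_filter(cube, geography)
    strata = cube.strata
    keys: list[str] = []
    work = strata.copy()
    if level == "ccg":
        lookup = geography.drop_duplicates("area_id").set_index("area_id")["ccg_id"]
        missing = sorted(set(work["area_id"]) - set(lookup.index))
        if missing:
            raise ValueError(f"areas missing from geography lookup: {missing[:5]}")
        work["ccg_id"] = work["area_id"].map(lookup)
        keys.append("ccg_id")
    elif level == "stratum":
        keys += ["area_id", "age_band", "gender", "ethnicity"]
    elif level != "national":
        raise ValueError(f"unknown aggregation level {level!r}")
    if by is not None:
        if by == "broad_age":
            frames = []
            draw_rows = []
            for grp in BROAD_AGE_GROUPS:
                mask = _broad_age_column(work["age_band"], grp)
                if mask.all():
                    sub = cube
                else:
                    sub = DrawCube(strata.loc[mask].reset_index(drop=True),
                                   cube.counts[mask])
                g, d = aggregate_draws(sub, geography, level=level, by=None)
                g.insert(len(keys), "broad_age", grp)
                frames.append(g)
                draw_rows.append(d)
            return (pd.concat(frames, ignore_index=True),
                    np.vstack(draw_rows))
        elif by in ("gender", "ethnicity"):
            keys.append(by)
        else:
            raise ValueError(f"unknown sub-stratification {by!r}")
    if not keys:
        groups = pd.DataFrame({"person_years": [work["person_years"].sum()]})
        return groups, cube.counts.sum(axis=0, keepdims=True)
    grouped = work.groupby(keys, sort=True)
    index = grouped.indices
    order = list(index)
    draws = np.vstack([cube.counts[index[k]].sum(axis=0) for k in order])
    groups = pd.DataFrame(
        [k if isinstance(k, tuple) else (k,) for k in order], columns=keys)
    groups["person_years"] = [work["person_years"].iloc[index[k]].sum()
                              for k in order]
    return groups, draws


def summarize_draws(groups: pd.DataFrame, draws: np.ndarray,
                    year: int | None = None, model_id: int | None = None
                    ) -> pd.DataFrame:
    """Mean and 2.5%/97.5% quantiles across draws, per group."""
    out = groups.copy()
    out["mean_count"] = draws.mean(axis=1)
    out["lower95"] = np.quantile(draws, 0.025, axis=1)
    out["upper95"] = np.quantile(draws, 0.975, axis=1)
    if year is not None:
        out["year"] = year
    if model_id is not None:
        out["model_id"] = model_id
    return out


def aggregate(cube: DrawCube, geography: pd.DataFrame | None = None,
              level: str = "national", by: str | None = None,
              age_range_filter: bool = False, year: int | None = None,
              model_id: int | None = None) -> pd.DataFrame:
    """Prediction table: group keys, mean_count, lower95, upper95,
    person_years (quantiles of sums, never sums of quantiles)."""
    groups, draws = aggregate_draws(cube, geography, level, by,
                                    age_range_filter)
    return to_rates(summarize_draws(groups, draws, year, model_id))


def to_rates(table: pd.DataFrame, per: float = 100_000.0) -> pd.DataFrame:
    """Attach rates per 100 000 person-years to a prediction table.

    Groups with zero person-years get absent (NaN) rates, never infinities.
    """
    out = table.copy()
    py = out["person_years"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        for src, dst in (("mean_count", "rate"), ("lower95", "rate_lower"),
                         ("upper95", "rate_upper")):
            r = out[src].to_numpy(dtype=float) / py * per
            out[dst] = np.where(py > 0, r, np.nan)
    return out
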