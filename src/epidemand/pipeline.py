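"""End-to-end pipeline: simulate -> fit -> predict -> validate -> forecast.

Every stage draws its randomness from a named seed recorded in the run
manifest, so re-running with the same configuration reproduces identical
outputs; the manifest also records a hash of the configuration and a
checksum per output file.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import io as eio
from .cascade import estimate_ratios, forecast_years, per_treated_summary
from .config import RunConfig
from .model import BayesianPoissonModel, PriorSpec, default_priors, model_registry
from .predict import aggregate, predict_strata
from .simulate import (generate_geography, generate_observed_cascade,
                       generate_projections, generate_seed_dataset)
from .validate import external_validation

logger = logging.getLogger(__name__)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _priors(config: RunConfig) -> PriorSpec:
    priors = default_priors()
    priors.overrides.update({k: tuple(v) for k, v in
                             config.prior_overrides.items()})
    return priors


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "seeds": dict(config.seeds), "stages": [], "outputs": {}}
    scenario = config.scenario

    def done(stage: str, paths: list[Path]):
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][p.name] = _checksum(p)
        logger.info("stage %s complete (%d outputs)", stage, len(paths))

    # ---- simulate --------------------------------------------------------
    stage = "simulate"
    try:
        sim_seed = config.seeds["simulate"]
        seed = generate_seed_dataset(scenario, rng_seed=sim_seed)
        geography = generate_geography(scenario, rng_seed=sim_seed)
        years = sorted(set(config.forecast_years) | {config.validation_year})
        projections = generate_projections(scenario, years, rng_seed=sim_seed)
        # observed service data for the validation year, generated from the
        # scenario's own truth on the validation-year denominators
        truth_frame = projections[config.validation_year].copy()
        from .simulate import expected_rates
        import numpy as np
        lam, _ = expected_rates(scenario, truth_frame)
        rng = np.random.default_rng(
            np.random.SeedSequence([sim_seed, 77]))
        truth_frame["cases"] = rng.poisson(lam)
        observed = generate_observed_cascade(
            truth_frame, geography, scenario, rng_seed=sim_seed)
        paths = []
        p = outdir / "seed_strata.csv"
        eio.write_strata_table(seed.frame, p)
        paths.append(p)
        p = outdir / "geography.csv"
        eio.write_geography(geography, p)
        paths.append(p)
        for y in years:
            p = outdir / f"projections_{y}.csv"
            eio.write_projection_table(projections[y], p)
            paths.append(p)
        p = outdir / "observed_cascade.csv"
        eio.write_observed_cascade(observed, p)
        paths.append(p)
        done(stage, paths)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- fit -------------------------------------------------------------
    stage = "fit"
    try:
        spec = model_registry()[config.model_id]
        model = BayesianPoissonModel.from_dataframe(
            seed.frame, spec, _priors(config))
        fit = model.fit(n_draws=config.n_draws,
                        rng_seed=config.seeds["fit"])
        eio.write_fit_archive(fit, outdir, stem="fit")
        done(stage, [outdir / "fit_coefficients.csv",
                     outdir / "fit_draws.csv", outdir / "fit_report.json"])
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- predict ---------------------------------------------------------
    stage = "predict"
    try:
        vy = config.validation_year
        if config.excluded_areas:
            bad = set(config.excluded_areas)
            for y in list(projections.years):
                f = projections.years[y]
                projections.years[y] = f[~f["area_id"].isin(bad)]
            logger.info("excluded %d areas from prediction denominators",
                        len(bad))
        cube = predict_strata(fit, projections[vy])
        pred_ccg = aggregate(cube, geography, level="ccg",
                             age_range_filter=True, year=vy,
                             model_id=config.model_id)
        p1 = outdir / f"predictions_{vy}_ccg.csv"
        pred_ccg.to_csv(p1, index=False)
        pred_nat = aggregate(cube, geography, level="national",
                             age_range_filter=True, year=vy,
                             model_id=config.model_id)
        p2 = outdir / f"predictions_{vy}_national.csv"
        pred_nat.to_csv(p2, index=False)
        done(stage, [p1, p2])
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- validate --------------------------------------------------------
    stage = "validate"
    try:
        nat_rows = []
        for by, stype in (("gender", "gender"), ("broad_age", "broad_age"),
                          ("ethnicity", "ethnicity")):
            t = aggregate(cube, geography, level="national", by=by,
                          age_range_filter=True)
            key = {"gender": "gender", "broad_age": "broad_age",
                   "ethnicity": "ethnicity"}[by]
            for _, r in t.iterrows():
                nat_rows.append({"stratum_type": stype, "stratum": r[key],
                                 "mean_count": r["mean_count"]})
        report = external_validation(
            pred_ccg, observed, exclusions=list(config.excluded_ccgs),
            adjustment=scenario.probable_adjustment,
            bands=config.band_edges,
            pred_national=pd.DataFrame(nat_rows),
            rng_seed=config.seeds.get("imputation", 0))
        p1 = outdir / "validation_report.json"
        eio.write_json(report.to_dict(), p1)
        obs_df = pd.DataFrame({
            "ccg_id": [r.ccg_id for r in observed],
            "treated": [r.treated for r in observed]})
        from .validate import probable_from_treated
        obs_df["observed"] = obs_df["treated"].map(
            lambda t: probable_from_treated(t, scenario.probable_adjustment))
        calib = pred_ccg.merge(obs_df, on="ccg_id")
        calib["rate_difference"] = ((calib["observed"] - calib["mean_count"])
                                    / calib["person_years"] * 100_000.0)
        lo, hi = config.band_edges
        calib["band"] = pd.cut(calib["rate_difference"].abs(),
                               [0, lo, hi, float("inf")],
                               labels=[f"<= {lo}", f"<= {hi}", f"> {hi}"],
                               include_lowest=True)
        p2 = outdir / "calibration_table.csv"
        calib[["ccg_id", "mean_count", "observed", "person_years",
               "rate_difference", "band"]].rename(
                   columns={"mean_count": "predicted"}).to_csv(p2, index=False)
        done(stage, [p1, p2])
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- forecast --------------------------------------------------------
    stage = "forecast"
    try:
        included = [r for r in observed
                    if r.ccg_id not in set(config.excluded_ccgs)]
        ratios = estimate_ratios(included,
                                 adjustment=scenario.probable_adjustment,
                                 source_year=config.validation_year)
        missing = [y for y in config.forecast_years if y not in projections]
        if missing:
            raise ValueError(f"no projections for forecast year(s) {missing}")
        fc = forecast_years(fit, projections, ratios, config.forecast_years,
                            geography=geography, age_range_filter=False)
        p = outdir / "forecast_summary.csv"
        fc.to_csv(p, index=False)
        manifest["per_treated"] = per_treated_summary(
            fc, config.forecast_years[-1])
        done(stage, [p])
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    eio.write_json(manifest, outdir / "manifest.json")
    return manifest
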