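"""Bayesian Poisson incidence regression with a person-years offset.

The incidence model treats the case count in each small-area x age x gender
x ethnicity stratum as Poisson with mean

    mu_j = person_years_j * exp(x_j' beta),

i.e. log person-years enters as an offset so the coefficients act on rates.
Individual-level terms (age band, gender, their interaction, ethnic group,
treatment-coded) appear in every candidate model; candidate models differ in
which area-level covariates (deprivation, population density, social
fragmentation, regional cannabis prevalence) they include.

Inference is Bayesian with independent Gaussian priors on the log-relative-
risk scale.  The posterior is approximated by a Gaussian (Laplace)
approximation at the posterior mode: the mode is found by Newton iteration,
the curvature is the analytic negative Hessian of the log-posterior, and
joint uncertainty is carried forward by sampling coefficient vectors from
the resulting multivariate Gaussian, preserving cross-parameter posterior
correlation.  An adaptive random-walk Metropolis sampler on the identical
log-posterior serves as an independent cross-check of the approximation.

Model adequacy is summarised by the deviance information criterion
(DIC = mean posterior deviance + effective number of parameters) and a
Pearson overdispersion statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import gammaln

logger = logging.getLogger(__name__)

AREA_TERM_NAMES = (
    "deprivation", "population_density", "social_fragmentation",
    "cannabis_prevalence", "ethnic_density", "inequality",
)

_DEFAULT_REFERENCES = {
    "age_band": "16-17", "gender": "female", "ethnicity": "white_british",
}


class FitError(RuntimeError):
    """Raised when a posterior fit cannot be completed."""


# --------------------------------------------------------------------------
# Model specification and priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: fixed individual-level terms plus a choice of
    area-level covariates and a functional form for deprivation."""

    model_id: int
    area_terms: tuple[str, ...] = ()
    deprivation_form: str = "quadratic"  # linear | quadratic | decile
    reference_levels: dict = field(
        default_factory=lambda: dict(_DEFAULT_REFERENCES))

    def __post_init__(self):
        unknown = set(self.area_terms) - set(AREA_TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown area term(s): {sorted(unknown)}")
        if self.deprivation_form not in ("linear", "quadratic", "decile"):
            raise ValueError(
                f"deprivation_form must be linear|quadratic|decile, "
                f"got {self.deprivation_form!r}")


def model_registry(deprivation_form: str = "quadratic") -> dict[int, ModelSpec]:
    """The six candidate models.

    Model 1 uses individual-level terms only; models 2-6 add area-level
    covariates.  Model 4 (deprivation + social fragmentation + cannabis)
    is the default forecasting model.
    """
    d = deprivation_form
    return {
        1: ModelSpec(1, (), d),
        2: ModelSpec(2, ("deprivation",), d),
        3: ModelSpec(3, ("deprivation", "cannabis_prevalence"), d),
        4: ModelSpec(4, ("deprivation", "social_fragmentation",
                         "cannabis_prevalence"), d),
        5: ModelSpec(5, ("deprivation", "social_fragmentation",
                         "cannabis_prevalence", "population_density"), d),
        6: ModelSpec(6, ("deprivation", "population_density"), d),
    }


@dataclass
class PriorSpec:
    """Independent Gaussian priors on the log-relative-risk scale.

    Every coefficient defaults to N(default_mean, default_sd^2); named
    overrides replace individual (mean, sd) pairs.  The intercept is a
    baseline log-rate rather than a log-relative-risk, so it carries a
    diffuse prior by default.
    """

    default_mean: float = 0.0
    default_sd: float = 1.0
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    intercept_sd: float = 10.0

    def __post_init__(self):
        if self.default_sd <= 0 or self.intercept_sd <= 0:
            raise ValueError("prior standard deviations must be > 0")
        for name, (_, sd) in self.overrides.items():
            if sd <= 0:
                raise ValueError(f"prior sd for {name!r} must be > 0")

    def for_columns(self, columns: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        means = np.full(len(columns), self.default_mean, dtype=float)
        sds = np.full(len(columns), self.default_sd, dtype=float)
        for i, c in enumerate(columns):
            if c == "intercept":
                means[i], sds[i] = 0.0, self.intercept_sd
            if c in self.overrides:
                means[i], sds[i] = self.overrides[c]
        return means, sds


def default_priors() -> PriorSpec:
    """Weakly-informative N(0,1) log-RR priors, with an informative prior
    on the cannabis-prevalence effect (centred at log 1.4, sd 0.15) carrying
    the published epidemiological evidence on cannabis use and psychosis."""
    return PriorSpec(overrides={"cannabis_prevalence": (np.log(1.4), 0.15)})


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Treatment-coded design for one candidate model.

    Continuous area covariates are stored z-scored; the standardisation
    constants are computed over unique areas (the sampling unit of area
    covariates) and retained so projection data can be transformed with the
    seed-data constants rather than re-standardised.
    """

    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    person_years: np.ndarray
    columns: list[str]
    factor_levels: dict[str, list[str]]
    standardization: dict[str, tuple[float, float]]
    spec: ModelSpec
    n_dropped_zero_py: int
    decile_edges: Optional[np.ndarray] = None
    row_index: Optional[pd.Index] = None

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def transform(self, frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Encode new strata (e.g. projected denominators) with the stored
        coding and standardisation constants.

        Returns ``(X, person_years)`` with one row per input row; rows with
        zero person-years are retained (their predicted counts are zero).
        """
        X = _encode(frame, self.spec, self.factor_levels,
                    self.standardization, self.decile_edges)
        py = frame["person_years"].to_numpy(dtype=float)
        return X, py


def _area_level_values(frame: pd.DataFrame, col: str) -> np.ndarray:
    if col not in frame.columns:
        raise ValueError(f"missing covariate column: {col!r}")
    return frame.groupby("area_id", sort=True)[col].first().to_numpy(dtype=float)


def _check_levels(frame: pd.DataFrame, factor_levels: dict[str, list[str]]):
    for factor, levels in factor_levels.items():
        seen = set(frame[factor].unique())
        unseen = seen - set(levels)
        if unseen:
            raise ValueError(
                f"unseen {factor} level(s): {sorted(unseen)}; "
                f"known levels: {levels}")


def _encode(frame: pd.DataFrame, spec: ModelSpec,
            factor_levels: dict[str, list[str]],
            standardization: dict[str, tuple[float, float]],
            decile_edges: Optional[np.ndarray]) -> np.ndarray:
    _check_levels(frame, factor_levels)
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    age = frame["age_band"].to_numpy()
    gen = frame["gender"].to_numpy()
    eth = frame["ethnicity"].to_numpy()
    age_nonref = factor_levels["age_band"][1:]
    gen_nonref = factor_levels["gender"][1:]
    eth_nonref = factor_levels["ethnicity"][1:]
    age_d = {a: (age == a).astype(float) for a in age_nonref}
    gen_d = {g: (gen == g).astype(float) for g in gen_nonref}
    for a in age_nonref:
        cols.append(age_d[a])
    for g in gen_nonref:
        cols.append(gen_d[g])
    for a in age_nonref:
        for g in gen_nonref:
            cols.append(age_d[a] * gen_d[g])
    for e in eth_nonref:
        cols.append((eth == e).astype(float))
    for term in spec.area_terms:
        if term not in frame.columns:
            raise ValueError(f"missing covariate column: {term!r}")
        m, s = standardization[term]
        z = (frame[term].to_numpy(dtype=float) - m) / s
        if term == "deprivation":
            if spec.deprivation_form == "linear":
                cols.append(z)
            elif spec.deprivation_form == "quadratic":
                cols.append(z)
                cols.append(z * z)
            else:  # decile categories from area-level seed deciles
                idx = np.clip(np.searchsorted(decile_edges, z, side="right"),
                              0, 9)
                for d in range(1, 10):
                    cols.append((idx == d).astype(float))
        else:
            cols.append(z)
    return np.column_stack(cols)


def _column_names(spec: ModelSpec, factor_levels: dict[str, list[str]]) -> list[str]:
    names = ["intercept"]
    age_nonref = factor_levels["age_band"][1:]
    gen_nonref = factor_levels["gender"][1:]
    names += [f"age[{a}]" for a in age_nonref]
    names += [f"gender[{g}]" for g in gen_nonref]
    names += [f"age[{a}]:gender[{g}]" for a in age_nonref for g in gen_nonref]
    names += [f"eth[{e}]" for e in factor_levels["ethnicity"][1:]]
    for term in spec.area_terms:
        if term == "deprivation":
            if spec.deprivation_form == "linear":
                names.append("deprivation")
            elif spec.deprivation_form == "quadratic":
                names += ["deprivation", "deprivation_sq"]
            else:
                names += [f"deprivation_decile[{d + 1}]" for d in range(1, 10)]
        else:
            names.append(term)
    return names


def build_design(seed: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Build the treatment-coded design matrix for ``spec`` from seed strata.

    Strata with zero person-years are excluded (the log-offset is undefined
    there) and their number logged.  Raises on unseen factor levels, missing
    covariate columns, or when every stratum has zero exposure.
    """
    if len(seed) == 0:
        raise ValueError("seed data-set is empty")
    py = seed["person_years"].to_numpy(dtype=float)
    keep = py > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d strata with zero person-years", n_dropped)
    if not keep.any():
        raise ValueError("all strata have zero person-years")
    frame = seed.loc[keep]

    factor_levels: dict[str, list[str]] = {}
    for factor in ("age_band", "gender", "ethnicity"):
        levels = sorted(frame[factor].unique())
        ref = spec.reference_levels.get(factor, levels[0])
        if ref not in levels:
            raise ValueError(
                f"reference level {ref!r} for {factor} not present in data")
        factor_levels[factor] = [ref] + [l for l in levels if l != ref]

    standardization: dict[str, tuple[float, float]] = {}
    decile_edges = None
    for term in spec.area_terms:
        vals = _area_level_values(frame, term)
        sd = float(vals.std(ddof=0))
        if sd == 0:
            raise ValueError(f"area covariate {term!r} is constant; not estimable")
        standardization[term] = (float(vals.mean()), sd)
    if "deprivation" in spec.area_terms and spec.deprivation_form == "decile":
        m, s = standardization["deprivation"]
        z = (_area_level_values(frame, "deprivation") - m) / s
        decile_edges = np.quantile(z, np.linspace(0.1, 0.9, 9))

    X = _encode(frame, spec, factor_levels, standardization, decile_edges)
    columns = _column_names(spec, factor_levels)
    assert X.shape[1] == len(columns)
    return DesignMatrix(
        X=X,
        y=frame["cases"].to_numpy(dtype=float),
        offset=np.log(frame["person_years"].to_numpy(dtype=float)),
        person_years=frame["person_years"].to_numpy(dtype=float),
        columns=columns,
        factor_levels=factor_levels,
        standardization=standardization,
        spec=spec,
        n_dropped_zero_py=n_dropped,
        decile_edges=decile_edges,
        row_index=frame.index,
    )


# --------------------------------------------------------------------------
# Deviance helpers
# --------------------------------------------------------------------------

def poisson_loglike(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
                    offset: np.ndarray) -> float:
    eta = X @ beta + offset
    return float(y @ eta - np.exp(eta).sum() - gammaln(y + 1).sum())


def deviance(beta: np.ndarray, design: DesignMatrix) -> float:
    """D(beta) = -2 * Poisson log-likelihood."""
    return -2.0 * poisson_loglike(beta, design.X, design.y, design.offset)


def compute_dic(fit: "PoissonLaplaceResults", design: DesignMatrix) -> float:
    """Deviance information criterion from posterior draws.

    DIC = Dbar + pD where Dbar is the posterior mean deviance and
    pD = Dbar - D(beta_bar) the effective number of parameters; the
    components are stored on the fit.
    """
    draws = fit.draws
    if draws is None or draws.shape[0] < 100:
        raise ValueError("DIC requires at least 100 posterior draws")
    dbar = float(np.mean([deviance(b, design) for b in draws]))
    dhat = deviance(draws.mean(axis=0), design)
    pd_ = dbar - dhat
    fit.mean_deviance = dbar
    fit.deviance_at_mean = dhat
    fit.effective_parameters = pd_
    fit.dic = dbar + pd_
    return fit.dic


# --------------------------------------------------------------------------
# Results objects
# --------------------------------------------------------------------------

class PoissonLaplaceResults:
    """Posterior fit of one candidate model.

    Carries the posterior mode, the curvature (negative Hessian of the
    log-posterior at the mode), S joint posterior draws, and deviance
    summaries.  ``relative_risks`` and ``summary`` present the fit on the
    relative-risk scale.
    """

    def __init__(self, model: "BayesianPoissonModel", params: np.ndarray,
                 curvature: np.ndarray, draws: np.ndarray,
                 converged: bool, n_iter: int, grad_norm: float,
                 rng_seed: Optional[int] = None):
        self.model = model
        self.design = model.design
        self.params = params
        self.curvature = curvature
        self.draws = draws
        self.converged = converged
        self.n_iter = n_iter
        self.grad_norm = grad_norm
        self.rng_seed = rng_seed
        self.dic: float = np.nan
        self.mean_deviance: float = np.nan
        self.deviance_at_mean: float = np.nan
        self.effective_parameters: float = np.nan
        self.method = "laplace"

    @property
    def columns(self) -> list[str]:
        return self.design.columns

    def cov_params(self) -> np.ndarray:
        c, low = cho_factor(self.curvature)
        return cho_solve((c, low), np.eye(len(self.params)))

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params()))

    def fittedvalues(self) -> np.ndarray:
        """Expected counts at the posterior mode."""
        return np.exp(self.design.X @ self.params + self.design.offset)

    def relative_risks(self, include_reference: bool = False) -> pd.DataFrame:
        """Posterior relative risks with 95% credible intervals.

        RR is the posterior median of exp(beta); the interval spans the
        2.5% and 97.5% draw quantiles.  With ``include_reference`` the
        reference category of each factor is listed with RR 1 by
        convention.
        """
        if self.draws is None or len(self.draws) == 0:
            raise ValueError("no posterior draws available")
        rr = np.exp(self.draws)
        med = np.median(rr, axis=0)
        lo, hi = np.quantile(rr, [0.025, 0.975], axis=0)
        mean = rr.mean(axis=0)
        rows = []
        if include_reference:
            fl = self.design.factor_levels
            for factor, prefix in (("age_band", "age"), ("gender", "gender"),
                                   ("ethnicity", "eth")):
                rows.append({"coefficient": f"{prefix}[{fl[factor][0]}]",
                             "rr": 1.0, "rr_mean": 1.0,
                             "rr_lower": 1.0, "rr_upper": 1.0,
                             "reference": True})
        for i, c in enumerate(self.columns):
            rows.append({"coefficient": c, "rr": med[i], "rr_mean": mean[i],
                         "rr_lower": lo[i], "rr_upper": hi[i],
                         "reference": False})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        se = self.bse()
        lines = [
            "Bayesian Poisson incidence model (Laplace approximation)",
            "=" * 72,
            f"Model id: {self.design.spec.model_id}    "
            f"Observations: {len(self.design.y)}    "
            f"Parameters: {self.design.n_params}",
            f"Converged: {self.converged} (iter {self.n_iter}, "
            f"|grad| {self.grad_norm:.2e})    Draws: "
            f"{0 if self.draws is None else len(self.draws)}",
            f"DIC: {self.dic:.2f}  (Dbar {self.mean_deviance:.2f}, "
            f"pD {self.effective_parameters:.2f})",
            "-" * 72,
            f"{'coefficient':<32}{'coef':>9}{'sd':>8}{'RR':>8}"
            f"{'[2.5%':>9}{'97.5%]':>9}",
            "-" * 72,
        ]
        rrtab = self.relative_risks()
        for i, c in enumerate(self.columns):
            r = rrtab.iloc[i]
            lines.append(
                f"{c:<32}{self.params[i]:>9.4f}{se[i]:>8.4f}"
                f"{r['rr']:>8.3f}{r['rr_lower']:>9.3f}{r['rr_upper']:>9.3f}")
        lines.append("=" * 72)
        return "\n".join(lines)


class MetropolisResults(PoissonLaplaceResults):
    """Posterior draws from the adaptive random-walk Metropolis oracle."""

    def __init__(self, *args, rhat: float = np.nan, accept_rate: float = np.nan,
                 usable: bool = True, **kwargs):
        super().__init__(*args, **kwargs)
        self.rhat = rhat
        self.accept_rate = accept_rate
        self.usable = usable
        self.method = "metropolis"


# --------------------------------------------------------------------------
# The model object
# --------------------------------------------------------------------------

class BayesianPoissonModel:
    """Poisson incidence model with Gaussian log-RR priors.

    Parameters
    ----------
    design : DesignMatrix
        Built with :func:`build_design`.
    priors : PriorSpec, optional
        Defaults to :func:`default_priors`.
    """

    def __init__(self, design: DesignMatrix, priors: Optional[PriorSpec] = None):
        self.design = design
        self.priors = priors if priors is not None else default_priors()
        self.prior_mean, prior_sd = self.priors.for_columns(design.columns)
        self.prior_precision = 1.0 / prior_sd ** 2

    @classmethod
    def from_dataframe(cls, seed: pd.DataFrame,
                       spec: Optional[ModelSpec] = None,
                       priors: Optional[PriorSpec] = None,
                       ) -> "BayesianPoissonModel":
        if spec is None:
            spec = model_registry()[4]
        return cls(build_design(seed, spec), priors)

    # ---- log-posterior pieces -------------------------------------------
    def logpost(self, beta: np.ndarray) -> float:
        d = beta - self.prior_mean
        return (poisson_loglike(beta, self.design.X, self.design.y,
                                self.design.offset)
                - 0.5 * float(d @ (self.prior_precision * d)))

    def score(self, beta: np.ndarray) -> np.ndarray:
        mu = np.exp(self.design.X @ beta + self.design.offset)
        return (self.design.X.T @ (self.design.y - mu)
                - self.prior_precision * (beta - self.prior_mean))

    def neg_hessian(self, beta: np.ndarray) -> np.ndarray:
        mu = np.exp(self.design.X @ beta + self.design.offset)
        return ((self.design.X.T * mu) @ self.design.X
                + np.diag(self.prior_precision))

    # ---- fitting ---------------------------------------------------------
    def fit(self, n_draws: int = 1000, rng_seed: int = 0,
            tol: float = 1e-8, maxiter: int = 100,
            compute_dic_: bool = True) -> PoissonLaplaceResults:
        """Laplace fit: Newton to the posterior mode, Gaussian draws from
        the mode/curvature, deviance summaries.

        Raises :class:`FitError` on non-convergence (reporting the gradient
        norm) or on a singular curvature (naming near-collinear columns).
        """
        X, y, off = self.design.X, self.design.y, self.design.offset
        beta = np.zeros(self.design.n_params)
        total_py = self.design.person_years.sum()
        beta[0] = np.log(max(y.sum(), 0.5) / total_py)
        lp = self.logpost(beta)
        converged = False
        it = 0
        gnorm = np.inf
        for it in range(1, maxiter + 1):
            g = self.score(beta)
            gnorm = float(np.linalg.norm(g))
            if gnorm < tol:
                converged = True
                break
            H = self.neg_hessian(beta)
            step = self._solve_ridge(H, g)
            # step halving keeps the iteration monotone
            t = 1.0
            for _ in range(40):
                cand = beta + t * step
                lp_c = self.logpost(cand)
                if np.isfinite(lp_c) and lp_c >= lp - 1e-12:
                    beta, lp = cand, lp_c
                    break
                t *= 0.5
            else:
                break
        if not converged:
            g = self.score(beta)
            gnorm = float(np.linalg.norm(g))
            converged = gnorm < tol
        if not converged:
            raise FitError(
                f"Newton iteration did not converge in {it} iterations; "
                f"gradient norm {gnorm:.3e}")
        H = self.neg_hessian(beta)
        draws = self._sample(beta, H, n_draws, rng_seed)
        res = PoissonLaplaceResults(self, beta, H, draws, converged, it,
                                    gnorm, rng_seed)
        if compute_dic_ and n_draws >= 100:
            compute_dic(res, self.design)
        return res

    def _solve_ridge(self, H: np.ndarray, g: np.ndarray) -> np.ndarray:
        w = np.linalg.eigvalsh(H)
        if w[0] <= 0 or w[0] < 1e-12 * w[-1]:
            self._diagnose_collinear(H)
            logger.warning("near-singular curvature; adding ridge 1e-8")
            H = H + 1e-8 * np.eye(len(g))
        c, low = cho_factor(H)
        return cho_solve((c, low), g)

    def _diagnose_collinear(self, H: np.ndarray):
        d = np.sqrt(np.diag(H))
        corr = H / np.outer(d, d)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        cols = self.design.columns
        if abs(corr[i, j]) > 0.999:
            raise FitError(
                f"singular curvature: columns {cols[i]!r} and {cols[j]!r} "
                "are (nearly) collinear")

    def _sample(self, mode: np.ndarray, H: np.ndarray, n_draws: int,
                rng_seed: int) -> np.ndarray:
        rng = np.random.default_rng(rng_seed)
        L = np.linalg.cholesky(H)
        z = rng.standard_normal((n_draws, len(mode)))
        # H = L L', covariance H^-1 = L'^-1 L^-1; draws = mode + L'^-1 z
        return mode + solve_triangular(L.T, z.T, lower=False).T

    def fit_mcmc(self, n_draws: int = 1000, n_chains: int = 4,
                 burn: int = 1000, thin: int = 1, rng_seed: int = 0,
                 rhat_threshold: float = 1.05) -> MetropolisResults:
        """Adaptive random-walk Metropolis on the same log-posterior.

        Proposal covariance is the Laplace curvature inverse scaled by
        2.38^2/p, with a global scale adapted during burn-in toward a
        0.234 acceptance rate.  Split-chain scale reduction (R-hat) above
        ``rhat_threshold`` flags the result as unusable.
        """
        if n_draws <= 0 or n_chains <= 0:
            raise ValueError("n_draws and n_chains must be positive")
        base = self.fit(n_draws=0, rng_seed=rng_seed, compute_dic_=False)
        p = self.design.n_params
        cov = base.cov_params() * (2.38 ** 2 / p)
        Lp = np.linalg.cholesky(cov)
        per_chain = int(np.ceil(n_draws / n_chains)) * thin
        ss = np.random.SeedSequence(rng_seed)
        chains = []
        accepts = []
        for cs in ss.spawn(n_chains):
            rng = np.random.default_rng(cs)
            beta = base.params + Lp @ rng.standard_normal(p)
            lp = self.logpost(beta)
            log_scale = 0.0
            out = np.empty((per_chain, p))
            n_acc = 0
            for t in range(burn + per_chain):
                prop = beta + np.exp(log_scale) * (Lp @ rng.standard_normal(p))
                lp_p = self.logpost(prop)
                if np.log(rng.uniform()) < lp_p - lp:
                    beta, lp = prop, lp_p
                    acc = 1.0
                else:
                    acc = 0.0
                if t < burn:
                    log_scale += (acc - 0.234) / np.sqrt(t + 1.0)
                else:
                    out[t - burn] = beta
                    n_acc += acc
            chains.append(out[::thin])
            accepts.append(n_acc / per_chain)
        rhat = float(np.max([_split_rhat(np.stack([c[:, k] for c in chains]))
                             for k in range(p)]))
        draws = np.concatenate(chains)[:n_draws]
        usable = rhat < rhat_threshold
        if not usable:
            warnings.warn(f"Metropolis chains not converged: max R-hat {rhat:.3f}")
        mean = draws.mean(axis=0)
        res = MetropolisResults(self, mean, base.curvature, draws, True, 0,
                                np.nan, rng_seed, rhat=rhat,
                                accept_rate=float(np.mean(accepts)),
                                usable=usable)
        if len(draws) >= 100:
            compute_dic(res, self.design)
        return res


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar parameter.

    ``chains`` has shape (n_chains, n_iter); each chain is split in half.
    """
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    if w == 0:
        return 1.0
    return float(np.sqrt(var_plus / w))


# --------------------------------------------------------------------------
# Covariate screening and overdispersion
# --------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    covariate: str
    rr: float
    rr_lower: float
    rr_upper: float
    keep: bool


def screen_covariate(seed: pd.DataFrame, base_spec: ModelSpec,
                     candidate: str, priors: Optional[PriorSpec] = None,
                     n_draws: int = 1000, rng_seed: int = 0) -> ScreeningResult:
    """Screen one area-level covariate by adding it to the base model.

    The covariate is dropped when its 95% credible interval on the RR scale
    contains 1 (no association detectable in the seed data).  A covariate
    constant across areas is rejected as not estimable.
    """
    if candidate in base_spec.area_terms:
        raise ValueError(f"{candidate!r} already in base model")
    spec = ModelSpec(base_spec.model_id,
                     base_spec.area_terms + (candidate,),
                     base_spec.deprivation_form, base_spec.reference_levels)
    model = BayesianPoissonModel.from_dataframe(seed, spec, priors)
    res = model.fit(n_draws=n_draws, rng_seed=rng_seed, compute_dic_=False)
    i = res.columns.index(candidate)
    rr = np.exp(res.draws[:, i])
    lo, hi = float(np.quantile(rr, 0.025)), float(np.quantile(rr, 0.975))
    keep = not (lo <= 1.0 <= hi)
    return ScreeningResult(candidate, float(np.median(rr)), lo, hi, keep)


@dataclass
class DispersionResult:
    statistic: float
    verdict: str
    threshold: float
    n_excluded_zero_fit: int
    poisson_dic: float
    nb_loglike: Optional[float] = None
    nb_alpha: Optional[float] = None
    poisson_mle_loglike: Optional[float] = None


def overdispersion_check(seed: pd.DataFrame, spec: ModelSpec,
                         priors: Optional[PriorSpec] = None,
                         threshold: float = 1.5, rng_seed: int = 0,
                         compare_nb: bool = True) -> DispersionResult:
    """Pearson dispersion check of the fitted Poisson model.

    Dispersion = sum((obs - fit)^2 / fit) / residual d.f.; values well above
    1 indicate variance beyond Poisson.  Optionally compares against a
    negative-binomial maximum-likelihood fit of the same design.
    """
    model = BayesianPoissonModel.from_dataframe(seed, spec, priors)
    res = model.fit(n_draws=200, rng_seed=rng_seed)
    mu = res.fittedvalues()
    y = model.design.y
    ok = mu > 0
    n_excl = int((~ok).sum())
    if n_excl:
        logger.info("excluded %d cells with zero fitted value", n_excl)
    df_resid = ok.sum() - model.design.n_params
    stat = float(((y[ok] - mu[ok]) ** 2 / mu[ok]).sum() / df_resid)
    verdict = "overdispersed" if stat > threshold else "no overdispersion"
    nb_ll = nb_alpha = pois_ll = None
    if compare_nb:
        import statsmodels.api as sm
        X = model.design.X
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(y, X, family=sm.families.Poisson(),
                          offset=model.design.offset).fit()
            pois_ll = float(pois.llf)
            try:
                nb = sm.NegativeBinomial(
                    y, X, exposure=model.design.person_years).fit(
                        disp=False, maxiter=200)
                nb_ll = float(nb.llf)
                nb_alpha = float(nb.params[-1])
            except Exception as exc:  # NB fit can fail on equidispersed data
                logger.info("negative-binomial comparison fit failed: %s", exc)
    return DispersionResult(stat, verdict, threshold, n_excl, res.dic,
                            nb_ll, nb_alpha, pois_ll)
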