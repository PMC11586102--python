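"""GLM/GLMM inference on the nightly activity metrics.

Two analysis families are supported, mirroring common practice for
activity-budget data:

* **reproductive condition** (single-site, single-season): one GLM per
  metric with condition as the only fixed effect — Poisson for return
  counts, gamma with inverse link for the duration metrics and emergence
  clock time — tested against the null by likelihood-ratio, with
  Tukey-style pairwise contrasts among conditions;
* **sex and environment** (multi-season): a deterministic set of 16 a
  priori additive/interactive candidate models per metric over sex, food
  season, temperature and precipitation, with crossed random intercepts
  for bat identity and year, ranked by AIC.

Family/link pairs are restricted to the combinations used for these data:
poisson+log, negative_binomial+log, gamma+inverse, gamma+log,
gaussian+identity.

Mixed models: gaussian responses use a linear mixed model with crossed
random intercepts (maximum likelihood, so AICs are comparable). For the
non-gaussian families no Laplace-approximate crossed GLMM is available in
the underlying libraries; the documented fallback fits the GLM with
cluster-robust (bat) standard errors and records ``fallback`` in the fit
metadata. Point estimates of fixed effects are unchanged by the fallback;
only their uncertainty accounting differs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

ALLOWED_FAMILY_LINKS = {
    ("poisson", "log"),
    ("negative_binomial", "log"),
    ("gamma", "inverse"),
    ("gamma", "log"),
    ("gaussian", "identity"),
}

DEFAULT_RANDOM_TERMS = ("bat_id", "year")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description: response, family/link, terms."""

    response: str
    family: str
    link: str
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.family, self.link) not in ALLOWED_FAMILY_LINKS:
            raise ValueError(
                f"unsupported family/link pair ({self.family}, {self.link}); "
                f"allowed: {sorted(ALLOWED_FAMILY_LINKS)}"
            )

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"{self.response} ~ {rhs}"

    def describe(self) -> str:
        tail = f" | ({' + '.join(self.random_terms)})" if self.random_terms else ""
        return f"{self.formula}{tail} [{self.family}/{self.link}]"


@dataclass
class ModelFit:
    """A fitted model with everything downstream inference needs."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    conf_int: pd.DataFrame
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    dispersion: float | None
    converged: bool
    fallback: str | None = None
    random_effect_sd: dict[str, float] | None = None
    result: object = field(default=None, repr=False)
    data: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class LrtResult:
    chi2: float
    df: int
    p_value: float


@dataclass
class ContrastResult:
    level_pair: tuple[str, str]
    estimate_response_scale: float
    ci_low: float
    ci_high: float
    p_adjusted: float
    p_unadjusted: float
    adjustment: str
    estimate_link_scale: float
    se_link_scale: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate_response_scale <= self.ci_high:
            raise ValueError("contrast CI must bracket the estimate")


def _statsmodels_family(spec: ModelSpec):
    links = sm.families.links
    if spec.family == "poisson":
        return sm.families.Poisson(links.Log())
    if spec.family == "gamma":
        link = links.InversePower() if spec.link == "inverse" else links.Log()
        return sm.families.Gamma(link)
    if spec.family == "gaussian":
        return sm.families.Gaussian(links.Identity())
    raise ValueError(f"no GLM family for {spec.family}")


def drop_nonpositive(table: pd.DataFrame, response: str,
                     report: dict | None = None) -> pd.DataFrame:
    """Drop rows with response <= 0 (gamma density is undefined at zero).

    Nights with no return-exit pair have zero hours inside; they cannot
    enter a gamma model and are excluded with a logged count.
    """
    keep = table[response] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%d row(s) with nonpositive %s dropped for gamma fit", n_dropped, response)
    if report is not None:
        report[f"nonpositive_{response}"] = n_dropped
    return table[keep].reset_index(drop=True)


def _validate_response(table: pd.DataFrame, spec: ModelSpec) -> None:
    y = table[spec.response]
    if spec.family == "gamma" and (y <= 0).any():
        raise ValueError(
            f"gamma response {spec.response!r} contains values <= 0; "
            "filter with drop_nonpositive() before fitting"
        )
    if spec.family in {"poisson", "negative_binomial"}:
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError(
                f"{spec.family} response {spec.response!r} must be non-negative integers"
            )


def fit_glm(table: pd.DataFrame, spec: ModelSpec, **fit_kwds) -> ModelFit:
    """Maximum-likelihood GLM fit for a spec without random terms.

    Negative-binomial models use the NB2 mean-dispersion parameterization
    with the dispersion estimated by full ML alongside the mean structure.
    """
    _validate_response(table, spec)
    if spec.family == "negative_binomial":
        model = smf.negativebinomial(spec.formula, data=table)
        res = model.fit(disp=0, maxiter=200, **fit_kwds)
        converged = bool(res.mle_retvals.get("converged", True))
        mean_params = res.params.drop("alpha")
        dispersion = float(res.params["alpha"])
        n_params = len(res.params)
    else:
        model = smf.glm(spec.formula, data=table, family=_statsmodels_family(spec))
        res = model.fit(**fit_kwds)
        converged = bool(getattr(res, "converged", True))
        mean_params = res.params
        dispersion = float(res.scale)
        n_params = len(res.params) + (0 if spec.family in {"poisson"} else 1)
    if not converged:
        logger.warning("fit did not converge: %s", spec.describe())
    aic = 2.0 * n_params - 2.0 * float(res.llf)
    ci = res.conf_int()
    ci.columns = ["ci_low", "ci_high"]
    return ModelFit(
        spec=spec,
        params=mean_params,
        bse=res.bse[mean_params.index],
        cov_params=res.cov_params().loc[mean_params.index, mean_params.index],
        conf_int=ci.loc[mean_params.index],
        loglik=float(res.llf),
        aic=aic,
        n_obs=int(res.nobs),
        n_params=n_params,
        dispersion=dispersion,
        converged=converged,
        result=res,
        data=table,
    )


def lrt(fit_alt: ModelFit, fit_null: ModelFit) -> LrtResult:
    """Likelihood-ratio test of a model against a nested null on the same rows."""
    if fit_alt.n_obs != fit_null.n_obs:
        raise ValueError("LRT requires identical data rows in both fits")
    if fit_alt.spec.response != fit_null.spec.response or (
        fit_alt.spec.family,
        fit_alt.spec.link,
    ) != (fit_null.spec.family, fit_null.spec.link):
        raise ValueError("LRT requires the same response and family/link")
    if not set(fit_null.spec.fixed_terms) <= set(fit_alt.spec.fixed_terms):
        raise ValueError("null model terms are not nested in the alternative")
    df = fit_alt.n_params - fit_null.n_params
    if df < 0:
        raise ValueError("alternative model has fewer parameters than the null")
    chi2 = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    p = 1.0 if df == 0 else float(sps.chi2.sf(chi2, df))
    return LrtResult(chi2=chi2, df=df, p_value=p)


# --------------------------------------------------------------------------
# Pairwise contrasts (estimated marginal means, Tukey-style adjustment)


def _design_info(fit: ModelFit):
    return fit.result.model.data.design_info


def _emm_rows(fit: ModelFit, factor: str) -> tuple[list[str], np.ndarray]:
    """Per-level averaged design rows (the estimated-marginal-means grid)."""
    data = fit.data
    if data is None:
        raise ValueError("fit carries no data; refit with fit_glm/fit_glmm")
    levels = sorted(data[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels in the fit data")
    di = _design_info(fit)
    rows = []
    for level in levels:
        grid = data.copy()
        grid[factor] = level
        X = patsy.build_design_matrices([di], grid, return_type="dataframe")[0]
        rows.append(X[fit.params.index].to_numpy().mean(axis=0))
    return levels, np.vstack(rows)


def _max_abs_z_prob(t: float, corr: np.ndarray) -> float:
    """P(max_j |Z_j| <= t) for Z ~ MVN(0, corr)."""
    if t <= 0:
        return 0.0
    m = corr.shape[0]
    if m == 1:
        return float(sps.norm.cdf(t) - sps.norm.cdf(-t))
    mvn = sps.multivariate_normal(mean=np.zeros(m), cov=corr, allow_singular=True)
    return float(mvn.cdf(np.full(m, t), lower_limit=np.full(m, -t)))


def pairwise_contrasts(
    fit: ModelFit, factor: str, adjustment: str = "tukey", alpha: float = 0.05
) -> list[ContrastResult]:
    """All pairwise level contrasts of `factor`, back-transformed.

    Contrasts are formed on the link scale from estimated marginal means
    (design rows averaged over the fit data with the factor forced to each
    level). The family-wise adjustment is the multivariate-normal max-|z|
    method over the full contrast set — the large-sample analogue of the
    Tukey adjustment used by emmeans. Estimates are reported on the
    response scale: ratios of predicted means for log and inverse links,
    differences for the identity link.
    """
    if adjustment not in {"tukey", "none"}:
        raise ValueError("adjustment must be 'tukey' or 'none'")
    if factor not in fit.data.columns:
        raise ValueError(f"factor {factor!r} not in the fit data")
    if not any(factor in term for term in fit.spec.fixed_terms):
        raise ValueError(f"factor {factor!r} is not a term of the fitted model")
    levels, emm = _emm_rows(fit, factor)
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    pairs = list(itertools.combinations(range(len(levels)), 2))
    C = np.vstack([emm[i] - emm[j] for i, j in pairs])
    est = C @ beta
    V = C @ cov @ C.T
    se = np.sqrt(np.maximum(np.diag(V), 1e-300))
    z = est / se
    corr = V / np.outer(se, se)

    p_unadj = 2.0 * sps.norm.sf(np.abs(z))
    if adjustment == "tukey" and len(pairs) > 1:
        p_adj = np.array([1.0 - _max_abs_z_prob(abs(zi), corr) for zi in z])
        crit = brentq(lambda t: _max_abs_z_prob(t, corr) - (1.0 - alpha), 1e-6, 20.0)
    else:
        p_adj = p_unadj.copy()
        crit = sps.norm.ppf(1.0 - alpha / 2.0)
    p_adj = np.clip(np.maximum(p_adj, p_unadj), 0.0, 1.0)

    eta = emm @ beta  # per-level linear predictor at the EMM grid
    results: list[ContrastResult] = []
    for k, (i, j) in enumerate(pairs):
        lo_link, hi_link = est[k] - crit * se[k], est[k] + crit * se[k]
        if fit.spec.link == "log":
            value = float(np.exp(est[k]))
            lo, hi = float(np.exp(lo_link)), float(np.exp(hi_link))
        elif fit.spec.link == "identity":
            value = float(est[k])
            lo, hi = float(lo_link), float(hi_link)
        elif fit.spec.link == "inverse":
            # mu = 1/eta, so mu_i/mu_j = eta_j/eta_i; delta method on log-ratio
            value = float(eta[j] / eta[i])
            grad = emm[j] / eta[j] - emm[i] / eta[i]
            se_log = float(np.sqrt(grad @ cov @ grad))
            lo = float(value * np.exp(-crit * se_log))
            hi = float(value * np.exp(crit * se_log))
        else:  # pragma: no cover - links are closed above
            raise AssertionError(fit.spec.link)
        results.append(
            ContrastResult(
                level_pair=(levels[i], levels[j]),
                estimate_response_scale=value,
                ci_low=min(lo, hi),
                ci_high=max(lo, hi),
                p_adjusted=float(p_adj[k]),
                p_unadjusted=float(p_unadj[k]),
                adjustment=adjustment,
                estimate_link_scale=float(est[k]),
                se_link_scale=float(se[k]),
            )
        )
    return results


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "level_a": [c.level_pair[0] for c in contrasts],
            "level_b": [c.level_pair[1] for c in contrasts],
            "estimate_response_scale": [c.estimate_response_scale for c in contrasts],
            "ci_low": [c.ci_low for c in contrasts],
            "ci_high": [c.ci_high for c in contrasts],
            "p_adjusted": [c.p_adjusted for c in contrasts],
            "p_unadjusted": [c.p_unadjusted for c in contrasts],
            "adjustment": [c.adjustment for c in contrasts],
        }
    )


# --------------------------------------------------------------------------
# Candidate set and AIC selection


def build_candidate_set(
    response: str,
    family: str,
    link: str,
    fixed_menu: tuple[str, ...] = ("sex", "season", "tmean_c", "precip_mm"),
    interaction: str = "sex:season",
    random_terms: tuple[str, ...] = DEFAULT_RANDOM_TERMS,
) -> list[ModelSpec]:
    """The deterministic 16-model a priori candidate set for one metric.

    The original supplementary model list is not archived with the data,
    so this is the package's documented reconstruction: the null; each
    single term; the sex+season pair and its interactive twin; those two
    plus temperature, plus precipitation, plus both; the environment-only
    pair; and sex or season with both environmental covariates. All models
    carry crossed random intercepts for bat and year.
    """
    sex, season, tmean, precip = fixed_menu

    def spec(*terms: str) -> ModelSpec:
        return ModelSpec(
            response=response,
            family=family,
            link=link,
            fixed_terms=tuple(terms),
            random_terms=tuple(random_terms),
        )

    both = (sex, season)
    inter = both + (interaction,)
    candidates = [
        spec(),
        spec(sex),
        spec(season),
        spec(tmean),
        spec(precip),
        spec(*both),
        spec(*inter),
        spec(*both, tmean),
        spec(*inter, tmean),
        spec(*both, precip),
        spec(*inter, precip),
        spec(*both, tmean, precip),
        spec(*inter, tmean, precip),
        spec(tmean, precip),
        spec(sex, tmean, precip),
        spec(season, tmean, precip),
    ]
    assert len(candidates) == 16
    return candidates


def select_by_aic(fits: list[ModelFit], best_delta: float = 2.0) -> pd.DataFrame:
    """Rank fits by AIC; the best set is every model within `best_delta`.

    All fits must be on identical data rows (same n_obs), otherwise AICs
    are not comparable and this raises.
    """
    if not fits:
        raise ValueError("no fits to rank")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits use differing numbers of rows: {sorted(n_obs)}")
    table = pd.DataFrame(
        {
            "model": [f.spec.describe() for f in fits],
            "terms": [" + ".join(f.spec.fixed_terms) or "1" for f in fits],
            "n_params": [f.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "n_obs": [f.n_obs for f in fits],
            "fallback": [f.fallback or "" for f in fits],
        }
    )
    table = table.sort_values(["aic", "n_params"], kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["in_best_set"] = table["delta_aic"] < best_delta
    return table


# --------------------------------------------------------------------------
# Mixed models


def fit_glmm(table: pd.DataFrame, spec: ModelSpec, **fit_kwds) -> ModelFit:
    """Fit a spec with crossed random intercepts.

    Gaussian responses are fit as a linear mixed model with variance
    components for each random term (one crossed intercept per grouping
    variable), by maximum likelihood so AICs are comparable across the
    candidate set. Other families use the documented fallback: the GLM
    point fit with cluster-robust standard errors grouped on the first
    random term, with ``fallback="glm_cluster_robust"`` recorded. A
    singular gaussian fit is flagged and the offending variance component
    reported as 0.
    """
    if not spec.random_terms:
        return fit_glm(table, spec, **fit_kwds)
    missing = [t for t in spec.random_terms if t not in table.columns]
    if missing:
        raise ValueError(f"random grouping column(s) missing from table: {missing}")

    if spec.family == "gaussian":
        vc = {term: f"0 + C({term})" for term in spec.random_terms}
        model = sm.MixedLM.from_formula(
            spec.formula,
            data=table,
            groups=np.ones(len(table)),
            vc_formula=vc,
            re_formula="0",
        )
        res = model.fit(reml=False, **fit_kwds)
        converged = bool(res.converged)
        re_sd = {term: float(np.sqrt(max(res.vcomp[i], 0.0)))
                 for i, term in enumerate(spec.random_terms)}
        if any(v == 0.0 for v in re_sd.values()):
            logger.warning("singular mixed fit (a variance component is 0): %s", spec.describe())
        n_params = len(res.fe_params) + len(spec.random_terms) + 1
        aic = 2.0 * n_params - 2.0 * float(res.llf)
        params = res.fe_params
        ci = res.conf_int().loc[params.index]
        ci.columns = ["ci_low", "ci_high"]
        return ModelFit(
            spec=spec,
            params=params,
            bse=res.bse[params.index],
            cov_params=res.cov_params().loc[params.index, params.index],
            conf_int=ci,
            loglik=float(res.llf),
            aic=aic,
            n_obs=int(res.nobs),
            n_params=n_params,
            dispersion=float(res.scale),
            converged=converged,
            random_effect_sd=re_sd,
            result=res,
            data=table,
        )

    cluster = spec.random_terms[0]
    groups = table[cluster]
    fit = fit_glm(
        table,
        replace(spec, random_terms=()),
        cov_type="cluster",
        cov_kwds={"groups": np.asarray(groups)},
        **fit_kwds,
    )
    fit.spec = spec
    fit.fallback = "glm_cluster_robust"
    fit.random_effect_sd = None
    return fit


# --------------------------------------------------------------------------
# Effect reporting


def effect_report(fit: ModelFit) -> pd.DataFrame:
    """Per-term effect sizes with 95% CIs on the response scale.

    Multiplicative links report ratios (exponentiated coefficients for the
    log link; ratios of predicted means against the intercept for the
    inverse link); the identity link reports plain differences in the
    response units. Reference levels are whatever the design's treatment
    coding chose (stated in the ``reference`` column).
    """
    params = fit.params
    ci = fit.conf_int
    intercept_name = "Intercept"
    rows = []
    reference = "treatment coding; first factor level alphabetically is the reference"
    for term in params.index:
        b = float(params[term])
        lo, hi = float(ci.loc[term, "ci_low"]), float(ci.loc[term, "ci_high"])
        if fit.spec.link == "log":
            scale = "ratio" if term != intercept_name else "mean"
            eff, elo, ehi = np.exp(b), np.exp(lo), np.exp(hi)
        elif fit.spec.link == "identity":
            scale = "difference" if term != intercept_name else "mean"
            eff, elo, ehi = b, lo, hi
        else:  # inverse link
            b0 = float(params[intercept_name])
            if term == intercept_name:
                scale = "mean"
                eff, elo, ehi = 1.0 / b0, 1.0 / hi, 1.0 / lo
            else:
                scale = "ratio"
                cov = fit.cov_params
                eta1, eta0 = b0 + b, b0
                eff = eta0 / eta1  # mu(level)/mu(ref) = eta0/eta1
                g0 = 1.0 / eta0 - 1.0 / eta1  # d log eff / d b0
                g1 = -1.0 / eta1  # d log eff / d b
                var_log = (
                    g0 * g0 * cov.loc[intercept_name, intercept_name]
                    + 2.0 * g0 * g1 * cov.loc[intercept_name, term]
                    + g1 * g1 * cov.loc[term, term]
                )
                half = 1.959963984540054 * float(np.sqrt(max(var_log, 0.0)))
                elo, ehi = eff * np.exp(-half), eff * np.exp(half)
        rows.append(
            {
                "term": term,
                "estimate_link_scale": b,
                "ci_low_link": lo,
                "ci_high_link": hi,
                "effect_response_scale": float(eff),
                "ci_low_response": float(min(elo, ehi)),
                "ci_high_response": float(max(elo, ehi)),
                "scale": scale,
                "reference": reference,
            }
        )
    return pd.DataFrame(rows)
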