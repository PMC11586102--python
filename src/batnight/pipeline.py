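"""End-to-end orchestration: config in, artifact directory out.

A run reads the four canonical inputs (detections, deployments, sites,
optionally daily environment), cleans and codes the detection stream,
derives the per-bat-night metrics, attaches covariates and fits the
statistical layer for the requested mode. Every artifact directory carries
a run log with the config hash, seed and package versions so any output
file can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, covariates, detections_io, event_coding, metrics, stats

logger = logging.getLogger(__name__)

# family/link per metric, per analysis mode
REPRO_FAMILIES: dict[str, tuple[str, str]] = {
    "n_returns": ("poisson", "log"),
    "hours_inside": ("gamma", "inverse"),
    "hours_active": ("gamma", "inverse"),
    "emergence_hour_of_day": ("gamma", "inverse"),
}
SEX_ENV_FAMILIES: dict[str, tuple[str, str]] = {
    "n_returns": ("negative_binomial", "log"),
    "hours_inside": ("gamma", "log"),
    "hours_active": ("gamma", "log"),
    "emergence_min_after_sunset": ("gaussian", "identity"),
}


@dataclass
class RunConfig:
    """Validated run configuration; all referenced paths must exist."""

    detections: Path
    deployments: Path
    sites: Path
    site_id: str
    out_dir: Path
    env: Path | None = None
    mode: str = "sex_environment"
    exclusion_days: int = 3
    window_days: int | None = None
    burst_gap_s: float = 60.0
    sunset_tolerance_min: float = 30.0
    adjustment: str = "tukey"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detections", "deployments", "sites", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.env is not None:
            self.env = Path(self.env)
        if self.mode not in covariates.ANALYSIS_MODES:
            raise ValueError(f"mode must be one of {covariates.ANALYSIS_MODES}")
        for path in [self.detections, self.deployments, self.sites] + (
            [self.env] if self.env else []
        ):
            if not Path(path).exists():
                raise FileNotFoundError(f"input file does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        canon = json.dumps(
            {k: str(v) for k, v in vars(self).items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(canon).hexdigest()[:12]


def _fit_repro_mode(table: pd.DataFrame, adjustment: str, report: dict) -> dict:
    """Single-fixed-effect GLM per metric + LRT + pairwise contrasts."""
    out = {"fits": [], "contrasts": [], "lrt": []}
    for response, (family, link) in REPRO_FAMILIES.items():
        sub = table
        if family == "gamma":
            sub = stats.drop_nonpositive(sub, response, report=report)
        if sub["repro_condition"].nunique() < 2 or len(sub) < 10:
            logger.warning("skipping %s: not enough data/levels", response)
            continue
        spec_alt = stats.ModelSpec(response, family, link, fixed_terms=("repro_condition",))
        spec_null = stats.ModelSpec(response, family, link)
        fit_alt = stats.fit_glm(sub, spec_alt)
        fit_null = stats.fit_glm(sub, spec_null)
        test = stats.lrt(fit_alt, fit_null)
        out["lrt"].append(
            {"response": response, "chi2": test.chi2, "df": test.df, "p_value": test.p_value}
        )
        out["fits"].append((response, fit_alt))
        cons = stats.pairwise_contrasts(fit_alt, "repro_condition", adjustment=adjustment)
        cdf = stats.contrasts_frame(cons)
        cdf.insert(0, "response", response)
        out["contrasts"].append(cdf)
    return out


def _fit_sex_env_mode(table: pd.DataFrame, report: dict) -> dict:
    """16-model AIC-ranked candidate set per metric, crossed random intercepts."""
    out = {"fits": [], "aic_tables": []}
    for response, (family, link) in SEX_ENV_FAMILIES.items():
        sub = table
        if family == "gamma":
            sub = stats.drop_nonpositive(sub, response, report=report)
        if len(sub) < 20:
            logger.warning("skipping %s: too few rows", response)
            continue
        specs = stats.build_candidate_set(response, family, link)
        fits = [stats.fit_glmm(sub, spec) for spec in specs]
        ranked = stats.select_by_aic(fits)
        ranked.insert(0, "response", response)
        out["aic_tables"].append(ranked)
        best_terms = ranked.loc[0, "terms"]
        best_fit = next(
            f for f in fits if (" + ".join(f.spec.fixed_terms) or "1") == best_terms
        )
        out["fits"].append((response, best_fit))
    return out


def _fit_to_json(response: str, fit: stats.ModelFit) -> dict:
    return {
        "response": response,
        "model": fit.spec.describe(),
        "family": fit.spec.family,
        "link": fit.spec.link,
        "coefficients": {
            term: {
                "estimate": float(fit.params[term]),
                "se": float(fit.bse[term]),
                "ci_low": float(fit.conf_int.loc[term, "ci_low"]),
                "ci_high": float(fit.conf_int.loc[term, "ci_high"]),
            }
            for term in fit.params.index
        },
        "loglik": fit.loglik,
        "aic": fit.aic,
        "n_obs": fit.n_obs,
        "dispersion": fit.dispersion,
        "converged": fit.converged,
        "fallback": fit.fallback,
        "random_effect_sd": fit.random_effect_sd,
    }


def run(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the out dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    sites = detections_io.load_sites(config.sites)
    if config.site_id not in sites:
        raise ValueError(f"site {config.site_id!r} not in {config.sites}")
    site = sites[config.site_id]
    detections = detections_io.read_detections(config.detections, sites)
    deployments = detections_io.read_deployments(config.deployments)
    env = detections_io.read_env(config.env) if config.env else None
    if config.mode == "sex_environment" and env is None:
        raise ValueError("sex_environment mode needs daily environment covariates (env)")

    coded, bat_nights = event_coding.code_detection_stream(
        detections,
        deployments,
        site,
        exclusion_days=config.exclusion_days,
        window_days=config.window_days,
        burst_gap_s=config.burst_gap_s,
        sunset_tolerance_min=config.sunset_tolerance_min,
        report=report,
    )
    coded.to_csv(out_dir / "coded_events.csv", index=False)

    metric_table = metrics.compute_all(bat_nights)
    metric_table.to_csv(out_dir / "metrics.csv", index=False)

    table = covariates.build_analysis_table(
        metric_table, deployments, env=env, mode=config.mode, report=report
    )
    if config.mode == "repro_condition":
        clock = pd.to_datetime(table["emergence_clock"])
        table = table.assign(
            emergence_hour_of_day=clock.dt.hour + clock.dt.minute / 60.0 + clock.dt.second / 3600.0
        )
    table.to_csv(out_dir / "analysis_table.csv", index=False)

    fits_json: list[dict] = []
    if config.mode == "repro_condition":
        fitted = _fit_repro_mode(table, config.adjustment, report)
        if fitted["contrasts"]:
            pd.concat(fitted["contrasts"], ignore_index=True).to_csv(
                out_dir / "contrasts.csv", index=False
            )
        with open(out_dir / "lrt.json", "w", encoding="utf-8") as fh:
            json.dump(fitted["lrt"], fh, indent=2)
    else:
        fitted = _fit_sex_env_mode(table, report)
        if fitted["aic_tables"]:
            pd.concat(fitted["aic_tables"], ignore_index=True).to_csv(
                out_dir / "aic_table.csv", index=False
            )
    for response, fit in fitted["fits"]:
        fits_json.append(_fit_to_json(response, fit))
        eff = stats.effect_report(fit)
        eff.insert(0, "response", response)
        eff.to_csv(out_dir / f"effects_{response}.csv", index=False)
    with open(out_dir / "fits.json", "w", encoding="utf-8") as fh:
        json.dump(fits_json, fh, indent=2)
    with open(out_dir / "cleaning_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "package_version": __version__,
                "config_hash": config.digest(),
                "seed": config.seed,
                "mode": config.mode,
                "finished_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
                "parameters": {k: str(v) for k, v in vars(config).items()},
                "n_bat_nights": int(len(metric_table)),
            },
            fh,
            indent=2,
        )
    logger.info("run complete: %d bat-nights, artifacts in %s", len(metric_table), out_dir)
    return out_dir
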