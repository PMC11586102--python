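"""Attach biological and environmental covariates to bat-night metrics.

Food availability follows the regional phenology of columnar cacti, the
main food source of nectarivorous bats in the study region: November
through January is the low season, February-April the nectar season,
May-July the nectar-fruit season, and August-October the fruit season.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

SEASON_MONTHS: dict[str, tuple[int, ...]] = {
    "low": (11, 12, 1),
    "nectar": (2, 3, 4),
    "nectar_fruit": (5, 6, 7),
    "fruit": (8, 9, 10),
}

_MONTH_TO_SEASON = {m: label for label, months in SEASON_MONTHS.items() for m in months}

REPRO_ANALYSIS_CONDITIONS = ("nonreproductive", "pregnant", "lactating")

ANALYSIS_MODES = ("repro_condition", "sex_environment")


def season_for_month(month: int) -> str:
    """Food-availability season label for a calendar month (1-12)."""
    if month not in _MONTH_TO_SEASON:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    return _MONTH_TO_SEASON[month]


def build_analysis_table(
    metrics: pd.DataFrame,
    deployments: pd.DataFrame,
    env: pd.DataFrame | None = None,
    mode: str = "sex_environment",
    report: dict | None = None,
) -> pd.DataFrame:
    """Join metrics with sex/condition, season, year and daily environment.

    ``mode="repro_condition"`` keeps females whose condition at tagging is
    nonreproductive, pregnant or lactating (postlactating females yielded
    no analyzable bat-nights in the study design and are excluded);
    ``mode="sex_environment"`` keeps all bats. Rows whose night lacks an
    environmental record are dropped complete-case with a logged count.
    """
    if mode not in ANALYSIS_MODES:
        raise ValueError(f"mode must be one of {ANALYSIS_MODES}, got {mode!r}")
    table = metrics.merge(
        deployments[["tag_id", "sex", "repro_condition"]].reset_index(drop=True),
        on="tag_id",
        how="left",
    )
    if table["sex"].isna().any():
        missing = sorted(table.loc[table["sex"].isna(), "tag_id"].unique())
        raise ValueError(f"metrics contain tags without deployment rows: {missing}")

    if mode == "repro_condition":
        table = table[
            (table["sex"] == "F")
            & table["repro_condition"].isin(REPRO_ANALYSIS_CONDITIONS)
        ]

    night_date = pd.to_datetime(table["night_date"])
    table = table.assign(
        bat_id=table["tag_id"],  # grouping column for the crossed random effect
        season=night_date.dt.month.map(_MONTH_TO_SEASON),
        year=night_date.dt.year,
    )

    if env is not None:
        n_before = len(table)
        table = table.merge(
            env[["date", "tmean_c", "precip_mm"]].reset_index(drop=True),
            left_on=table["night_date"].map(pd.Timestamp).map(pd.Timestamp.date),
            right_on="date",
            how="left",
        ).drop(columns=["date"])
        n_missing = int(table["tmean_c"].isna().sum())
        if n_missing:
            logger.info(
                "%d of %d bat-night(s) dropped: no environmental record", n_missing, n_before
            )
        if report is not None:
            report["missing_env_rows"] = n_missing
        table = table.dropna(subset=["tmean_c", "precip_mm"])

    return table.reset_index(drop=True)
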