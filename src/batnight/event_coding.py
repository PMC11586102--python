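"""Clean detection streams and code passages into alternating EXIT/ENTRY events.

A single cord antenna at a roost entrance cannot sense direction, so
direction is inferred by alternation: the first nightly detection is the
emergence EXIT, the next a return ENTRY, and so on. A missed passage
silently flips subsequent inferred directions; this is a known limitation
of single-antenna coding (quantified by the synthetic module) and is not
corrected here.

The cleaning sequence mirrors the field protocol:

1. drop detections in the first days after tagging (handling stress),
2. optionally keep only a fixed window after that (so the reproductive
   condition recorded at tagging still applies),
3. collapse read bursts into passages,
4. merge roosts of a complex into a single logical entrance,
5. assign passages to nights and code directions.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detections_io import Night, Site, compute_sun_times

logger = logging.getLogger(__name__)

EXIT = "EXIT"
ENTRY = "ENTRY"

CODED_EVENT_COLUMNS = ["tag_id", "night_date", "timestamp", "direction", "roost_id", "ordinal"]


@dataclass
class BatNight:
    """One bat's coded events between a sunset and the following sunrise."""

    tag_id: str
    night: Night
    events: pd.DataFrame  # columns: timestamp, direction, roost_id, ordinal
    censored_open_end: bool
    pre_sunset_emergence: bool

    def __post_init__(self) -> None:
        n = len(self.events)
        if n == 0:
            raise ValueError("BatNight requires at least one coded event")
        if self.censored_open_end != (n % 2 == 1):
            raise ValueError("censored_open_end must equal odd event count")


def filter_post_tagging(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    exclusion_days: int = 3,
    unknown_tags: str = "drop",
    report: dict | None = None,
) -> pd.DataFrame:
    """Drop each tag's detections within `exclusion_days` of its tagging time.

    The default of 3 days discards the window in which handling stress can
    distort behavior. Detections of tags absent from the deployment table
    are dropped with a warning (``unknown_tags="drop"``) or raise
    (``unknown_tags="error"``).
    """
    if unknown_tags not in {"drop", "error"}:
        raise ValueError("unknown_tags must be 'drop' or 'error'")
    known = detections["tag_id"].isin(deployments.index)
    n_unknown = int((~known).sum())
    if n_unknown and unknown_tags == "error":
        raise ValueError(
            f"{n_unknown} detection(s) of tags absent from the deployment table"
        )
    if n_unknown:
        logger.warning("%d detection(s) of unknown tags dropped", n_unknown)
    det = detections[known]
    cutoff = deployments["tagged_at"].reindex(det["tag_id"]).to_numpy() + np.timedelta64(
        exclusion_days, "D"
    )
    keep = det["timestamp"].to_numpy() >= cutoff
    n_dropped = int((~keep).sum())
    if n_dropped:
        per_tag = det.loc[~keep, "tag_id"].value_counts()
        logger.info(
            "post-tagging exclusion (%d d): dropped %d detection(s) across %d tag(s)",
            exclusion_days, n_dropped, len(per_tag),
        )
        fully_excluded = set(det["tag_id"].unique()) - set(det.loc[keep, "tag_id"].unique())
        if fully_excluded:
            logger.warning(
                "tag(s) with all detections inside the exclusion window: %s",
                sorted(fully_excluded),
            )
    if report is not None:
        report["unknown_tag_detections"] = n_unknown
        report["post_tagging_excluded"] = n_dropped
    return det[keep].reset_index(drop=True)


def select_condition_window(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    window_days: int | None = 14,
    exclusion_days: int = 3,
    report: dict | None = None,
) -> pd.DataFrame:
    """Keep only detections within `window_days` after the post-tagging exclusion.

    Used for the reproductive-condition analysis: the condition recorded at
    tagging is only trusted for a short window (default 14 days). Pass
    ``window_days=None`` to keep everything (the sex/season analysis uses
    all detections).
    """
    if window_days is None:
        return detections.reset_index(drop=True)
    cutoff = deployments["tagged_at"].reindex(detections["tag_id"]).to_numpy() + np.timedelta64(
        exclusion_days + window_days, "D"
    )
    keep = detections["timestamp"].to_numpy() < cutoff
    n_dropped = int((~keep).sum())
    if report is not None:
        report["outside_condition_window"] = n_dropped
    return detections[keep].reset_index(drop=True)


def deduplicate_bursts(detections: pd.DataFrame, burst_gap_s: float = 60.0) -> pd.DataFrame:
    """Collapse runs of rapid same-tag reads into single passages.

    Successive reads of one tag separated by at most `burst_gap_s` seconds
    belong to one passage, stamped with the run's first timestamp; the
    number of raw reads collapsed is kept in ``n_raw_reads``. Idempotent,
    and monotone: a larger gap threshold never yields more passages.
    """
    if burst_gap_s < 0:
        raise ValueError("burst_gap_s must be >= 0")
    if detections.empty:
        return pd.DataFrame(columns=["tag_id", "timestamp", "site_id", "roost_id", "n_raw_reads"])
    det = detections.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    same_tag = det["tag_id"].eq(det["tag_id"].shift())
    gap = det["timestamp"].diff().dt.total_seconds()
    new_passage = ~(same_tag & (gap <= burst_gap_s))
    passage_id = new_passage.cumsum()
    agg = {"tag_id": "first", "timestamp": "first", "site_id": "first", "roost_id": "first"}
    passages = det.groupby(passage_id).agg(agg)
    if "n_raw_reads" in det.columns:  # re-application keeps raw-read bookkeeping
        passages["n_raw_reads"] = det.groupby(passage_id)["n_raw_reads"].sum()
    else:
        passages["n_raw_reads"] = det.groupby(passage_id).size()
    return passages.reset_index(drop=True)


def merge_roost_complex(passages: pd.DataFrame, site: Site) -> pd.DataFrame:
    """Rewrite roost ids of a merged complex to a single logical entrance.

    When two roosts sit close enough that bats switch between them within a
    night, their entrances are coded as one site: ``coding_roost`` becomes
    the site id while the original ``roost_id`` is retained for reporting.
    Identity for sites with ``merge_roosts=False``.
    """
    out = passages.copy()
    at_site = out["site_id"] == site.site_id
    if site.merge_roosts:
        out.loc[at_site, "coding_roost"] = site.site_id
    if "coding_roost" not in out.columns:
        out["coding_roost"] = out["roost_id"]
    else:
        out["coding_roost"] = out["coding_roost"].fillna(out["roost_id"])
    return out


def assign_nights(
    passages: pd.DataFrame,
    site: Site,
    sunset_tolerance_min: float = 30.0,
    report: dict | None = None,
) -> tuple[pd.DataFrame, dict[dt.date, Night]]:
    """Attach each passage to the night whose window contains it.

    The night window is [sunset - tolerance, sunrise]; the tolerance band
    admits occasional emergence slightly before civil sunset. Passages
    outside every window (daytime reads) are dropped and counted.
    Returns (passages with ``night_date``, {night_date: Night}).
    """
    if passages.empty:
        return passages.assign(night_date=pd.Series(dtype=object)), {}
    tol = dt.timedelta(minutes=sunset_tolerance_min)
    dates = pd.to_datetime(passages["timestamp"]).dt.date
    nights: dict[dt.date, Night] = {}
    for date in sorted(set(dates) | {d - dt.timedelta(days=1) for d in set(dates)}):
        nights[date] = compute_sun_times(site, date)

    ts = passages["timestamp"]
    same_day = dates.map(lambda d: nights[d])
    prev_day = dates.map(lambda d: nights[d - dt.timedelta(days=1)])
    in_same = (ts >= same_day.map(lambda n: n.sunset) - tol) & (
        ts <= same_day.map(lambda n: n.sunrise)
    )
    in_prev = (ts >= prev_day.map(lambda n: n.sunset) - tol) & (
        ts <= prev_day.map(lambda n: n.sunrise)
    )
    out = passages.copy()
    out["night_date"] = np.where(
        in_same, dates, np.where(in_prev, dates - dt.timedelta(days=1), None)
    )
    n_daytime = int(out["night_date"].isna().sum())
    if n_daytime:
        logger.info("%d daytime passage(s) dropped", n_daytime)
    if report is not None:
        report["daytime_passages"] = n_daytime
    out = out.dropna(subset=["night_date"]).reset_index(drop=True)
    used = {d for d in out["night_date"].unique()}
    return out, {d: n for d, n in nights.items() if d in used}


def code_directions(
    passages: pd.DataFrame, nights: dict[dt.date, Night]
) -> tuple[pd.DataFrame, list[BatNight]]:
    """Impose strict EXIT/ENTRY alternation per bat-night, emergence first.

    The first passage of a bat-night is the emergence EXIT; directions then
    alternate. An odd event count leaves the final outside interval
    unobserved (``censored_open_end``). Returns the coded-event table and
    the per-bat-night objects.
    """
    if passages.empty:
        return pd.DataFrame(columns=CODED_EVENT_COLUMNS), []
    coded_rows: list[pd.DataFrame] = []
    bat_nights: list[BatNight] = []
    for (tag_id, night_date), grp in passages.groupby(["tag_id", "night_date"], sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
        n = len(grp)
        ordinal = np.arange(1, n + 1)
        direction = np.where(ordinal % 2 == 1, EXIT, ENTRY)
        roost_col = "coding_roost" if "coding_roost" in grp.columns else "roost_id"
        events = pd.DataFrame(
            {
                "tag_id": tag_id,
                "night_date": night_date,
                "timestamp": grp["timestamp"],
                "direction": direction,
                "roost_id": grp[roost_col],
                "ordinal": ordinal,
            }
        )
        night = nights[night_date]
        coded_rows.append(events)
        bat_nights.append(
            BatNight(
                tag_id=tag_id,
                night=night,
                events=events,
                censored_open_end=bool(n % 2 == 1),
                pre_sunset_emergence=bool(grp["timestamp"].iloc[0] < night.sunset),
            )
        )
    coded = pd.concat(coded_rows, ignore_index=True)[CODED_EVENT_COLUMNS]
    return coded, bat_nights


def code_detection_stream(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    site: Site,
    exclusion_days: int = 3,
    window_days: int | None = None,
    burst_gap_s: float = 60.0,
    sunset_tolerance_min: float = 30.0,
    report: dict | None = None,
) -> tuple[pd.DataFrame, list[BatNight]]:
    """Full cleaning + coding chain for one site's detection stream."""
    det = detections[detections["site_id"] == site.site_id]
    det = filter_post_tagging(det, deployments, exclusion_days, report=report)
    det = select_condition_window(
        det, deployments, window_days, exclusion_days, report=report
    )
    passages = deduplicate_bursts(det, burst_gap_s)
    passages = merge_roost_complex(passages, site)
    passages, nights = assign_nights(passages, site, sunset_tolerance_min, report=report)
    return code_directions(passages, nights)
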