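"""Readers and validators for PIT-tag detection streams and their side tables.

A study deployment produces four kinds of plain-text input:

* ``detections.csv`` — raw antenna reads: ``tag_id,timestamp,site_id,roost_id[,antenna_id]``
* ``deployments.csv`` — one row per tagged bat: sex, reproductive condition, tagging time
* ``sites.yaml`` — per-site coordinates, UTC offset and roost membership
* ``env.csv`` — daily mean temperature and precipitation

All timestamps are *local civil time* with the site's fixed UTC offset; no
daylight-saving inference is attempted, so sunset-relative arithmetic is
unambiguous. CSV is the canonical dialect (comma, UTF-8, header row);
readers reject anything else rather than sniffing.

Sunset and sunrise are computed with the NOAA solar calculator method
(Julian-century series for solar declination and the equation of time,
zenith 90.833 deg to include refraction and the solar radius).
"""

from __future__ import annotations

import csv
import datetime as dt
import io
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["tag_id", "timestamp", "site_id", "roost_id", "antenna_id"]

SEXES = {"F", "M"}
REPRO_CONDITIONS = {"nonreproductive", "pregnant", "lactating", "postlactating", "NA"}


class SchemaError(ValueError):
    """Input file violates the documented schema."""


@dataclass(frozen=True)
class Site:
    """A roost site: coordinates, clock offset and member roost entrances."""

    site_id: str
    latitude: float
    longitude: float
    utc_offset_hours: float
    roost_ids: frozenset[str]
    merge_roosts: bool = False

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"site {self.site_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"site {self.site_id}: longitude {self.longitude} out of range")
        if self.merge_roosts and len(self.roost_ids) < 2:
            raise ValueError(
                f"site {self.site_id}: merge_roosts requires at least 2 roost_ids"
            )


@dataclass(frozen=True)
class Night:
    """One night at a site: the sunset that opens it and the next sunrise."""

    site_id: str
    night_date: dt.date
    sunset: dt.datetime
    sunrise: dt.datetime

    def __post_init__(self) -> None:
        if not self.sunset < self.sunrise:
            raise ValueError(f"night {self.night_date}: sunset must precede sunrise")


# --------------------------------------------------------------------------
# NOAA solar calculation


def _julian_day(date: dt.date) -> float:
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_params(jc: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (min) at Julian century jc."""
    gml = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    ctr = (
        math.sin(math.radians(gma)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(math.radians(2 * gma)) * (0.019993 - 0.000101 * jc)
        + math.sin(math.radians(3 * gma)) * 0.000289
    )
    true_long = gml + ctr
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    eot = 4.0 * math.degrees(
        var_y * math.sin(2.0 * math.radians(gml))
        - 2.0 * ecc * math.sin(math.radians(gma))
        + 4.0 * ecc * var_y * math.sin(math.radians(gma)) * math.cos(2.0 * math.radians(gml))
        - 0.5 * var_y * var_y * math.sin(4.0 * math.radians(gml))
        - 1.25 * ecc * ecc * math.sin(2.0 * math.radians(gma))
    )
    return decl, eot


def _sun_events(latitude: float, longitude: float, utc_offset_hours: float,
                date: dt.date) -> tuple[dt.datetime, dt.datetime]:
    """(sunrise, sunset) local civil datetimes on `date`, NOAA method."""
    jd = _julian_day(date) + 0.5 - utc_offset_hours / 24.0  # local noonish in UT
    jc = (jd - 2451545.0) / 36525.0
    decl, eot = _solar_params(jc)
    lat_r, decl_r = math.radians(latitude), math.radians(decl)
    cos_ha = (
        math.cos(math.radians(90.833)) / (math.cos(lat_r) * math.cos(decl_r))
        - math.tan(lat_r) * math.tan(decl_r)
    )
    if not -1.0 < cos_ha < 1.0:
        raise ValueError(
            f"polar day/night at latitude {latitude} on {date}: no sunrise/sunset"
        )
    ha = math.degrees(math.acos(cos_ha))  # half day-length, degrees
    solar_noon_min = 720.0 - 4.0 * longitude - eot + utc_offset_hours * 60.0
    sunrise_min = solar_noon_min - 4.0 * ha
    sunset_min = solar_noon_min + 4.0 * ha
    midnight = dt.datetime.combine(date, dt.time())
    return (
        midnight + dt.timedelta(minutes=sunrise_min),
        midnight + dt.timedelta(minutes=sunset_min),
    )


@lru_cache(maxsize=4096)
def compute_sun_times(site: Site, date: dt.date) -> Night:
    """Night record for `date` at `site`: sunset on `date`, sunrise on `date`+1.

    Supported latitudes are |lat| < 60 deg; closer to the poles the NOAA
    series degrades and polar day/night raises.
    """
    if abs(site.latitude) >= 60.0:
        raise ValueError(
            f"latitude {site.latitude} outside supported range (|lat| < 60 deg)"
        )
    _, sunset = _sun_events(site.latitude, site.longitude, site.utc_offset_hours, date)
    sunrise, _ = _sun_events(
        site.latitude, site.longitude, site.utc_offset_hours, date + dt.timedelta(days=1)
    )
    night = Night(site_id=site.site_id, night_date=date, sunset=sunset, sunrise=sunrise)
    span = (night.sunrise - night.sunset).total_seconds() / 3600.0
    if not 6.0 <= span <= 16.0:
        raise ValueError(
            f"night length {span:.1f} h on {date} outside supported 6-16 h band"
        )
    return night


# --------------------------------------------------------------------------
# Readers


def load_sites(path: str | Path) -> dict[str, Site]:
    """Load the site registry from YAML keyed by site_id."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping of site_id -> attributes")
    sites: dict[str, Site] = {}
    for site_id, attrs in raw.items():
        sites[site_id] = Site(
            site_id=str(site_id),
            latitude=float(attrs["latitude"]),
            longitude=float(attrs["longitude"]),
            utc_offset_hours=float(attrs["utc_offset"]),
            roost_ids=frozenset(str(r) for r in attrs["roost_ids"]),
            merge_roosts=bool(attrs.get("merge_roosts", False)),
        )
    return sites


def _parse_timestamp(text: str, path: str, line_no: int) -> dt.datetime:
    try:
        ts = dt.datetime.fromisoformat(text)
    except ValueError as exc:
        raise SchemaError(f"{path}, line {line_no}: unparseable timestamp {text!r}") from exc
    if ts.tzinfo is not None:
        raise SchemaError(
            f"{path}, line {line_no}: timestamps must be local civil time without tz suffix"
        )
    return ts


def read_detections(path: str | Path, site_registry: dict[str, Site]) -> pd.DataFrame:
    """Read a detection stream, validate against the site registry.

    Returns a DataFrame with columns ``tag_id, timestamp, site_id, roost_id,
    antenna_id`` sorted by (tag_id, timestamp). Exact duplicate rows are
    dropped with a logged count; an unknown site or roost, or an unparseable
    timestamp, is a hard error naming the offending line.
    """
    path = Path(path)
    rows: list[dict] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file without header")
        required = {"tag_id", "timestamp", "site_id", "roost_id"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            site_id = row["site_id"]
            site = site_registry.get(site_id)
            if site is None:
                raise SchemaError(f"{path}, line {line_no}: unknown site {site_id!r}")
            roost_id = row["roost_id"]
            if roost_id not in site.roost_ids:
                raise SchemaError(
                    f"{path}, line {line_no}: roost {roost_id!r} not registered for site {site_id!r}"
                )
            rows.append(
                {
                    "tag_id": row["tag_id"],
                    "timestamp": _parse_timestamp(row["timestamp"], str(path), line_no),
                    "site_id": site_id,
                    "roost_id": roost_id,
                    "antenna_id": row.get("antenna_id") or "",
                }
            )
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    n_before = len(df)
    df = df.drop_duplicates()
    n_dup = n_before - len(df)
    if n_dup:
        logger.info("%d duplicate detection row(s) dropped from %s", n_dup, path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def write_detections(detections: pd.DataFrame, path: str | Path) -> None:
    """Write a detection DataFrame in the canonical CSV schema (round-trips)."""
    out = detections.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[DETECTION_COLUMNS].to_csv(path, index=False)


def read_deployments(path: str | Path) -> pd.DataFrame:
    """Read the tag-deployment table, indexed by tag_id.

    One row per tag; a duplicated tag_id or a male carrying a reproductive
    condition is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"tag_id": str})
    required = {"tag_id", "tagged_at", "site_id", "sex", "repro_condition"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    dup = df["tag_id"][df["tag_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate tag_id(s): {sorted(dup.unique())}")
    df["tagged_at"] = pd.to_datetime(df["tagged_at"])
    df["repro_condition"] = df["repro_condition"].fillna("NA")
    bad_sex = set(df["sex"]) - SEXES
    if bad_sex:
        raise SchemaError(f"{path}: unknown sex value(s) {sorted(bad_sex)}")
    bad_repro = set(df["repro_condition"]) - REPRO_CONDITIONS
    if bad_repro:
        raise SchemaError(f"{path}: unknown repro_condition value(s) {sorted(bad_repro)}")
    males_with_condition = df[(df["sex"] == "M") & (df["repro_condition"] != "NA")]
    if len(males_with_condition):
        raise SchemaError(
            f"{path}: repro_condition set for male tag(s) "
            f"{sorted(males_with_condition['tag_id'])}"
        )
    return df.set_index("tag_id", drop=False)


def read_env(path: str | Path) -> pd.DataFrame:
    """Read daily environmental covariates ``date,tmean_c,precip_mm``.

    Gap days are accepted and reported via the log; negative precipitation
    is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"date", "tmean_c", "precip_mm"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if (df["precip_mm"] < 0).any():
        raise SchemaError(f"{path}: negative precip_mm")
    if df["date"].duplicated().any():
        raise SchemaError(f"{path}: duplicate dates")
    df = df.sort_values("date").reset_index(drop=True)
    if len(df) > 1:
        full = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1], freq="D").date
        gaps = sorted(set(full) - set(df["date"]))
        if gaps:
            logger.warning("env table has %d gap day(s), first %s", len(gaps), gaps[0])
    return df.set_index("date", drop=False)
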