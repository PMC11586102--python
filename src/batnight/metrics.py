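"""The four per-bat-night activity metrics.

* **emergence time** — minutes between local sunset and the first exit
  (negative inside the pre-sunset tolerance band), plus the clock time;
* **returns to the roost** — number of entries after the first exit;
* **hours inside** — summed return-to-exit intervals;
* **hours of activity** — summed exit-to-return intervals (time outside).

For a night whose events end with a paired return, inside + outside time
telescopes exactly to (last event - first exit); this conservation identity
is enforced by :func:`compute_all`. Open-ended final exits (censored
nights) contribute nothing to the duration sums rather than being
truncated at sunrise, which would fabricate a datum.
"""

from __future__ import annotations

import pandas as pd

from .event_coding import ENTRY, EXIT, BatNight

METRICS_COLUMNS = [
    "tag_id",
    "night_date",
    "emergence_min_after_sunset",
    "emergence_clock",
    "n_returns",
    "hours_inside",
    "hours_active",
    "n_events",
    "censored_open_end",
]

_CONSERVATION_TOL_S = 1.0


def emergence_time(bat_night: BatNight) -> tuple[float, pd.Timestamp]:
    """Minutes after sunset of the first exit, and its clock time."""
    first = bat_night.events.iloc[0]
    if first["direction"] != EXIT:
        raise ValueError("first coded event must be an EXIT")
    ts = pd.Timestamp(first["timestamp"])
    minutes = (ts - pd.Timestamp(bat_night.night.sunset)).total_seconds() / 60.0
    return minutes, ts


def count_returns(bat_night: BatNight) -> int:
    """Number of ENTRY events (returns after the first exit)."""
    return int((bat_night.events["direction"] == ENTRY).sum())


def hours_inside(bat_night: BatNight) -> float:
    """Summed hours across consecutive (return, next exit) pairs.

    Time before the first exit is not counted, and a final unpaired entry
    contributes nothing.
    """
    ev = bat_night.events
    total_s = 0.0
    for i in range(1, len(ev) - 1, 2):  # ENTRY at even index (0-based odd), EXIT follows
        total_s = total_s + (ev["timestamp"].iloc[i + 1] - ev["timestamp"].iloc[i]).total_seconds()
    return total_s / 3600.0


def hours_active(bat_night: BatNight) -> float:
    """Summed hours across (exit, return) pairs; an open final exit is skipped."""
    ev = bat_night.events
    total_s = 0.0
    for i in range(0, len(ev) - 1, 2):
        total_s = total_s + (ev["timestamp"].iloc[i + 1] - ev["timestamp"].iloc[i]).total_seconds()
    return total_s / 3600.0


def compute_metrics(bat_night: BatNight) -> dict:
    """All four metrics for one bat-night as a plain record."""
    minutes, clock = emergence_time(bat_night)
    return {
        "tag_id": bat_night.tag_id,
        "night_date": bat_night.night.night_date,
        "emergence_min_after_sunset": minutes,
        "emergence_clock": clock,
        "n_returns": count_returns(bat_night),
        "hours_inside": hours_inside(bat_night),
        "hours_active": hours_active(bat_night),
        "n_events": len(bat_night.events),
        "censored_open_end": bat_night.censored_open_end,
    }


def compute_all(bat_nights: list[BatNight]) -> pd.DataFrame:
    """Metrics table, one row per bat-night, with the conservation check.

    For every uncensored night, hours_inside + hours_active must equal the
    span from first to last event to within one second; a violation names
    the bat-night and raises, since it indicates corrupted coding upstream.
    """
    rows = [compute_metrics(bn) for bn in bat_nights]
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    for bn, row in zip(bat_nights, rows):
        if row["censored_open_end"]:
            continue
        span_h = (
            bn.events["timestamp"].iloc[-1] - bn.events["timestamp"].iloc[0]
        ).total_seconds() / 3600.0
        if abs(row["hours_inside"] + row["hours_active"] - span_h) > _CONSERVATION_TOL_S / 3600.0:
            raise ValueError(
                f"conservation violation for bat {row['tag_id']} night {row['night_date']}: "
                f"inside {row['hours_inside']:.4f} h + active {row['hours_active']:.4f} h "
                f"!= span {span_h:.4f} h"
            )
    return df
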