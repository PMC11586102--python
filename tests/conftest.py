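import datetime as dt

import pandas as pd
import pytest

from batnight.detections_io import Night, Site
from batnight.event_coding import ENTRY, EXIT, BatNight


@pytest.fixture
def carmen_like_site() -> Site:
    """Single-roost maternity site at the study latitude."""
    return Site(
        site_id="carmen",
        latitude=24.2,
        longitude=-110.3,
        utc_offset_hours=-7.0,
        roost_ids=frozenset({"cave"}),
    )


@pytest.fixture
def complex_site() -> Site:
    """Two nearby roosts coded as one logical entrance."""
    return Site(
        site_id="complex",
        latitude=24.1,
        longitude=-110.0,
        utc_offset_hours=-7.0,
        roost_ids=frozenset({"chivato", "gitana"}),
        merge_roosts=True,
    )


@pytest.fixture
def simple_night() -> Night:
    return Night(
        site_id="carmen",
        night_date=dt.date(2017, 4, 10),
        sunset=dt.datetime(2017, 4, 10, 19, 0, 0),
        sunrise=dt.datetime(2017, 4, 11, 6, 0, 0),
    )


def make_bat_night(night: Night, minutes_after_sunset: list[float],
                   tag_id: str = "bat01") -> BatNight:
    """Coded bat-night from passage offsets (minutes after sunset)."""
    n = len(minutes_after_sunset)
    events = pd.DataFrame(
        {
            "tag_id": tag_id,
            "night_date": night.night_date,
            "timestamp": [
                pd.Timestamp(night.sunset) + pd.Timedelta(minutes=m)
                for m in minutes_after_sunset
            ],
            "direction": [EXIT if i % 2 == 0 else ENTRY for i in range(n)],
            "roost_id": "cave",
            "ordinal": list(range(1, n + 1)),
        }
    )
    return BatNight(
        tag_id=tag_id,
        night=night,
        events=events,
        censored_open_end=n % 2 == 1,
        pre_sunset_emergence=minutes_after_sunset[0] < 0,
    )
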