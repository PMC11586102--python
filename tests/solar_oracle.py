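"""Independent solar-position oracle for the sunset/sunrise tests.

Implements the PSA algorithm (Blanco-Muriel et al. 2001), a closed-form
solar ephemeris based on sidereal time — a derivation independent of the
NOAA declination/equation-of-time series used by the package — and finds
sunset/sunrise by bisection on solar elevation = -0.8333 deg (the standard
refraction + solar-radius horizon).
"""

from __future__ import annotations

import datetime as dt
import math

_EARTH_MEAN_RADIUS_KM = 6371.01
_ASTRONOMICAL_UNIT_KM = 149597890.0


def psa_elevation_deg(when_utc: dt.datetime, latitude: float, longitude: float) -> float:
    """Topocentric solar elevation (degrees) at a UTC instant."""
    hours = when_utc.hour + when_utc.minute / 60.0 + when_utc.second / 3600.0
    y, m, d = when_utc.year, when_utc.month, when_utc.day
    aux1 = int((m - 14) / 12)  # C-style truncation
    aux2 = (
        int(1461 * (y + 4800 + aux1) / 4)
        + int(367 * (m - 2 - 12 * aux1) / 12)
        - int(3 * int((y + 4900 + aux1) / 100) / 4)
        + d
        - 32075
    )
    julian_date = aux2 - 0.5 + hours / 24.0
    elapsed = julian_date - 2451545.0

    omega = 2.1429 - 0.0010394594 * elapsed
    mean_longitude = 4.8950630 + 0.017202791698 * elapsed
    mean_anomaly = 6.2400600 + 0.0172019699 * elapsed
    ecliptic_longitude = (
        mean_longitude
        + 0.03341607 * math.sin(mean_anomaly)
        + 0.00034894 * math.sin(2 * mean_anomaly)
        - 0.0001134
        - 0.0000203 * math.sin(omega)
    )
    ecliptic_obliquity = 0.4090928 - 6.2140e-9 * elapsed + 0.0000396 * math.cos(omega)

    sin_ecl = math.sin(ecliptic_longitude)
    right_ascension = math.atan2(math.cos(ecliptic_obliquity) * sin_ecl,
                                 math.cos(ecliptic_longitude))
    if right_ascension < 0:
        right_ascension += 2.0 * math.pi
    declination = math.asin(math.sin(ecliptic_obliquity) * sin_ecl)

    gmst = 6.6974243242 + 0.0657098283 * elapsed + hours
    lmst = math.radians(gmst * 15.0 + longitude)
    hour_angle = lmst - right_ascension
    lat_r = math.radians(latitude)
    zenith = math.acos(
        math.cos(lat_r) * math.cos(hour_angle) * math.cos(declination)
        + math.sin(declination) * math.sin(lat_r)
    )
    zenith += (_EARTH_MEAN_RADIUS_KM / _ASTRONOMICAL_UNIT_KM) * math.sin(zenith)
    return 90.0 - math.degrees(zenith)


def _bisect_crossing(
    lo: dt.datetime, hi: dt.datetime, latitude: float, longitude: float, rising: bool
) -> dt.datetime:
    """Instant where elevation crosses -0.8333 deg between lo and hi."""
    target = -0.8333
    for _ in range(40):
        mid = lo + (hi - lo) / 2
        above = psa_elevation_deg(mid, latitude, longitude) > target
        if above != rising:  # crossing still ahead of mid
            lo = mid
        else:
            hi = mid
    return lo + (hi - lo) / 2


def psa_sun_events(
    date: dt.date, latitude: float, longitude: float, utc_offset_hours: float
) -> tuple[dt.datetime, dt.datetime]:
    """(sunrise, sunset) in local civil time on `date` via the PSA oracle."""
    offset = dt.timedelta(hours=utc_offset_hours)
    local_midnight = dt.datetime.combine(date, dt.time())
    noon_utc = local_midnight + dt.timedelta(hours=12) - offset
    start_utc = local_midnight - offset
    end_utc = local_midnight + dt.timedelta(hours=24) - offset
    sunrise_utc = _bisect_crossing(start_utc, noon_utc, latitude, longitude, rising=True)
    sunset_utc = _bisect_crossing(noon_utc, end_utc, latitude, longitude, rising=False)
    return sunrise_utc + offset, sunset_utc + offset
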