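"""Solar geometry: NOAA solar-calculator equations and elevation binning.

The position algorithm follows NOAA's solar calculator (the Meeus-based
spreadsheet equations: mean longitude/anomaly in Julian centuries,
equation of centre, apparent longitude, true obliquity, then equation of
time and declination -> hour angle -> zenith/azimuth). Accuracy is a few
thousandths of a degree over the satellite era, far inside the 0.2 deg
target that a 3 deg elevation-binning scheme needs. (The simpler
fractional-year Fourier series was tried first and rejected: its
equation-of-time/declination truncation leaves worst-case elevation
errors above 0.2 deg.) No atmospheric refraction correction is applied:
refraction matters only below ~1 deg elevation, which falls in
near-night bins that never enter calibration fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .site import SiteConfig

#: Sentinel bin index for timestamps with the sun below the horizon.
NIGHT_BIN = -1


@dataclass(frozen=True)
class SolarPosition:
    """Solar geometry at one instant.

    All angles in degrees; ``timestamp`` is timezone-aware UTC.
    ``noon_elevation_deg`` is the solar-noon elevation of the civil day
    (in site local time) containing the timestamp.
    """

    timestamp: datetime
    elevation_deg: float
    azimuth_deg: float
    declination_deg: float
    noon_elevation_deg: float


def _to_utc_index(timestamps) -> pd.DatetimeIndex:
    """Coerce scalar/array timestamps to a tz-aware UTC DatetimeIndex."""
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype=object)))
    if idx.tz is None:
        raise ValueError(
            "timestamps must be timezone-aware; attach a UTC offset before "
            "computing solar position"
        )
    return idx.tz_convert("UTC")

def _eqtime_declination(utc: pd.DatetimeIndex):
    """Equation of time (minutes) and solar declination (radians).

    NOAA solar-calculator equations: Julian centuries since J2000, mean
    longitude and anomaly, equation of centre, apparent longitude and
    true obliquity (with the principal nutation term).
    """
    t = (utc.to_julian_date().to_numpy() - 2451545.0) / 36525.0

    l0 = np.deg2rad((280.46646 + 36000.76983 * t + 0.0003032 * t**2) % 360.0)
    m = np.deg2rad((357.52911 + 35999.05029 * t - 0.0001537 * t**2) % 360.0)
    ecc = 0.016708634 - 0.000042037 * t - 0.0000001267 * t**2

    centre = (
        (1.914602 - 0.004817 * t - 0.000014 * t**2) * np.sin(m)
        + (0.019993 - 0.000101 * t) * np.sin(2 * m)
        + 0.000289 * np.sin(3 * m)
    )
    true_long_deg = np.rad2deg(l0) + centre
    omega = np.deg2rad(125.04 - 1934.136 * t)
    app_long = np.deg2rad(true_long_deg - 0.00569 - 0.00478 * np.sin(omega))

    mean_obliq = (
        23.0 + (26.0 + (21.448 - t * (46.8150 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    )
    obliq = np.deg2rad(mean_obliq + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))

    y = np.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * np.rad2deg(
        y * np.sin(2 * l0)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0)
        - 0.5 * y**2 * np.sin(4 * l0)
        - 1.25 * ecc**2 * np.sin(2 * m)
    )
    return eqtime, decl


def _angles(utc: pd.DatetimeIndex, lat_deg: float, lon_deg: float):
    """Elevation, azimuth, declination (degrees) for UTC timestamps."""
    hour = (
        utc.hour.to_numpy(dtype=float)
        + utc.minute.to_numpy(dtype=float) / 60.0
        + utc.second.to_numpy(dtype=float) / 3600.0
        + utc.microsecond.to_numpy(dtype=float) / 3.6e9
    )
    eqtime, decl = _eqtime_declination(utc)

    # True solar time in minutes (timezone handled by working in UTC).
    tst = hour * 60.0 + eqtime + 4.0 * lon_deg
    ha = np.deg2rad(tst / 4.0 - 180.0)

    lat = np.deg2rad(lat_deg)
    cos_zen = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    elevation = 90.0 - np.rad2deg(np.arccos(cos_zen))

    # Azimuth measured from south (west positive), shifted to
    # north-clockwise convention.
    az_south = np.arctan2(
        np.sin(ha), np.cos(ha) * np.sin(lat) - np.tan(decl) * np.cos(lat)
    )
    azimuth = (np.rad2deg(az_south) + 180.0) % 360.0
    return elevation, azimuth, np.rad2deg(decl)


def noon_elevation(site: SiteConfig, civil_date) -> float:
    """Solar-noon elevation (deg) for a civil date at the site.

    Solar noon is located from the equation of time; the elevation there
    reduces to 90 - |latitude - declination|.
    """
    day = pd.Timestamp(civil_date)
    if day.tz is not None:
        day = day.tz_convert(None)
    # Approximate local solar noon in UTC, then refine declination there.
    approx = pd.DatetimeIndex(
        [day + pd.Timedelta(hours=12.0 - site.longitude_deg / 15.0)]
    ).tz_localize("UTC")
    eqtime = float(_eqtime_declination(approx)[0][0])
    noon_utc = pd.DatetimeIndex(
        [day + pd.Timedelta(minutes=720.0 - 4.0 * site.longitude_deg - eqtime)]
    ).tz_localize("UTC")
    decl = float(np.rad2deg(_eqtime_declination(noon_utc)[1])[0])
    return 90.0 - abs(site.latitude_deg - decl)


def solar_position(site: SiteConfig, timestamp: datetime) -> SolarPosition:
    """Full solar geometry for one timezone-aware timestamp."""
    utc = _to_utc_index([timestamp])
    elev, az, decl = _angles(utc, site.latitude_deg, site.longitude_deg)
    local_day = utc.tz_convert(None) + pd.Timedelta(hours=site.utc_offset_h)
    return SolarPosition(
        timestamp=utc[0].to_pydatetime(warn=False),
        elevation_deg=float(elev[0]),
        azimuth_deg=float(az[0]),
        declination_deg=float(decl[0]),
        noon_elevation_deg=noon_elevation(site, local_day.normalize()[0]),
    )


def solar_position_series(site: SiteConfig, timestamps) -> pd.DataFrame:
    """Vectorised solar geometry.

    Returns a DataFrame indexed by the (UTC) timestamps with columns
    ``elevation_deg``, ``azimuth_deg``, ``declination_deg`` and
    ``noon_elevation_deg`` (per civil day at the site).
    """
    utc = _to_utc_index(timestamps)
    elev, az, decl = _angles(utc, site.latitude_deg, site.longitude_deg)
    local_days = (utc.tz_convert(None) + pd.Timedelta(hours=site.utc_offset_h)).normalize()
    noon = pd.Series(local_days).map(
        {d: noon_elevation(site, d) for d in local_days.unique()}
    )
    return pd.DataFrame(
        {
            "elevation_deg": elev,
            "azimuth_deg": az,
            "declination_deg": decl,
            "noon_elevation_deg": noon.to_numpy(),
        },
        index=utc,
    )


def elevation_bin(elevation_deg, bin_width_deg: float = 3.0):
    """Map solar elevation to its bin index (lower-edge label).

    Bins are half-open ``[k*w, (k+1)*w)``; any elevation below the
    horizon maps to :data:`NIGHT_BIN`. Accepts scalars or arrays.
    """
    if bin_width_deg <= 0:
        raise ValueError("bin width must be positive")
    el = np.asarray(elevation_deg, dtype=float)
    idx = np.floor(el / bin_width_deg).astype(int)
    idx = np.where(el < 0.0, NIGHT_BIN, idx)
    if np.isscalar(elevation_deg):
        return int(idx)
    return idx


def bin_lower_edge(bin_index, bin_width_deg: float = 3.0):
    """Lower elevation edge (deg) of a bin index."""
    return np.asarray(bin_index) * bin_width_deg


def bin_center(bin_index, bin_width_deg: float = 3.0):
    """Centre elevation (deg) of a bin index."""
    return (np.asarray(bin_index) + 0.5) * bin_width_deg
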