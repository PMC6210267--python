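"""Clear-sky global radiation (Ryan-Stolzenbach) and percent illumination.

The Ryan-Stolzenbach model gives clear-sky global radiation on a
horizontal surface as

    I = I0 * atc**m * sin(el)

where ``atc`` is a bulk atmospheric transmission coefficient (valid
0.70-0.91), ``el`` the solar elevation and ``m`` the relative optical
air mass corrected for site altitude:

    m = [(288 - 0.0065 z) / 288]**5.256
        / (sin(el) + 0.15 * (el_deg + 3.885)**-1.253)

Percent illumination is measured global radiation as a fraction of the
modelled clear-sky value; it is the driver of the cross-calibration
functions. Values above 100% (cloud-edge enhancement) are retained; the
calibration lookup clamps to its fitted range separately.
"""

from __future__ import annotations

import numpy as np

from .site import SiteConfig

SOLAR_CONSTANT_WM2 = 1367.0

#: Modelled clear-sky radiation below this floor (W m-2) makes the
#: measured/modelled ratio numerically meaningless (dawn/dusk); the
#: illumination is flagged missing instead.
ILLUMINATION_FLOOR_WM2 = 10.0

#: Illumination cap used when evaluating calibration functions: keeps
#: cloud-enhancement points (>100%) usable without extrapolating the
#: fitted functions far beyond their 15-100% support.
ILLUMINATION_CAP_PCT = 120.0


def eccentricity_factor(doy):
    """Earth-Sun distance correction to the solar constant."""
    return 1.0 + 0.033 * np.cos(2.0 * np.pi * np.asarray(doy, dtype=float) / 365.0)


def optical_air_mass(elevation_deg, altitude_m: float):
    """Altitude-corrected relative optical air mass (Kasten-style)."""
    el = np.asarray(elevation_deg, dtype=float)
    pressure_ratio = ((288.0 - 0.0065 * altitude_m) / 288.0) ** 5.256
    denom = np.sin(np.deg2rad(el)) + 0.15 * (el + 3.885) ** -1.253
    return pressure_ratio / denom


def modeled_clear_sky(site: SiteConfig, elevation_deg, doy=None):
    """Clear-sky global radiation, W m-2; 0 for the sun at/below horizon.

    ``doy`` (day of year) enables the Earth-Sun distance factor; omitted,
    mean distance is assumed.
    """
    if not 0.70 <= site.atc <= 0.91:
        raise ValueError(f"atc {site.atc} outside valid range [0.70, 0.91]")
    el = np.asarray(elevation_deg, dtype=float)
    i0 = SOLAR_CONSTANT_WM2 * (1.0 if doy is None else eccentricity_factor(doy))
    with np.errstate(invalid="ignore"):
        m = optical_air_mass(np.maximum(el, 1e-6), site.altitude_m)
        out = i0 * site.atc**m * np.sin(np.deg2rad(el))
    out = np.where(el <= 0.0, 0.0, out)
    if np.isscalar(elevation_deg) and out.ndim == 0:
        return float(out)
    return out


def percent_illumination(measured_wm2, modeled_wm2, floor_wm2: float = ILLUMINATION_FLOOR_WM2):
    """Measured global radiation as a percentage of the clear-sky model.

    Returns NaN wherever the modelled value is below ``floor_wm2``
    (sun near or below the horizon), so low-sun ratios never blow up.
    Values above 100% are returned as-is.
    """
    measured = np.asarray(measured_wm2, dtype=float)
    modeled = np.asarray(modeled_wm2, dtype=float)
    if np.any(modeled < 0):
        raise ValueError("modelled clear-sky radiation must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * measured / modeled
    pct = np.where(modeled < floor_wm2, np.nan, pct)
    if np.isscalar(measured_wm2) and pct.ndim == 0:
        return float(pct)
    return pct
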