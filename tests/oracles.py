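"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the solar oracle is
the Michalsky (1988) Astronomical Almanac algorithm (valid 1950-2050),
distinct from the package's NOAA Fourier-series formulation; the
light-response oracle is a brute-force grid search.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def michalsky_elevation(lat_deg: float, lon_deg: float, timestamp) -> float:
    """Solar elevation (deg, no refraction) via the Astronomical Almanac
    low-precision algorithm."""
    t = pd.Timestamp(timestamp)
    if t.tz is None:
        raise ValueError("oracle needs tz-aware timestamps")
    t = t.tz_convert("UTC")
    jd = t.to_julian_date()
    n = jd - 2451545.0

    mnlong = (280.460 + 0.9856474 * n) % 360.0
    mnanom = np.deg2rad((357.528 + 0.9856003 * n) % 360.0)
    eclong = np.deg2rad(
        (mnlong + 1.915 * np.sin(mnanom) + 0.020 * np.sin(2 * mnanom)) % 360.0
    )
    oblqec = np.deg2rad(23.439 - 4.0e-7 * n)

    ra = np.arctan2(np.cos(oblqec) * np.sin(eclong), np.cos(eclong))
    dec = np.arcsin(np.sin(oblqec) * np.sin(eclong))

    hour_ut = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
    gmst = (6.697375 + 0.0657098242 * n + hour_ut) % 24.0
    lmst = np.deg2rad(((gmst + lon_deg / 15.0) % 24.0) * 15.0)
    ha = lmst - ra
    lat = np.deg2rad(lat_deg)
    el = np.arcsin(
        np.sin(dec) * np.sin(lat) + np.cos(dec) * np.cos(lat) * np.cos(ha)
    )
    return float(np.rad2deg(el))


def _lr_model(ppfd, tair, amax, alpha, r10, q10):
    return -(amax * alpha * ppfd) / (amax + alpha * ppfd) + r10 * q10 ** (
        (tair - 10.0) / 10.0
    )


def grid_search_light_response(ppfd, tair, nee, passes: int = 8, n_grid: int = 11):
    """Brute-force light-response fit: coarse 4-D grid, then refinement.

    Each pass re-grids a box of +-3 previous steps around the incumbent:
    the box shrinks slowly enough to walk along the ridges that the
    model's correlated parameter pairs produce. Returns ``(params, sse,
    steps)`` with ``steps`` the final grid resolution per parameter.
    """
    ppfd = np.asarray(ppfd, dtype=float)
    tair = np.asarray(tair, dtype=float)
    nee = np.asarray(nee, dtype=float)
    lo = np.array([1.0, 0.001, 0.1, 1.0])
    hi = np.array([45.0, 0.12, 6.0, 4.0])
    best = None
    for _ in range(passes):
        axes = [np.linspace(lo[k], hi[k], n_grid) for k in range(4)]
        grids = np.meshgrid(*axes, indexing="ij")
        theta = np.stack([g.ravel() for g in grids], axis=1)
        model = _lr_model(
            ppfd[None, :], tair[None, :],
            theta[:, 0:1], theta[:, 1:2], theta[:, 2:3], theta[:, 3:4],
        )
        sse = np.sum((nee[None, :] - model) ** 2, axis=1)
        i = int(np.argmin(sse))
        best = theta[i]
        steps = (hi - lo) / (n_grid - 1)
        lo = np.maximum(best - 3 * steps, [1e-3, 1e-5, 0.0, 1.0])
        hi = best + 3 * steps
    return best, float(sse[i]), steps
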