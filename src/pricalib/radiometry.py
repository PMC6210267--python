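"""Reflectance, PRI/sPRI, broadband NDVI, precipitation filter, 30-min bins.

All spectral math is ratio-based in logger machine units: the paired
narrowband radiometers report a downward-looking radiance channel (36 deg
field stop) and an upward-looking irradiance channel (cosine diffuser)
per band (532 and 570 nm), and reflectance is simply radiance/irradiance.
Machine units cancel in every downstream index, so no absolute radiometric
conversion is ever applied.

Fixed processing order: precipitation filter -> per-minute reflectance and
PRI -> cross-calibration correction -> 30-min binning. Filtering before
binning prevents droplet-noise minutes from biasing window means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BANDS = (532, 570)

#: Default exclusion window around precipitation events.
PRECIP_WINDOW = pd.Timedelta(minutes=30)


def reflectance(radiance, irradiance):
    """Uncorrected reflectance r/i; NaN where irradiance <= 0."""
    r = np.asarray(radiance, dtype=float)
    i = np.asarray(irradiance, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(i > 0, r / np.where(i > 0, i, 1.0), np.nan)
    if np.isscalar(radiance) and rho.ndim == 0:
        return float(rho)
    return rho


def pri(rho532, rho570):
    """Photochemical reflectance index (rho532 - rho570)/(rho532 + rho570)."""
    a = np.asarray(rho532, dtype=float)
    b = np.asarray(rho570, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / np.where(denom != 0, denom, 1.0), np.nan)
    if np.isscalar(rho532) and out.ndim == 0:
        return float(out)
    return out


def spri(pri_values):
    """Scaled PRI, (1 + PRI)/2, mapping [-1, 1] onto [0, 1]."""
    out = (1.0 + np.asarray(pri_values, dtype=float)) / 2.0
    if np.isscalar(pri_values) and out.ndim == 0:
        return float(out)
    return out


def pri_from_spri(spri_values):
    """Inverse of :func:`spri`."""
    out = 2.0 * np.asarray(spri_values, dtype=float) - 1.0
    if np.isscalar(spri_values) and out.ndim == 0:
        return float(out)
    return out


def broadband_ndvi(rho_pyr, rho_ppfd):
    """Broadband NDVI from pyranometer and quantum-sensor reflectances.

    ``rho_pyr`` is the shortwave (pyranometer) albedo, ``rho_ppfd`` the
    PAR-band (quantum sensor) albedo; green canopies absorb PAR strongly,
    so the normalised difference behaves like narrowband NDVI.
    """
    return pri(rho_pyr, rho_ppfd)  # same normalised-difference algebra


def filter_precipitation(
    df: pd.DataFrame,
    precip: pd.Series,
    window: pd.Timedelta = PRECIP_WINDOW,
) -> pd.DataFrame:
    """Drop rows inside [event start - window, event end + window].

    ``precip`` is a time-indexed series of precipitation amounts; any
    strictly positive value marks an event timestamp. Water on the cosine
    diffusers corrupts the optical signal well beyond the event itself,
    hence the symmetric guard window (default 30 min).
    """
    if precip.empty or not (precip.fillna(0) > 0).any():
        return df
    events = precip.index[precip.fillna(0) > 0]
    keep = np.ones(len(df), dtype=bool)
    times = df.index
    # Merge contiguous event timestamps into intervals before masking.
    ev = pd.Series(events).sort_values()
    gaps = ev.diff() > window
    group = gaps.cumsum()
    for _, chunk in ev.groupby(group):
        start = chunk.iloc[0] - window
        end = chunk.iloc[-1] + window
        keep &= ~((times >= start) & (times <= end))
    return df.loc[keep]


def bin_halfhour(data, min_coverage: float = 0.5):
    """Average a time-indexed Series/DataFrame into :00/:30 half-hours.

    Windows are half-open [t, t+30min). A window keeps its mean only if at
    least ``min_coverage`` of the expected samples (inferred from the
    median sampling interval) are present and non-missing; sparser windows
    are set to NaN.
    """
    obj = data if isinstance(data, (pd.Series, pd.DataFrame)) else pd.Series(data)
    if len(obj) == 0:
        return obj
    step = obj.index.to_series().diff().median()
    expected = max(int(pd.Timedelta(minutes=30) / step), 1) if pd.notna(step) else 1
    grouped = obj.resample("30min", label="left", closed="left")
    mean = grouped.mean()
    count = grouped.count()
    mask = count < min_coverage * expected
    if isinstance(mean, pd.DataFrame):
        return mean.mask(mask)
    return mean.mask(mask)


def read_logger_csv(path) -> pd.DataFrame:
    """Read a logger-dialect CSV (ISO 8601 ``timestamp`` column, empty cell
    = missing) into a time-indexed DataFrame."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df.set_index("timestamp").sort_index()


def write_logger_csv(df: pd.DataFrame, path) -> None:
    """Write a time-indexed DataFrame back to the logger CSV dialect."""
    out = df.reset_index()
    out = out.rename(columns={out.columns[0]: "timestamp"})
    out.to_csv(path, index=False)
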