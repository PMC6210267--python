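"""White-panel cross-calibration of paired radiance/irradiance fore-optics.

A downward-looking radiance sensor (field stop) and an upward-looking
irradiance sensor (cosine diffuser) do not share a spectral/angular
response, and their relative response drifts with sky condition. Logging
both over a near-Lambertian white standard panel yields a
*cross-calibration ratio* (panel radiance / sky irradiance, machine
units) whose dependence on percent illumination is close to linear
within each 3 deg solar-elevation bin. Fitting that line per (band, bin)
gives a set of calibration functions; dividing an uncorrected field
reflectance by the looked-up ratio yields corrected reflectance:

    rho_corrected = rho_uncorrected / ratio
                  = (r_target / i_sky) / (r_standard / i_sky)

Two application modes exist: *diurnal* (ratio follows the instantaneous
solar elevation bin) and *midday* (all of a day's points use the bin of
that day's solar-noon elevation). Diurnal correction resolves
morning/evening geometry that midday correction cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from . import radiometry, solar
from .clearsky import ILLUMINATION_CAP_PCT
from .site import SiteConfig

#: Reflectance factor of the white standard panel (Spectralon).
PANEL_REFLECTANCE = 0.99

#: Minimum within-bin illumination spread (percent, std dev) for a
#: meaningful slope estimate.
MIN_ILLUM_SPREAD_PCT = 2.0


def theoretical_panel_ratio(reflectance_factor: float = 1.0) -> float:
    """Radiance/irradiance ratio of an ideal diffuse (Lambertian) reflector.

    A Lambertian surface under irradiance E radiates L = rho * E / pi, so
    the ratio is ``reflectance_factor / pi`` — about 0.318 for an ideal
    (rho = 1) panel. Measured cross-calibration ratios should scatter
    around this value when fore-optic gains are matched.
    """
    return reflectance_factor / np.pi


@dataclass(frozen=True)
class BinCalibration:
    """One fitted calibration line: ratio = slope * illumination + intercept."""

    slope: float
    intercept: float
    n: int
    r2: float
    illum_min: float
    illum_max: float

    def ratio_at(self, illumination_pct: float) -> float:
        """Evaluate the line with illumination clamped to the fit range."""
        x = float(np.clip(illumination_pct, self.illum_min, self.illum_max))
        return self.slope * x + self.intercept


@dataclass
class CalibrationFunctionSet:
    """Per-band, per-elevation-bin calibration lines.

    ``functions[band][bin_index]`` holds a :class:`BinCalibration`. Bins
    that failed the minimum-n or illumination-spread rules are absent;
    lookups fall back to the nearest retained bin (and report the
    fallback) so that peak-summer elevations above the calibration
    campaign's span remain correctable.
    """

    bin_width_deg: float = 3.0
    functions: dict[int, dict[int, BinCalibration]] = field(default_factory=dict)

    def bands(self):
        return sorted(self.functions)

    def bins(self, band: int):
        return sorted(self.functions[band])

    def lookup(self, band: int, bin_index: int) -> tuple[BinCalibration, bool]:
        """Calibration for a bin, falling back to the nearest retained bin.

        Returns ``(calibration, exact)`` where ``exact`` is False when a
        neighbouring bin was substituted.
        """
        try:
            per_band = self.functions[band]
        except KeyError:
            raise KeyError(f"no calibration functions for band {band}") from None
        if not per_band:
            raise ValueError(f"calibration set for band {band} is empty")
        if bin_index in per_band:
            return per_band[bin_index], True
        nearest = min(per_band, key=lambda b: (abs(b - bin_index), b))
        return per_band[nearest], False

    def to_json(self, path=None):
        payload = {
            "bin_width_deg": self.bin_width_deg,
            "functions": {
                str(band): {
                    str(b): vars(c) for b, c in per_band.items()
                }
                for band, per_band in self.functions.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationFunctionSet":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        funcs = {
            int(band): {
                int(b): BinCalibration(**c) for b, c in per_band.items()
            }
            for band, per_band in payload["functions"].items()
        }
        return cls(bin_width_deg=payload["bin_width_deg"], functions=funcs)


def fit_calibration(
    panel: pd.DataFrame,
    site: SiteConfig,
    min_n: int = 20,
    illum_cap_pct: float = ILLUMINATION_CAP_PCT,
) -> CalibrationFunctionSet:
    """Fit per-(band, bin) calibration lines from panel observations.

    ``panel`` needs columns ``band``, ``r_standard``, ``i_sky``,
    ``illumination_pct`` and ``elevation_deg``. Rows with non-positive
    sky irradiance, missing illumination, or the sun below the horizon
    are discarded; illumination is capped at ``illum_cap_pct`` before
    fitting. Ordinary least squares of ratio on illumination per bin;
    bins with fewer than ``min_n`` rows or degenerate illumination
    spread are omitted.
    """
    required = {"band", "r_standard", "i_sky", "illumination_pct", "elevation_deg"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel observations missing columns: {sorted(missing)}")
    data = panel.loc[
        (panel["i_sky"] > 0)
        & panel["illumination_pct"].notna()
        & (panel["elevation_deg"] > 0)
    ].copy()
    if data.empty:
        raise ValueError("no usable panel observations")
    data["ratio"] = data["r_standard"] / data["i_sky"]
    data["illum"] = data["illumination_pct"].clip(upper=illum_cap_pct)
    data["bin"] = solar.elevation_bin(
        data["elevation_deg"].to_numpy(), site.elevation_bin_width_deg
    )

    calset = CalibrationFunctionSet(bin_width_deg=site.elevation_bin_width_deg)
    for (band, b), grp in data.groupby(["band", "bin"]):
        if b == solar.NIGHT_BIN or len(grp) < min_n:
            continue
        illum = grp["illum"].to_numpy()
        if np.std(illum) < MIN_ILLUM_SPREAD_PCT:
            continue
        fit = stats.linregress(illum, grp["ratio"].to_numpy())
        calset.functions.setdefault(int(band), {})[int(b)] = BinCalibration(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            n=int(len(grp)),
            r2=float(fit.rvalue**2),
            illum_min=float(illum.min()),
            illum_max=float(illum.max()),
        )
    return calset


Mode = Literal["diurnal", "midday"]


def correction_ratio(
    calset: CalibrationFunctionSet,
    band: int,
    elevation_deg: float,
    illumination_pct: float,
    mode: Mode = "diurnal",
    noon_elevation_deg: float | None = None,
) -> float:
    """Cross-calibration ratio for one observation.

    Diurnal mode selects the bin of the instantaneous solar elevation;
    midday mode the bin of that day's solar-noon elevation (required via
    ``noon_elevation_deg``). Illumination is clamped to the bin's fitted
    range, never extrapolated (fitted slopes are negative: extrapolation
    could drive the ratio through zero).
    """
    if mode == "midday":
        if noon_elevation_deg is None:
            raise ValueError("midday mode requires noon_elevation_deg")
        sel_elev = noon_elevation_deg
    else:
        sel_elev = elevation_deg
    b = solar.elevation_bin(sel_elev, calset.bin_width_deg)
    cal, _ = calset.lookup(band, int(b))
    return cal.ratio_at(illumination_pct)


def correct_reflectance(rho_uncorrected, ratio):
    """Corrected reflectance rho/ratio; NaN where the ratio is <= 0."""
    rho = np.asarray(rho_uncorrected, dtype=float)
    r = np.asarray(ratio, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, rho / np.where(r > 0, r, 1.0), np.nan)
    if np.isscalar(rho_uncorrected) and out.ndim == 0:
        return float(out)
    return out


def _ratio_series(
    calset: CalibrationFunctionSet,
    band: int,
    elevation: np.ndarray,
    illumination: np.ndarray,
) -> np.ndarray:
    """Vectorised bin lookup + line evaluation for one band."""
    bins = solar.elevation_bin(elevation, calset.bin_width_deg)
    out = np.full(len(bins), np.nan)
    day = bins != solar.NIGHT_BIN
    for b in np.unique(bins[day]):
        cal, _ = calset.lookup(band, int(b))
        sel = bins == b
        x = np.clip(illumination[sel], cal.illum_min, cal.illum_max)
        out[sel] = cal.slope * x + cal.intercept
    out[np.isnan(illumination)] = np.nan
    return out


def apply_correction(
    optical: pd.DataFrame,
    calset: CalibrationFunctionSet,
    elevation_deg: pd.Series,
    illumination_pct: pd.Series,
    mode: Mode = "diurnal",
    noon_elevation_deg: pd.Series | None = None,
) -> pd.DataFrame:
    """Correct a two-band reflectance frame and recompute PRI/sPRI.

    ``optical`` must carry ``rho532``/``rho570`` (uncorrected, machine
    ratio). Returns a copy with corrected reflectances, ``pri`` and
    ``spri`` columns, and a ``corrected`` flag naming the mode.
    """
    elev = elevation_deg.reindex(optical.index).to_numpy(dtype=float)
    illum = illumination_pct.reindex(optical.index).to_numpy(dtype=float)
    if mode == "midday":
        if noon_elevation_deg is None:
            raise ValueError("midday mode requires noon_elevation_deg")
        sel_elev = noon_elevation_deg.reindex(optical.index).to_numpy(dtype=float)
        # keep night masking based on the true elevation
        sel_elev = np.where(elev < 0, -1.0, sel_elev)
    else:
        sel_elev = elev
    out = optical.copy()
    for band in radiometry.BANDS:
        ratio = _ratio_series(calset, band, sel_elev, illum)
        out[f"rho{band}"] = correct_reflectance(optical[f"rho{band}"].to_numpy(), ratio)
    out["pri"] = radiometry.pri(out["rho532"].to_numpy(), out["rho570"].to_numpy())
    out["spri"] = radiometry.spri(out["pri"].to_numpy())
    out["corrected"] = mode
    return out
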