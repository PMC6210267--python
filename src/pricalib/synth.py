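"""Seeded synthetic data: white-panel campaigns and full canopy/flux seasons.

Everything the pipeline estimates is generated with a known ground
truth so that calibration, phenology, light-response and LUE-model
recovery can be tested end to end. The generator emulates the
measurement system of a boreal deciduous tower site:

* solar geometry at 56.7439 N, -118.3439 E, 867 m (UTC-7);
* stochastic cloudiness (AR(1) in logit space) driving roughly
  15-100% illumination, with mixed-sky days so every elevation bin
  sees a spread of illuminations;
* paired fore-optics whose relative gain varies linearly with percent
  illumination, more steeply at low solar elevation (what the
  cross-calibration corrects), with specular noise that shrinks as
  the sun climbs;
* a double-logistic fAPAR/NDVI season with a maturity -> senescence
  transition, quadratically (saturating) linked NDVI-fAPAR;
* a rectangular-hyperbola flux truth (Amax, alpha, R10, Q10
  trajectories) generating NEE = -GPP + Reco + noise;
* an sPRI signal coupled facultatively to instantaneous LUE during
  maturity and increasingly to canopy structure (fAPAR) during
  senescence.

Identical seed + config give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import clearsky, solar
from .calibration import PANEL_REFLECTANCE
from .site import DEFAULT_SITE, SiteConfig


@dataclass(frozen=True)
class CloudParams:
    """AR(1) cloudiness in logit space, sampled on a 10-min grid."""

    mean_logit: float = 1.2
    persistence: float = 0.95
    sd: float = 0.8
    floor: float = 0.12     # minimum illumination fraction
    ceiling: float = 1.05   # mild cloud-edge enhancement allowed


@dataclass(frozen=True)
class SensorGainParams:
    """Fore-optic relative gain model per band.

    gain = base * (1 + illum_slope[band] * (100 - illum)/100 * w(elev)) with
    the elevation weight w piecewise-constant per 3-deg bin (evaluated
    at bin centres), so the per-bin ratio-illumination truth is exactly
    linear. Ratio noise grows toward low elevations (specular effects).
    """

    base_gain_532: float = 1.05
    base_gain_570: float = 0.93
    # interference filters and diffusers age differently per band, so the
    # illumination sensitivity is band-specific; a common slope would
    # cancel out of the PRI ratio and make correction mode irrelevant
    illum_slope_532: float = 0.14
    illum_slope_570: float = 0.10
    weight_base: float = 0.25
    weight_range: float = 1.25
    weight_ref_deg: float = 60.0
    irr_machine_scale_532: float = 0.8   # machine units per W m-2
    irr_machine_scale_570: float = 1.1
    noise_sd: float = 0.003
    noise_elev_coef: float = 1.5

    def base_gain(self, band: int) -> float:
        return {532: self.base_gain_532, 570: self.base_gain_570}[band]

    def illum_slope(self, band: int) -> float:
        return {532: self.illum_slope_532, 570: self.illum_slope_570}[band]

    def irr_scale(self, band: int) -> float:
        return {532: self.irr_machine_scale_532, 570: self.irr_machine_scale_570}[band]

    def elev_weight(self, elevation_deg, bin_width_deg: float = 3.0):
        bins = solar.elevation_bin(np.maximum(elevation_deg, 0.0), bin_width_deg)
        center = solar.bin_center(np.maximum(bins, 0), bin_width_deg)
        w = self.weight_base + self.weight_range * (1.0 - center / self.weight_ref_deg)
        return np.clip(w, 0.05, None)

    def gain(self, band: int, illumination_pct, elevation_deg):
        w = self.elev_weight(elevation_deg)
        frac = (100.0 - np.asarray(illumination_pct, dtype=float)) / 100.0
        return self.base_gain(band) * (1.0 + self.illum_slope(band) * frac * w)

    def ratio_noise_sd(self, elevation_deg):
        el = np.clip(np.asarray(elevation_deg, dtype=float), 0.0, self.weight_ref_deg)
        return self.noise_sd * (1.0 + self.noise_elev_coef * (1.0 - el / self.weight_ref_deg))


@dataclass(frozen=True)
class PhenologyParams:
    """Double-logistic greenness season with a quadratic NDVI->fAPAR map."""

    greenup_doy: float = 135.0
    greenup_tau: float = 7.0
    senescence_transition_doy: float = 233.0  # 21 Aug
    senescence_tau: float = 8.0
    ndvi_min: float = 0.25
    ndvi_max: float = 0.74
    # descending-power quadratic mapping NDVI -> fAPAR (saturating)
    fapar_coeffs: tuple[float, float, float] = (-1.9596, 2.954, -0.3484)
    soil_reflectance: float = 0.10
    canopy_par_reflectance_bare: float = 0.06
    canopy_par_reflectance_drop: float = 0.025
    pyr_albedo: float = 0.16


@dataclass(frozen=True)
class FluxTruthParams:
    """True light-use-efficiency model and respiration trajectories.

    LUE_true = lue_max * capacity(doy) * (1 - npq_coef * P/(P + npq_p0)):
    a seasonal capacity (greenness-scaled, including the senescence
    decline) times a mild light-saturation (non-photochemical quenching)
    factor. GPP_true = LUE_true * fAPAR * PPFD — a saturating light
    response whose initial slope (the true apparent quantum yield) is
    lue_max * capacity * fAPAR. NEE = -GPP_true + Reco_true + noise.
    """

    lue_max: float = 0.028     # mol CO2 / mol photons at low light, peak season
    npq_coef: float = 0.35     # fractional LUE depression at saturating light
    npq_p0: float = 600.0      # umol m-2 s-1, half-saturation of the NPQ term
    capacity_floor: float = 0.03  # leafless canopies fix essentially nothing
    #: photosynthetic capacity declines before the canopy sheds leaves
    #: (chlorophyll breakdown precedes abscission), so the capacity
    #: trajectory's autumn fall leads the fAPAR/NDVI fall by this many days
    capacity_fall_lead_days: float = 12.0
    r10_base: float = 1.2      # umol m-2 s-1
    r10_range: float = 1.5
    q10: float = 2.0
    nee_noise_sd: float = 0.5  # umol m-2 s-1


@dataclass(frozen=True)
class PriCouplingParams:
    """sPRI = f(true LUE, canopy structure) + noise.

    During maturity sPRI tracks instantaneous LUE (facultative,
    xanthophyll-driven). After the transition the physiological coupling
    weakens (``senescence_coupling`` < 1) and a constitutive structural
    term proportional to the fAPAR decline takes over.
    """

    intercept: float = 0.35
    slope: float = 6.0          # sPRI units per LUE unit
    #: timescale (hours) over which the xanthophyll pool integrates the
    #: light environment; sPRI follows LUE smoothed over this window, so
    #: minute-scale cloud flecks are not fully mirrored in the PRI signal
    relaxation_hours: float = 3.0
    senescence_coupling: float = 0.35
    structure_slope: float = 0.25  # sPRI units per fAPAR unit below transition
    # canopy-scale PRI scatter is large (structure, view geometry, shadow
    # fractions); coupling noise is sized accordingly
    noise_sd_maturity: float = 0.035
    noise_sd_senescence: float = 0.03
    rho570_base: float = 0.055
    rho570_drift: float = 0.015


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    site: SiteConfig = DEFAULT_SITE
    panel_start: str = "2015-06-01"
    panel_days: int = 23
    season_start: str = "2015-05-01"
    season_end: str = "2015-10-15"
    cloud: CloudParams = field(default_factory=CloudParams)
    gains: SensorGainParams = field(default_factory=SensorGainParams)
    phenology: PhenologyParams = field(default_factory=PhenologyParams)
    flux: FluxTruthParams = field(default_factory=FluxTruthParams)
    pri: PriCouplingParams = field(default_factory=PriCouplingParams)
    precip_events_per_day: float = 0.12
    precip_mean_minutes: float = 90.0
    par_fraction: float = 0.45
    umol_per_joule_par: float = 4.6
    pyranometer_noise_sd: float = 0.5  # W m-2, per-minute instrument precision

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# --------------------------------------------------------------------------
# shared helpers


def _utc_range(site: SiteConfig, start_local: str, end_local, freq: str) -> pd.DatetimeIndex:
    local = pd.date_range(start_local, end_local, freq=freq, inclusive="left")
    return (local - pd.Timedelta(hours=site.utc_offset_h)).tz_localize("UTC")


def _ar1_cloud(rng: np.random.Generator, n: int, p: CloudParams) -> np.ndarray:
    """Illumination fraction series on the native (10-min) grid."""
    x = np.empty(n)
    stat_sd = p.sd / np.sqrt(1.0 - p.persistence**2)
    x[0] = p.mean_logit + stat_sd * rng.standard_normal()
    eps = rng.standard_normal(n) * p.sd
    for i in range(1, n):
        x[i] = p.mean_logit + p.persistence * (x[i - 1] - p.mean_logit) + eps[i]
    f = 1.0 / (1.0 + np.exp(-x))
    return np.clip(f * 1.1, p.floor, p.ceiling)


def _interp_to(index_coarse: pd.DatetimeIndex, values: np.ndarray,
               index_fine: pd.DatetimeIndex) -> np.ndarray:
    xc = index_coarse.asi8.astype(float)
    xf = index_fine.asi8.astype(float)
    return np.interp(xf, xc, values)


# --------------------------------------------------------------------------
# panel campaign


def panel_truth_table(config: GeneratorConfig) -> pd.DataFrame:
    """Exact per-(band, bin) slope/intercept of ratio vs illumination."""
    g = config.gains
    width = config.site.elevation_bin_width_deg
    rows = []
    lambertian = PANEL_REFLECTANCE / np.pi
    for band in (532, 570):
        base = g.base_gain(band)
        for b in range(int(np.ceil(90.0 / width))):
            center = (b + 0.5) * width
            w = float(np.clip(
                g.weight_base + g.weight_range * (1.0 - center / g.weight_ref_deg),
                0.05, None,
            ))
            slope = -lambertian * base * g.illum_slope(band) * w / 100.0
            intercept = lambertian * base * (1.0 + g.illum_slope(band) * w)
            rows.append({"band": band, "bin": b, "slope_true": slope,
                         "intercept_true": intercept, "elev_weight": w})
    return pd.DataFrame(rows)


def generate_panel_campaign(config: GeneratorConfig):
    """1-min white-panel records over the campaign period.

    Returns ``(panel, truth)``: ``panel`` is a long-format frame indexed
    by UTC timestamp with columns band, r_standard, i_sky, pyr_global;
    ``truth`` the exact per-bin calibration lines (see
    :func:`panel_truth_table`).
    """
    rng = np.random.default_rng(config.seed)
    site = config.site
    start = pd.Timestamp(config.panel_start)
    end = start + pd.Timedelta(days=config.panel_days)
    idx10 = _utc_range(site, start, end, "10min")
    idx1 = _utc_range(site, start, end, "1min")

    f10 = _ar1_cloud(rng, len(idx10), config.cloud)
    f1 = _interp_to(idx10, f10, idx1)

    pos = solar.solar_position_series(site, idx1)
    elev = pos["elevation_deg"].to_numpy()
    doy = idx1.dayofyear.to_numpy(dtype=float)
    cs = clearsky.modeled_clear_sky(site, elev, doy)
    measured = np.clip(
        cs * f1 + rng.normal(0.0, config.pyranometer_noise_sd, len(idx1)), 0.0, None
    )
    measured[elev <= 0] = 0.0
    illum = 100.0 * f1

    frames = []
    lambertian = PANEL_REFLECTANCE / np.pi
    for band in (532, 570):
        gain = config.gains.gain(band, illum, elev)
        ratio_true = lambertian * gain
        noise = rng.normal(0.0, 1.0, len(idx1)) * config.gains.ratio_noise_sd(elev)
        i_sky = measured * config.gains.irr_scale(band)
        r_standard = (ratio_true + noise) * i_sky
        frames.append(
            pd.DataFrame(
                {
                    "band": band,
                    "r_standard": r_standard,
                    "i_sky": i_sky,
                    "pyr_global": measured,
                },
                index=idx1,
            )
        )
    panel = pd.concat(frames).sort_index()
    panel.index.name = "timestamp"
    return panel, panel_truth_table(config)


# --------------------------------------------------------------------------
# season


def _season_shape(doy: np.ndarray, p: PhenologyParams,
                  fall_lead_days: float = 0.0) -> np.ndarray:
    """Double-logistic greenness in [0, 1].

    ``fall_lead_days`` moves the autumn decline earlier without touching
    greenup (used for the physiological-capacity trajectory).
    """
    rise = 1.0 / (1.0 + np.exp(-(doy - p.greenup_doy) / p.greenup_tau))
    # place the falling logistic so that the post-peak curvature extremum
    # (what the NDVI detector estimates) lands on the configured doy
    fall_mid = (
        p.senescence_transition_doy
        + np.log(2.0 + np.sqrt(3.0)) * p.senescence_tau
        - fall_lead_days
    )
    fall = 1.0 / (1.0 + np.exp((doy - fall_mid) / p.senescence_tau))
    s = rise * fall
    return s / s.max()


def _true_transition_doy(doys: np.ndarray, ndvi: np.ndarray) -> float:
    """Curvature-extremum day of the noiseless daily NDVI curve."""
    d2 = np.full(len(ndvi), np.nan)
    d2[1:-1] = ndvi[2:] - 2 * ndvi[1:-1] + ndvi[:-2]
    peak = int(np.argmax(ndvi))
    post = np.arange(len(ndvi)) > peak
    cand = np.where(post & ~np.isnan(d2))[0]
    if cand.size == 0:  # date range ends before any senescence bend
        return float("nan")
    return float(doys[cand[np.argmin(d2[cand])]])


@dataclass
class SeasonData:
    """Generated season: co-registered streams plus ground truth.

    ``optical``: 1-min rad/irr per band + precip; ``broadband``: 10-min
    pyranometer and quantum channels; ``wsn``: 15-min canopy PPFD
    channels; ``flux``: 30-min NEE/met; ``truth`` maps names to truth
    tables (daily phenology, 30-min fluxes/efficiency, calibration
    lines, transition day-of-year).
    """

    optical: pd.DataFrame
    broadband: pd.DataFrame
    wsn: pd.DataFrame
    flux: pd.DataFrame
    truth: dict

    def write(self, directory) -> dict[str, Path]:
        """Write the logger-dialect CSVs (plus truth tables) to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("optical", "broadband", "wsn", "flux"):
            df = getattr(self, name).reset_index()
            df = df.rename(columns={df.columns[0]: "timestamp"})
            paths[name] = directory / f"{name}.csv"
            df.to_csv(paths[name], index=False)
        for key, tab in self.truth.items():
            if isinstance(tab, pd.DataFrame):
                paths[f"truth_{key}"] = directory / f"truth_{key}.csv"
                tab.to_csv(paths[f"truth_{key}"])
        (directory / "truth_scalars.json").write_text(
            json.dumps({k: v for k, v in self.truth.items()
                        if isinstance(v, (int, float, str))}, indent=2)
        )
        return paths


def generate_season(config: GeneratorConfig) -> SeasonData:
    """Generate one full growing season with ground truth."""
    rng = np.random.default_rng(config.seed + 1)
    site = config.site
    ph = config.phenology
    fx = config.flux
    pc = config.pri

    idx10 = _utc_range(site, config.season_start, config.season_end, "10min")
    local10 = idx10.tz_convert(None) + pd.Timedelta(hours=site.utc_offset_h)
    doy10 = local10.dayofyear.to_numpy(dtype=float)

    # ---- daily phenology truth -------------------------------------------
    days = pd.date_range(config.season_start, config.season_end, freq="D",
                         inclusive="left")
    doys = days.dayofyear.to_numpy(dtype=float)
    shape = _season_shape(doys, ph)
    ndvi_daily = ph.ndvi_min + (ph.ndvi_max - ph.ndvi_min) * shape
    fapar_daily = np.polyval(ph.fapar_coeffs, ndvi_daily)
    r_can_daily = ph.canopy_par_reflectance_bare - ph.canopy_par_reflectance_drop * shape
    t_daily = (1.0 - r_can_daily - fapar_daily) / (1.0 - ph.soil_reflectance)
    transition_doy = _true_transition_doy(doys, ndvi_daily)

    cap_shape = _season_shape(doys, ph, fall_lead_days=fx.capacity_fall_lead_days)
    capacity = fx.capacity_floor + (1.0 - fx.capacity_floor) * cap_shape
    # true apparent quantum yield = initial slope of the light response
    alpha_daily = fx.lue_max * capacity * fapar_daily
    r10_daily = fx.r10_base + fx.r10_range * shape

    daily_truth = pd.DataFrame(
        {
            "doy": doys, "shape": shape, "ndvi_true": ndvi_daily,
            "fapar_true": fapar_daily, "t_true": t_daily, "r_true": r_can_daily,
            "capacity": capacity, "alpha_true": alpha_daily,
            "r10_true": r10_daily,
        },
        index=days,
    )

    def at10(col):
        return np.interp(doy10, doys, daily_truth[col].to_numpy())

    # ---- radiation & met backbone (10-min) -------------------------------
    f10 = _ar1_cloud(rng, len(idx10), config.cloud)
    pos10 = solar.solar_position_series(site, idx10)
    elev10 = pos10["elevation_deg"].to_numpy()
    cs10 = clearsky.modeled_clear_sky(site, elev10, doy10)
    global10 = cs10 * f10
    global10[elev10 <= 0] = 0.0
    ppfd10 = global10 * config.par_fraction * config.umol_per_joule_par

    hour10 = local10.hour.to_numpy(dtype=float) + local10.minute.to_numpy(dtype=float) / 60.0
    t_seas = 3.0 + 15.0 * np.sin(np.pi * np.clip(doy10 - 120.0, 0.0, 180.0) / 180.0)
    tair10 = t_seas + 5.0 * np.cos(2.0 * np.pi * (hour10 - 15.0) / 24.0)
    tair10 = tair10 + np.repeat(
        rng.normal(0.0, 1.5, len(days)), len(idx10) // len(days) + 1
    )[: len(idx10)]

    # ---- flux truth (10-min, later aggregated to 30-min) ------------------
    cap10, r10_10 = at10("capacity"), at10("r10_true")
    fapar10 = at10("fapar_true")
    lue_model10 = fx.lue_max * cap10 * (
        1.0 - fx.npq_coef * ppfd10 / (ppfd10 + fx.npq_p0)
    )
    gpp10 = lue_model10 * fapar10 * ppfd10
    reco10 = r10_10 * fx.q10 ** ((tair10 - 10.0) / 10.0)
    lue10 = np.where(ppfd10 > 1.0, lue_model10, np.nan)

    # ---- sPRI truth (10-min) ---------------------------------------------
    senescent = doy10 >= transition_doy
    fapar_at_trans = float(np.interp(transition_doy, doys, fapar_daily))
    lue_ref = float(np.nanmean(lue10[~senescent]))
    lue_filled = np.where(np.isnan(lue10), lue_ref, lue10)
    # xanthophyll pool integrates light over hours: couple sPRI to the
    # relaxation-smoothed LUE, not to minute-scale flecks
    smooth_steps = max(int(pc.relaxation_hours * 6), 1)  # 10-min grid
    lue_filled = (
        pd.Series(lue_filled).rolling(smooth_steps, center=True, min_periods=1)
        .mean().to_numpy()
    )
    coupling = np.where(senescent, pc.senescence_coupling, 1.0)
    structural = np.where(senescent, pc.structure_slope * (fapar10 - fapar_at_trans), 0.0)
    noise_sd = np.where(senescent, pc.noise_sd_senescence, pc.noise_sd_maturity)
    spri10 = (
        pc.intercept
        + pc.slope * (coupling * lue_filled + (1.0 - coupling) * lue_ref)
        + structural
        + rng.normal(0.0, 1.0, len(idx10)) * noise_sd
    )
    pri10 = 2.0 * spri10 - 1.0
    rho570_10 = pc.rho570_base + pc.rho570_drift * (1.0 - at10("shape"))
    rho532_10 = rho570_10 * (1.0 + pri10) / (1.0 - pri10)

    # ---- 1-min optical stream --------------------------------------------
    idx1 = _utc_range(site, config.season_start, config.season_end, "1min")
    pos1 = solar.solar_position_series(site, idx1)
    elev1 = pos1["elevation_deg"].to_numpy()
    f1 = _interp_to(idx10, f10, idx1)
    doy1 = (idx1.tz_convert(None) + pd.Timedelta(hours=site.utc_offset_h)).dayofyear.to_numpy(dtype=float)
    cs1 = clearsky.modeled_clear_sky(site, elev1, doy1)
    global1 = np.where(elev1 > 0, cs1 * f1, 0.0)
    illum1 = 100.0 * f1
    rho532_1 = _interp_to(idx10, rho532_10, idx1)
    rho570_1 = _interp_to(idx10, rho570_10, idx1)

    # precipitation events
    precip1 = np.zeros(len(idx1))
    n_events = rng.poisson(config.precip_events_per_day *
                           (len(idx1) / 1440.0))
    starts = rng.integers(0, len(idx1), n_events)
    durations = np.maximum(
        rng.exponential(config.precip_mean_minutes, n_events).astype(int), 5
    )
    for s0, d in zip(starts, durations):
        precip1[s0: s0 + d] += rng.gamma(2.0, 0.05, min(d, len(idx1) - s0))
    raining = precip1 > 0

    optical = {"precip_mm": precip1}
    for band, rho_true in ((532, rho532_1), (570, rho570_1)):
        gain = config.gains.gain(band, illum1, elev1)
        ratio_true = gain * rho_true / np.pi
        sd = config.gains.ratio_noise_sd(elev1) * 0.5
        sd = np.where(raining, sd * 20.0, sd)
        ratio_obs = ratio_true + rng.normal(0.0, 1.0, len(idx1)) * sd
        irr = global1 * config.gains.irr_scale(band)
        optical[f"rad{band}"] = ratio_obs * irr
        optical[f"irr{band}"] = irr
    optical_df = pd.DataFrame(optical, index=idx1)
    optical_df.index.name = "timestamp"

    # ---- broadband (10-min) & WSN (15-min) -------------------------------
    ndvi10 = at10("ndvi_true") + rng.normal(0.0, 0.008, len(idx10))
    rho_pyr = ph.pyr_albedo * (1.0 + rng.normal(0.0, 0.02, len(idx10)))
    rho_ppfd = rho_pyr * (1.0 - ndvi10) / (1.0 + ndvi10)
    broadband = pd.DataFrame(
        {
            "pyr_down": global10,
            "pyr_up": rho_pyr * global10,
            "ppfd_down": ppfd10,
            "ppfd_up": rho_ppfd * ppfd10,
        },
        index=idx10,
    )
    broadband.index.name = "timestamp"

    idx15 = _utc_range(site, config.season_start, config.season_end, "15min")
    doy15 = (idx15.tz_convert(None) + pd.Timedelta(hours=site.utc_offset_h)).dayofyear.to_numpy(dtype=float)
    ppfd15 = _interp_to(idx10, ppfd10, idx15)
    t15 = np.interp(doy15, doys, t_daily)
    r15 = np.interp(doy15, doys, r_can_daily)
    mnoise = lambda n: 1.0 + rng.normal(0.0, 0.01, n)  # noqa: E731
    wsn = pd.DataFrame(
        {
            "ppfd_above_down": ppfd15 * mnoise(len(idx15)),
            "ppfd_above_up": r15 * ppfd15 * mnoise(len(idx15)),
            "ppfd_below_down": t15 * ppfd15 * mnoise(len(idx15)),
            "ppfd_below_up": ph.soil_reflectance * t15 * ppfd15 * mnoise(len(idx15)),
        },
        index=idx15,
    )
    wsn.index.name = "timestamp"

    # ---- 30-min flux records ---------------------------------------------
    back = pd.DataFrame(
        {"ppfd": ppfd10, "tair": tair10, "gpp_true": gpp10, "reco_true": reco10,
         "fapar_true": fapar10, "lue_true": lue10, "spri_true": spri10,
         "rho532_true": rho532_10, "rho570_true": rho570_10},
        index=idx10,
    )
    flux30 = back.resample("30min", label="left", closed="left").mean()
    n30 = len(flux30)
    night = flux30["ppfd"].to_numpy() < 5.0
    ustar = np.where(
        night,
        rng.lognormal(np.log(0.18), 0.5, n30),
        rng.lognormal(np.log(0.35), 0.4, n30),
    )
    nee = (
        -flux30["gpp_true"].to_numpy()
        + flux30["reco_true"].to_numpy()
        + rng.normal(0.0, fx.nee_noise_sd, n30)
    )
    flux = pd.DataFrame(
        {
            "nee": nee,
            "ustar": ustar,
            "tair": flux30["tair"].to_numpy(),
            "ppfd": flux30["ppfd"].to_numpy(),
            "qc": 0,
        },
        index=flux30.index,
    )
    flux.index.name = "timestamp"

    truth = {
        "daily": daily_truth,
        "halfhour": flux30[["gpp_true", "reco_true", "fapar_true",
                            "lue_true", "spri_true",
                            "rho532_true", "rho570_true", "ppfd", "tair"]],
        "calibration": panel_truth_table(config),
        "transition_doy": transition_doy,
        "q10_true": fx.q10,
    }
    return SeasonData(optical=optical_df, broadband=broadband, wsn=wsn,
                      flux=flux, truth=truth)


def generate_daily_ndvi(config: GeneratorConfig, noise_sd: float = 0.002) -> tuple[pd.Series, float]:
    """Cheap path: one season's noisy daily NDVI plus the true transition
    day-of-year (for phenology-recovery experiments without the full
    optical/flux streams).

    ``noise_sd`` is the noise of the *daily* product: averaging ~25
    near-noon 10-min broadband samples (instrument sd ~0.008) leaves
    about 0.002 on the daily mean, which is what this path emulates.
    """
    rng = np.random.default_rng(config.seed + 2)
    ph = config.phenology
    days = pd.date_range(config.season_start, config.season_end, freq="D",
                         inclusive="left")
    doys = days.dayofyear.to_numpy(dtype=float)
    ndvi = ph.ndvi_min + (ph.ndvi_max - ph.ndvi_min) * _season_shape(doys, ph)
    transition = _true_transition_doy(doys, ndvi)
    noisy = pd.Series(ndvi + rng.normal(0.0, noise_sd, len(days)), index=days)
    return noisy, transition


def simulate_light_response_window(
    amax: float = 20.0,
    alpha: float = 0.03,
    r10: float = 2.0,
    q10: float = 2.0,
    noise_sd: float = 0.0,
    n: int = 48,
    seed: int = 0,
) -> pd.DataFrame:
    """One composite diurnal window generated exactly from the
    rectangular-hyperbola + Q10 model (for fit-recovery experiments)."""
    rng = np.random.default_rng(seed)
    tod = np.arange(n) * (48.0 / n) / 2.0  # hours
    ppfd = 1600.0 * np.clip(np.sin(np.pi * (tod - 4.0) / 16.0), 0.0, None)
    tair = 12.0 + 6.0 * np.cos(2.0 * np.pi * (tod - 15.0) / 24.0)
    gpp = amax * alpha * ppfd / (amax + alpha * ppfd)
    nee = -gpp + r10 * q10 ** ((tair - 10.0) / 10.0)
    nee = nee + rng.normal(0.0, noise_sd, n)
    idx = pd.timedelta_range(0, periods=n, freq=pd.Timedelta(hours=24 / n * 2) / 2)
    return pd.DataFrame({"nee": nee, "ppfd": ppfd, "tair": tair}, index=idx)
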