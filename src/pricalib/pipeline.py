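"""End-to-end pipeline: panel fit -> corrected sPRI -> phenology -> fluxes
-> LUE models and stratified correlations.

The stages mirror a field deployment: a white-panel campaign yields the
calibration function set; the season's optical stream is precipitation-
filtered, converted to reflectance, corrected (diurnal and/or midday)
and binned to 30 min; broadband NDVI locates the senescence transition;
WSN channels give fAPAR/APAR; the flux stream gives GPP, Reco and the
apparent quantum yield alpha; finally sPRI and alpha are evaluated as
LUE proxies, stratified by phenological stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration, canopy, clearsky, flux as fluxmod, lue as luemod, radiometry, solar
from .site import SiteConfig


def prepare_panel(panel: pd.DataFrame, site: SiteConfig) -> pd.DataFrame:
    """Attach solar elevation and percent illumination to raw panel rows.

    ``panel`` carries band, r_standard, i_sky and a co-logged pyranometer
    channel ``pyr_global`` (W m-2) used to derive percent illumination
    against the clear-sky model.
    """
    idx = panel.index
    pos = solar.solar_position_series(site, idx.unique())
    elev = pos["elevation_deg"].reindex(idx)
    doy = idx.tz_convert("UTC").dayofyear.to_numpy(dtype=float)
    modeled = clearsky.modeled_clear_sky(site, elev.to_numpy(), doy)
    out = panel.copy()
    out["elevation_deg"] = elev.to_numpy()
    out["illumination_pct"] = clearsky.percent_illumination(
        out["pyr_global"].to_numpy(), modeled
    )
    return out


def calibrate_from_panel(panel: pd.DataFrame, site: SiteConfig,
                         min_n: int = 20) -> calibration.CalibrationFunctionSet:
    """Convenience wrapper: prepare raw panel rows and fit the function set."""
    prepared = prepare_panel(panel, site)
    return calibration.fit_calibration(prepared, site, min_n=min_n)


def correct_optical(
    optical: pd.DataFrame,
    calset: calibration.CalibrationFunctionSet,
    site: SiteConfig,
    measured_global: pd.Series,
    mode: calibration.Mode = "diurnal",
    precip_window: pd.Timedelta = radiometry.PRECIP_WINDOW,
) -> pd.DataFrame:
    """Filter, correct and 30-min-bin the two-band optical stream.

    ``optical`` is the 1-min logger frame (rad/irr per band + precip_mm);
    ``measured_global`` a co-located pyranometer series (any resolution;
    interpolated to the optical timestamps) used for percent
    illumination. Returns the 30-min frame with corrected rho532/rho570,
    pri and spri.
    """
    filtered = radiometry.filter_precipitation(
        optical, optical["precip_mm"], window=precip_window
    )
    rho = pd.DataFrame(index=filtered.index)
    for band in radiometry.BANDS:
        rho[f"rho{band}"] = radiometry.reflectance(
            filtered[f"rad{band}"].to_numpy(), filtered[f"irr{band}"].to_numpy()
        )

    pos = solar.solar_position_series(site, filtered.index)
    elev = pos["elevation_deg"]
    doy = filtered.index.tz_convert("UTC").dayofyear.to_numpy(dtype=float)
    modeled = clearsky.modeled_clear_sky(site, elev.to_numpy(), doy)
    glob = measured_global.reindex(
        measured_global.index.union(filtered.index)
    ).interpolate(method="time").reindex(filtered.index)
    illum = pd.Series(
        clearsky.percent_illumination(glob.to_numpy(), modeled), index=filtered.index
    )

    corrected = calibration.apply_correction(
        rho, calset, elev, illum, mode=mode,
        noon_elevation_deg=pos["noon_elevation_deg"],
    )
    binned = radiometry.bin_halfhour(
        corrected[["rho532", "rho570", "pri", "spri"]]
    )
    binned["corrected"] = mode
    return binned


def broadband_ndvi_series(broadband: pd.DataFrame) -> pd.Series:
    """10-min broadband NDVI from pyranometer + quantum channel pairs."""
    rho_pyr = radiometry.reflectance(
        broadband["pyr_up"].to_numpy(), broadband["pyr_down"].to_numpy()
    )
    rho_ppfd = radiometry.reflectance(
        broadband["ppfd_up"].to_numpy(), broadband["ppfd_down"].to_numpy()
    )
    return pd.Series(
        radiometry.broadband_ndvi(rho_pyr, rho_ppfd),
        index=broadband.index, name="ndvi",
    )


@dataclass
class PipelineResult:
    """Everything the season pipeline produces."""

    calset: calibration.CalibrationFunctionSet
    spri_diurnal: pd.DataFrame
    spri_midday: pd.DataFrame
    ndvi_daily: pd.Series
    fapar_daily: pd.Series
    ndvi_fapar_coeffs: np.ndarray
    ndvi_fapar_r2: float
    phenology: canopy.PhenologyStage
    halfhour: pd.DataFrame          # co-registered 30-min analysis frame
    light_response: pd.DataFrame    # per-2-day-window fit table
    reco_params: tuple[float, float]
    comparisons: list[luemod.ModelComparison] = field(default_factory=list)
    models: dict = field(default_factory=dict)

    def comparison(self, proxy: str, scope: str) -> luemod.ModelComparison:
        for c in self.comparisons:
            if c.proxy == proxy and c.scope == scope:
                return c
        raise KeyError(f"no comparison {proxy}/{scope}")

    def summary(self) -> str:
        lines = ["Stratified correlations (Pearson r^2):"]
        for c in self.comparisons:
            lines.append(
                f"  {c.proxy:<12s} {c.scope:<11s} r2={c.r2:5.2f}  "
                f"p={c.p_value:8.2e}  n={c.n}"
            )
        lines.append("LUE-model GPP reconstruction:")
        for name, info in self.models.items():
            lines.append(
                f"  {name:<12s} r2 vs observed GPP = {info['gpp_r2']:.2f} "
                f"(n={info['n']})"
            )
        t = self.phenology.transition_date
        lines.append(
            "Senescence transition: "
            + (f"{t.date()} (doy {t.dayofyear})" if t is not None else "not detected")
        )
        return "\n".join(lines)


def run_season_pipeline(
    panel: pd.DataFrame,
    optical: pd.DataFrame,
    broadband: pd.DataFrame,
    wsn: pd.DataFrame,
    flux_records: pd.DataFrame,
    site: SiteConfig,
) -> PipelineResult:
    """Run the complete analysis on co-registered raw streams."""
    # 1. cross-calibration
    calset = calibrate_from_panel(panel, site)

    # 2. corrected sPRI (diurnal for analysis, midday for comparison)
    measured_global = broadband["pyr_down"]
    spri_diurnal = correct_optical(optical, calset, site, measured_global, "diurnal")
    spri_midday = correct_optical(optical, calset, site, measured_global, "midday")

    # 3. phenology from broadband NDVI
    ndvi = broadband_ndvi_series(broadband)
    ndvi_daily = canopy.daily_near_noon_mean(ndvi, site.utc_offset_h)
    stage = canopy.phenology_transition(ndvi_daily)

    # 4. canopy light absorption
    fractions = canopy.wsn_canopy_fractions(wsn)
    fapar_daily = canopy.daily_near_noon_mean(fractions["fapar"], site.utc_offset_h)
    coeffs, nf_r2 = canopy.ndvi_fapar_fit(ndvi_daily, fapar_daily)
    fapar30 = radiometry.bin_halfhour(fractions[["fapar", "ppfd_in"]])

    # 5. fluxes: u* filter, respiration, partitioning, light response
    retained = fluxmod.ustar_filter(flux_records, site.ustar_threshold_ms)
    reco_table, reco = fluxmod.windowed_reco(retained)
    r10, q10 = (float(reco_table["r10"].mean()), float(reco_table["q10"].mean()))
    gpp = pd.Series(
        fluxmod.partition_gpp(retained["nee"].to_numpy(), reco.to_numpy()),
        index=retained.index, name="gpp",
    )
    # daytime only: partitioned GPP at night is noise around zero
    gpp[retained["ppfd"] < fluxmod.NIGHT_PPFD] = 0.0
    lr = fluxmod.season_light_response(retained, site.utc_offset_h)
    good = lr["converged"] & lr["within_bounds"] & lr["alpha_identified"]
    alpha30 = _broadcast_windows(lr.loc[good, "alpha"], retained.index, site)

    # 6. co-registered 30-min analysis frame
    half = pd.DataFrame(index=retained.index)
    half["gpp"] = gpp
    half["ppfd"] = retained["ppfd"]
    half["fapar"] = fapar30["fapar"].reindex(half.index)
    half["apar"] = half["fapar"] * half["ppfd"]
    half["lue"] = luemod.lue(half["gpp"], half["apar"])
    half["spri"] = spri_diurnal["spri"].reindex(half.index)
    half["alpha"] = alpha30
    half["stage"] = stage.label_for(half.index, site.utc_offset_h).to_numpy()
    day = half["ppfd"] >= fluxmod.NIGHT_PPFD
    half = half.loc[day]

    # 7. stratified correlations and LUE models
    comparisons: list[luemod.ModelComparison] = []
    stages = half["stage"]
    comparisons += luemod.stratified_correlation(
        half["spri"], half["lue"], stages, proxy_name="spri-lue")
    comparisons += luemod.stratified_correlation(
        half["spri"], half["alpha"], stages, proxy_name="spri-alpha")
    comparisons += luemod.stratified_correlation(
        half["spri"], half["fapar"], stages, proxy_name="spri-fapar")
    comparisons += luemod.stratified_correlation(
        half["alpha"], half["lue"], stages, proxy_name="alpha-lue")
    comparisons += luemod.stratified_correlation(
        half["apar"], half["gpp"], stages, proxy_name="apar-gpp")

    models = {}
    for proxy in ("spri", "alpha"):
        try:
            model = luemod.fit_lue_model(half[proxy], half["lue"], proxy_name=proxy)
        except ValueError:
            continue
        pred = luemod.predict_gpp(model, half[proxy], half["apar"])
        paired = pd.concat({"pred": pred, "obs": half["gpp"]}, axis=1).dropna()
        r = np.corrcoef(paired["pred"], paired["obs"])[0, 1]
        models[proxy] = {"model": model, "gpp_r2": float(r**2), "n": len(paired)}

    return PipelineResult(
        calset=calset,
        spri_diurnal=spri_diurnal,
        spri_midday=spri_midday,
        ndvi_daily=ndvi_daily,
        fapar_daily=fapar_daily,
        ndvi_fapar_coeffs=coeffs,
        ndvi_fapar_r2=nf_r2,
        phenology=stage,
        halfhour=half,
        light_response=lr,
        reco_params=(r10, q10),
        comparisons=comparisons,
        models=models,
    )


def _broadcast_windows(per_window: pd.Series, index: pd.DatetimeIndex,
                       site: SiteConfig) -> pd.Series:
    """Expand per-2-day-window values onto a 30-min index."""
    if per_window.empty:
        return pd.Series(np.nan, index=index)
    idx = index
    if idx.tz is not None:
        idx = idx.tz_convert(None)
    local_day = (idx + pd.Timedelta(hours=site.utc_offset_h)).normalize()
    day0 = local_day.min()
    window_start = day0 + pd.to_timedelta(
        ((local_day - day0).days // 2) * 2, unit="D"
    )
    mapped = pd.Series(window_start).map(per_window.to_dict())
    return pd.Series(mapped.to_numpy(), index=index)
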