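# Methods

This note documents the models, numerical choices and limitations behind
`pricalib`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Solar geometry (`pricalib.solar`)

Solar position uses the NOAA solar-calculator equations (Meeus-based:
Julian centuries, mean longitude/anomaly, equation of centre, apparent
longitude, true obliquity with the principal nutation term, then
equation of time → hour angle → zenith/azimuth). Worst-case elevation
disagreement with an independent Michalsky-algorithm oracle is ~0.01°
over 1000 random mid-latitude cases (tested). A simpler fractional-year
Fourier series was tried first and rejected: its calendar-year anchoring
drifts with the leap cycle (≈0.4° declination error near equinoxes) and
even a J2000-anchored variant leaves ≈0.24° worst-case error — above
the 0.2° budget a 3° elevation-binning scheme should comfortably hold.

No atmospheric refraction correction: refraction matters below ~1°
elevation, which falls in near-night bins excluded from calibration
fitting (the clear-sky illumination floor removes them). Timestamps are
UTC internally; the site's civil offset is used only at I/O and for
"civil day" constructs (solar-noon elevation, daily aggregation).

Elevation bins are half-open `[k·w, (k+1)·w)` labelled by the lower
edge; sub-horizon elevations map to a night sentinel.

## Clear sky and percent illumination (`pricalib.clearsky`)

Ryan–Stolzenbach clear-sky global radiation:
`I = I0 · atc^m · sin(el)` with `I0 = 1367 W m⁻²` scaled by the
eccentricity factor `1 + 0.033·cos(2π·doy/365)` and the
altitude-corrected optical air mass
`m = [(288 − 0.0065 z)/288]^5.256 / (sin el + 0.15 (el + 3.885)^−1.253)`.
The atmospheric transmission coefficient defaults to 0.8, the midpoint
of the model's documented 0.70–0.91 range, and is configurable per site.

Percent illumination = 100 · measured/modelled. Modelled values below
10 W m⁻² (sun within ~2–3° of the horizon) are flagged missing rather
than divided by — dawn/dusk ratios are numerically meaningless and the
corresponding bins are handled separately by the binning scheme anyway.
Values above 100% (cloud-edge enhancement) are retained; calibration
lookups clamp illumination to each bin's fitted range (never
extrapolate: fitted slopes are negative, extrapolation could cross
ratio ≤ 0), and fitting caps illumination at 120%.

## Radiometry (`pricalib.radiometry`)

All spectral math is ratio-based in logger machine units (no absolute
radiometric conversion — machine units cancel in every index).
Processing order is fixed: precipitation filter → per-minute
reflectance/PRI → cross-calibration correction → 30-min binning.
Filtering first keeps droplet-noise minutes out of window means; the
correction precedes averaging so that each minute is corrected with its
own geometry.

* Precipitation filter: rows within ±30 min (configurable) of any
  positive precipitation reading are dropped; water on the cosine
  diffusers corrupts the signal beyond the event itself.
* 30-min bins are half-open, aligned to :00/:30; a window keeps its mean
  only if ≥50% of expected samples are present. The 50% rule is this
  package's choice (tolerates short optical dropouts while refusing
  mostly-empty windows).

## Cross-calibration (`pricalib.calibration`)

Per band and per 3° elevation bin, the cross-calibration ratio
`r_standard/i_sky` is regressed on percent illumination by ordinary
least squares. Bins need ≥20 points (configurable) and ≥2% illumination
spread; others are omitted. Lookups for omitted bins (e.g. peak-summer
elevations above a calibration campaign's span) fall back to the nearest
retained bin and report the fallback — refusing would discard mid-summer
data. Functions are step-wise per bin (no cross-bin interpolation),
matching the binned procedure.

`theoretical_panel_ratio()` returns the Lambertian radiance/irradiance
ratio ρ/π (≈0.318 for an ideal panel): an L = ρE/π surface viewed by a
radiance fore-optic against a cosine irradiance fore-optic. Fitted
ratios scatter around this value when fore-optic gains are matched. The
0.99 panel reflectance factor is *not* divided out — it cancels in the
PRI band ratio and shifts absolute corrected reflectance by only ~1%.

Correction modes: *diurnal* (bin of the instantaneous elevation) and
*midday* (bin of the day's solar-noon elevation, for every point that
day). Diurnal mode resolves morning/evening gain changes that midday
mode cannot; the acceptance suite verifies the resulting error ordering
on corrected reflectance. On the band-ratio index (PRI) only the
*differential* part of the gain error survives, so the mode difference
is first-order on reflectance but second-order on PRI.

## Canopy light and phenology (`pricalib.canopy`)

fAPAR = 1 − t − r + t·r_s from WSN quantum-sensor channels; APAR =
fAPAR · PPFD. Daily NDVI/fAPAR values are near-noon (10:00–14:00 local)
means, avoiding low-sun artefacts.

The NDVI–fAPAR relation is a degree-2 polynomial least squares of fAPAR
on NDVI (x = NDVI: this orientation reproduces the canonical worked
point NDVI 0.65 ↔ fAPAR ≈ 0.74 when the published coefficients are
evaluated).

Phenology transition: daily NDVI is smoothed with a centred 7-day moving
average and the transition placed at the most negative discrete second
derivative in the post-peak part of the season. The second derivative
uses a **9-day central-difference stencil**: a 1-day stencil on the
smoothed series is dominated by day-scale noise (signal curvature of a
τ≈8-day senescence logistic is ~7×10⁻⁴ NDVI day⁻² against a noise floor
of similar size at realistic daily-product noise), while the 9-day
stencil measures curvature at the bend's own timescale and recovers the
configured transition within ±3 days on 20 seeded seasons. Trade-off:
an abrupt step decline is localised up to one stencil width *early*
(the detector marks the onset of downward curvature). Series whose
post-peak decline is < 0.05 NDVI carry no transition.

## Fluxes (`pricalib.flux`)

Sign convention: NEE = −GPP + Reco, negative NEE = uptake. The u* filter
removes records with u* strictly below 0.21 m s⁻¹ (threshold retained).

**Respiration.** Full moving-window flux-partitioning schemes are out of
scope; Reco comes from a simplified nighttime regression
`NEE_night = R10 · Q10^((Tair−10)/10)` on PPFD < 5 µmol m⁻² s⁻¹ rows.
The default is *windowed* (10-day blocks, ≥30 night rows each; windows
that fail inherit the nearest fitted window's parameters): a single
season-wide fit confounds the seasonal R10 trajectory with temperature
(warm nights coincide with the productive season) and inflates Q10 by
~30% on the synthetic season. A season-wide variant remains available.

**Light response.** NEE = −Amax·α·P/(Amax + α·P) + R10·Q10^((T−10)/10),
fitted per consecutive 2-day block after averaging the block into one
composite diurnal cycle. The optimiser is Gauss–Newton with analytic
Jacobian and step-halving; Levenberg–Marquardt (scipy) is the fallback
on non-convergence. Initialisation: Amax = 95th percentile of −NEE,
α = 0.02, R10 = mean nighttime NEE, Q10 = 2. Fits are flagged when
out of bounds (Amax ≤ 0, α outside (0, 0.125], Q10 outside [1, 4]) and
when α is *unidentified*: the asymptotic standard error from (JᵀJ)⁻¹
must satisfy α > 2·se(α), otherwise the window (little light, vanishing
uptake) contributes a leverage point rather than information and is
excluded from proxy analyses. On noisy windows the parameters trade off
along ridges (Amax–α, R10–Q10, uptake-vs-respiration offsets); the
fitted total NEE model, not individual parameters, is the robustly
identified object, and the test suite's brute-force grid oracle checks
equivalence accordingly.

GPP partitioning: GPP = Reco − NEE, clipped at zero (and set to zero at
night, where partitioned "GPP" is noise).

## LUE models (`pricalib.lue`, `pricalib.pipeline`)

LUE = GPP/APAR on 30-min records, missing where APAR < 50 µmol m⁻² s⁻¹
(dawn/dusk ratio blow-up guard; the value is this package's choice).
LUE models are season-wide linear calibrations lue = a·proxy + b
(maturity-only training is available by slicing), with modelled
GPP = (a·proxy + b)·APAR clipped at zero — so GPP_model/APAR equals the
modelled LUE wherever nothing was clipped. All correlations are Pearson
(matching the linear-regression framing throughout); stratified
correlations report r², two-sided p and n per scope (season, maturity,
senescence), omitting scopes with n < 3.

## The synthetic world (`pricalib.synth`)

The generator emulates the measurement system of a boreal deciduous
(aspen) tower site; every estimated quantity has stored ground truth.
Key defaults and why:

* **Site**: 56.7439° N, 118.3439° W, 867 m, UTC−7. Panel campaign
  1 June + 23 days (elevations 0–56.7°); season 1 May – 15 Oct 2015.
* **Cloudiness**: AR(1) in logit space on a 10-min grid (persistence
  0.95, sd 0.8), clipped to illumination fraction [0.12, 1.05] — mixed
  skies give every elevation bin a spread of illuminations, which the
  calibration design needs; 1.05 allows mild cloud-edge enhancement.
* **PPFD** = global × 0.45 (PAR fraction) × 4.6 µmol J⁻¹ (standard
  conversions); nights exactly zero.
* **Fore-optic gains**: gain = base · (1 + s_band · (100−illum)/100 ·
  w(elev)) with band-specific illumination slopes (0.14 at 532 nm, 0.10
  at 570 nm — filters and diffusers age differently per band; a common
  slope would cancel out of the PRI ratio entirely and make the
  correction mode irrelevant, contrary to field experience). The
  elevation weight w is piecewise-constant per 3° bin, so the per-bin
  ratio–illumination truth is exactly linear and slope/intercept truth
  is well defined. Ratio noise grows toward low elevations (specular
  reflection), giving the boxplot-spread decrease with elevation.
* **Phenology**: double-logistic greenness; NDVI in [0.25, 0.74]; fAPAR
  from a saturating quadratic of NDVI. The configured senescence
  transition day (default 233 = 21 Aug) is defined as the curvature
  extremum of the noiseless daily NDVI curve, and the falling logistic
  is positioned to place it there; the stored truth is computed
  numerically from the noiseless curve.
* **Flux truth / true LUE model**:
  LUE_true = lue_max · capacity(doy) · (1 − npq·P/(P + P₀)) with
  lue_max = 0.028 mol mol⁻¹, npq = 0.35, P₀ = 600 µmol m⁻² s⁻¹;
  GPP_true = LUE_true · fAPAR · P; Reco from R10(doy) ∈ [1.2, 2.7] and
  Q10 = 2; NEE = −GPP + Reco + N(0, 0.5). The capacity's autumn decline
  *leads* the fAPAR decline by 12 days (chlorophyll breakdown precedes
  abscission), which is what separates the physiological (LUE) and
  structural (fAPAR) senescence signals. Off-season capacity floor 0.03:
  leafless canopies fix essentially nothing. The true apparent quantum
  yield is the light response's initial slope, lue_max·capacity·fAPAR.
* **sPRI coupling**: during maturity sPRI = 0.35 + 6·LUE_smoothed + ε
  (facultative coupling; LUE smoothed over a 3-h xanthophyll relaxation
  window — canopy PRI does not mirror minute-scale cloud flecks).
  After the transition the physiological coupling weakens (×0.35) and a
  constitutive structural term 0.25·(fAPAR − fAPAR_transition) takes
  over, with coupling noise 0.035 (maturity) / 0.03 (senescence) sPRI
  units — canopy-scale PRI scatter is large (structure, view geometry,
  shadow fractions).
* **Instrument noise**: pyranometer 0.5 W m⁻² per minute
  (silicon-sensor precision class); broadband NDVI sample noise 0.008;
  WSN channels 1% multiplicative.

What a green test does and does not establish: the generator's biases
are exactly linear per bin and share the pipeline's clear-sky model, so
calibration recovery tests verify the estimator, not the linearity
assumption itself; real fore-optics add azimuth/BRDF structure
(explicitly not modelled — the correction does not account for solar
azimuth), temperature drifts and dark-current effects. The sPRI–LUE
coupling is imposed, so the stratified correlations verify that the
pipeline *recovers the encoded structure* (facultative maturity
coupling, constitutive senescence takeover, α as the stronger proxy),
not that nature behaves this way. The quantitative r² values on
synthetic data are outcomes of the stated world, never calibration
targets.

## Known limitations

* No solar-azimuth/BRDF correction; no per-waveband (spectral)
  clear-sky model.
* The simplified Q10 respiration regression is not a full
  moving-window partitioning; at sites with strong hysteresis between
  soil temperature and respiration it will bias daytime Reco.
* The step-decline phenology case is localised early by up to one
  stencil width (see above).
* Machine-unit ratios assume both channels of a pair are logged
  synchronously; no time-lag handling between radiance and irradiance
  channels.
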