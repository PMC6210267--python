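# pricalib

Cross-calibration of paired narrowband PRI radiometers, and validation of
the photochemical reflectance index (PRI) as a proxy of canopy light use
efficiency (LUE) against eddy-covariance carbon fluxes.

## The problem

Automated two-band spot radiometers (532 nm and 570 nm, one
downward-looking radiance fore-optic and one upward-looking cosine
irradiance fore-optic per band) log continuously on flux towers and
deliver PRI = (ρ532 − ρ570)/(ρ532 + ρ570), a tracker of the
xanthophyll-cycle changes that accompany non-photochemical quenching.
The two fore-optics do not share a spectral/angular response, and their
relative gain drifts with sky condition, so raw band ratios are biased
in a way that varies with percent illumination and solar elevation.
This package implements the offline *diurnal cross-calibration* that
fixes this: the sensor pair logs over a 99% reflective white standard
panel for ~23 days, and the cross-calibration ratio

    ratio = r_standard / i_sky

is regressed on percent illumination within every 3° solar-elevation
bin. Field reflectances are then corrected as

    ρ_corrected = ρ_uncorrected / ratio(elevation bin, illumination)

either per instantaneous elevation (*diurnal* mode) or per daily
solar-noon elevation (*midday* mode). Corrected, scaled PRI
(sPRI = (1 + PRI)/2) is evaluated as an LUE proxy against:

* LUE = GPP/APAR from 30-min eddy-covariance GPP and a wireless sensor
  network's fAPAR (fAPAR = 1 − t − r + t·r_s);
* the apparent quantum yield α from rectangular-hyperbola light-response
  fits, NEE = −Amax·α·P/(Amax + α·P) + R10·Q10^((Tair−10)/10), fit per
  2-day composite diurnal window by Gauss–Newton;
* broadband-NDVI phenology (maturity vs senescence stages split at the
  second-derivative bend of the daily NDVI curve).

Intended users: ecosystem ecologists and proximal-remote-sensing groups
running PRI/NDVI spot radiometers alongside flux towers.

Because no field campaign data are distributed, the package ships a
fully parameterised synthetic-data generator (`pricalib.synth`) that
emulates the measurement system of a boreal aspen site (56.7439° N,
118.3439° W, 867 m) — solar geometry, AR(1) cloudiness,
illumination/elevation-dependent fore-optic gains, double-logistic
phenology, and a light-response flux truth — with ground truth for
every quantity the pipeline estimates.

## Worked example

```python
from pricalib import pipeline, synth

config = synth.GeneratorConfig(seed=1)
panel, cal_truth = synth.generate_panel_campaign(config)   # 23-day white panel
season = synth.generate_season(config)                     # May-October season
result = pipeline.run_season_pipeline(
    panel, season.optical, season.broadband, season.wsn, season.flux,
    config.site,
)
print(result.summary())
```

prints (seed 1):

```
Stratified correlations (Pearson r^2):
  spri-lue     season      r2= 0.70  p=0.00e+00  n=3643
  spri-lue     maturity    r2= 0.55  p=0.00e+00  n=2704
  spri-lue     senescence  r2= 0.30  p=1.26e-75  n=939
  spri-fapar   maturity    r2= 0.54  p=0.00e+00  n=2990
  spri-fapar   senescence  r2= 0.85  p=0.00e+00  n=1159
  alpha-lue    season      r2= 0.76  p=0.00e+00  n=3018
  ...
LUE-model GPP reconstruction:
  spri         r2 vs observed GPP = 0.94 (n=4149)
  alpha        r2 vs observed GPP = 0.99 (n=3436)
Senescence transition: 2015-08-19 (doy 231)
```

Reading it: sPRI tracks LUE more tightly during canopy maturity (r² 0.55,
the facultative xanthophyll signal) than during leaf senescence (0.30),
while its correlation with fAPAR flips the other way (0.54 vs 0.85) —
during senescence the PRI signal is dominated by constitutive
structure/pigment-pool change, not physiology. The 2-day apparent quantum
yield is the stronger season-wide LUE proxy (0.76 vs 0.70), and LUE
models built from either proxy reconstruct GPP as modelled-LUE × APAR.
The NDVI second-derivative detector places the senescence onset at
day-of-year 231 (generator truth: 233).

## Command line

```
pricalib simulate --seed 1 --out data/          # synthetic season + truth
pricalib simulate --seed 1 --campaign --out data/
pricalib calibrate data/panel.csv --out cal.json
pricalib correct data/optical.csv cal.json --global-csv data/broadband.csv --out spri30.csv
pricalib report data/ --out results/            # comparisons.csv + summary.txt
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` regenerates the
seeded panel campaign and season, runs the complete analysis from
scratch, prints the stratified-correlation summary, the number of fitted
calibration functions and the NDVI–fAPAR quadratic, and writes the
result JSON to `--out`.
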