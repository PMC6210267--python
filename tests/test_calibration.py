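"""Cross-calibration fitting, lookup and ratio-correction algebra."""

import numpy as np
import pandas as pd
import pytest

from pricalib import calibration, pipeline, solar
from pricalib.site import DEFAULT_SITE


def _panel_frame(ratio_fn, n=2000, seed=0, noise_sd=0.0, band=532):
    """Synthetic prepared-panel rows with a prescribed ratio(illum) law."""
    rng = np.random.default_rng(seed)
    illum = rng.uniform(15, 100, n)
    elev = rng.uniform(1, 56, n)
    i_sky = rng.uniform(100, 800, n)
    ratio = ratio_fn(illum, elev) + rng.normal(0, noise_sd, n)
    idx = pd.date_range("2015-06-01", periods=n, freq="1min", tz="UTC")
    return pd.DataFrame(
        {
            "band": band,
            "r_standard": ratio * i_sky,
            "i_sky": i_sky,
            "illumination_pct": illum,
            "elevation_deg": elev,
        },
        index=idx,
    )


def test_theoretical_panel_ratio_is_lambertian():
    assert calibration.theoretical_panel_ratio() == pytest.approx(1 / np.pi)


def test_constant_ratio_gives_flat_functions():
    """An ideal panel with ratio 0.318 everywhere: every bin fits slope 0,
    intercept 0.318."""
    panel = _panel_frame(lambda illum, elev: np.full_like(illum, 0.318))
    calset = calibration.fit_calibration(panel, DEFAULT_SITE)
    for b in calset.bins(532):
        cal = calset.functions[532][b]
        assert cal.slope == pytest.approx(0.0, abs=1e-6)
        assert cal.intercept == pytest.approx(0.318, abs=1e-6)


def test_linear_bias_recovered_in_target_bin():
    """ratio = 0.35 - 0.0004*illum in the [39, 42) bin, n=200, noise 0.005:
    slope and intercept recovered within 2%."""
    rng = np.random.default_rng(3)
    illum = rng.uniform(15, 100, 200)
    ratio = 0.35 - 0.0004 * illum + rng.normal(0, 0.005, 200)
    i_sky = np.full(200, 500.0)
    idx = pd.date_range("2015-06-10", periods=200, freq="1min", tz="UTC")
    panel = pd.DataFrame(
        {
            "band": 532,
            "r_standard": ratio * i_sky,
            "i_sky": i_sky,
            "illumination_pct": illum,
            "elevation_deg": rng.uniform(39, 42, 200),
        },
        index=idx,
    )
    calset = calibration.fit_calibration(panel, DEFAULT_SITE, min_n=20)
    cal = calset.functions[532][13]
    # OLS sampling tolerance: 3 standard errors of the slope estimate
    se_slope = 0.005 / (np.sqrt(200) * illum.std())
    assert abs(cal.slope - (-0.0004)) < 3 * se_slope
    assert cal.intercept == pytest.approx(0.35, rel=0.02)
    assert cal.n == 200


def test_empty_input_rejected():
    empty = pd.DataFrame(
        columns=["band", "r_standard", "i_sky", "illumination_pct", "elevation_deg"]
    )
    with pytest.raises(ValueError):
        calibration.fit_calibration(empty, DEFAULT_SITE)


def test_degenerate_illumination_bin_omitted():
    panel = _panel_frame(lambda illum, elev: np.full_like(illum, 0.3))
    panel["illumination_pct"] = 80.0  # no spread anywhere
    calset = calibration.fit_calibration(panel, DEFAULT_SITE)
    assert not calset.functions  # every bin dropped


class TestCorrectionRatio:
    @staticmethod
    def _calset():
        cs = calibration.CalibrationFunctionSet(bin_width_deg=3.0)
        cs.functions[532] = {
            13: calibration.BinCalibration(-0.0004, 0.35, 100, 0.9, 15.0, 100.0),
            5: calibration.BinCalibration(0.0, 0.318, 100, 0.9, 15.0, 100.0),
        }
        return cs

    def test_flat_function_returns_intercept(self):
        assert calibration.correction_ratio(
            self._calset(), 532, 16.0, 57.0
        ) == pytest.approx(0.318)

    def test_linear_evaluation(self):
        assert calibration.correction_ratio(
            self._calset(), 532, 40.0, 50.0
        ) == pytest.approx(0.33)

    def test_illumination_clamped_to_fit_range(self):
        at_cap = calibration.correction_ratio(self._calset(), 532, 40.0, 140.0)
        at_100 = calibration.correction_ratio(self._calset(), 532, 40.0, 100.0)
        assert at_cap == at_100

    def test_midday_mode_uses_noon_bin(self):
        r = calibration.correction_ratio(
            self._calset(), 532, 40.0, 50.0, mode="midday", noon_elevation_deg=16.0
        )
        assert r == pytest.approx(0.318)  # noon bin 5, not the 40-deg bin

    def test_midday_mode_requires_noon_elevation(self):
        with pytest.raises(ValueError):
            calibration.correction_ratio(self._calset(), 532, 40.0, 50.0, mode="midday")

    def test_gap_falls_back_to_nearest_bin(self):
        cal, exact = self._calset().lookup(532, 18)  # above fitted span
        assert not exact
        assert cal.intercept == pytest.approx(0.35)  # nearest is bin 13


@pytest.mark.parametrize(
    "rho, ratio, expected", [(0.0318, 0.318, 0.1), (0.42, 1.0, 0.42)]
)
def test_correct_reflectance_examples(rho, ratio, expected):
    assert calibration.correct_reflectance(rho, ratio) == pytest.approx(expected)


def test_correct_reflectance_nonpositive_ratio_missing():
    assert np.isnan(calibration.correct_reflectance(0.05, 0.0))
    assert np.isnan(calibration.correct_reflectance(0.05, -0.2))


def test_serialization_round_trip(tmp_path):
    cs = calibration.CalibrationFunctionSet(bin_width_deg=3.0)
    cs.functions[532] = {4: calibration.BinCalibration(-1e-4, 0.32, 55, 0.8, 20, 105)}
    cs.functions[570] = {4: calibration.BinCalibration(-2e-4, 0.29, 60, 0.7, 20, 105)}
    path = tmp_path / "cal.json"
    cs.to_json(path)
    back = calibration.CalibrationFunctionSet.from_json(path)
    assert back.bin_width_deg == cs.bin_width_deg
    assert back.functions == cs.functions


class TestCampaignRecovery:
    """Generator ground truth: fitted lines and fore-optic shape checks."""

    def test_slopes_and_intercepts_within_5_percent(self, config, panel_campaign):
        panel, truth = panel_campaign
        prep = pipeline.prepare_panel(panel, config.site)
        calset = calibration.fit_calibration(prep, config.site, min_n=20)
        for band in calset.bands():
            for b, cal in calset.functions[band].items():
                row = truth[(truth["band"] == band) & (truth["bin"] == b)].iloc[0]
                assert cal.slope == pytest.approx(row["slope_true"], rel=0.05)
                assert cal.intercept == pytest.approx(row["intercept_true"], rel=0.05)

    def test_low_elevation_bins_have_steeper_slopes(self, config, panel_campaign):
        """Low sun -> stronger illumination sensitivity: fitted slopes are
        more negative at low elevation bins than near-noon bins."""
        panel, _ = panel_campaign
        prep = pipeline.prepare_panel(panel, config.site)
        calset = calibration.fit_calibration(prep, config.site)
        for band in calset.bands():
            bins = calset.bins(band)
            low = calset.functions[band][bins[0]].slope
            high = calset.functions[band][bins[-1]].slope
            assert low < high < 0

    def test_ratio_spread_shrinks_with_elevation(self, config, panel_campaign):
        """Specular noise at low sun: per-bin ratio residual spread
        decreases toward high elevations."""
        panel, _ = panel_campaign
        prep = pipeline.prepare_panel(panel, config.site)
        prep = prep.loc[(prep["band"] == 532) & (prep["i_sky"] > 0)]
        prep = prep.dropna(subset=["illumination_pct"])
        ratio = prep["r_standard"] / prep["i_sky"]
        bins = solar.elevation_bin(prep["elevation_deg"].to_numpy(), 3.0)
        spread = {
            b: ratio[bins == b].std() for b in np.unique(bins) if b >= 1
        }
        ordered = [spread[b] for b in sorted(spread)]
        assert ordered[0] > ordered[-1]
        # broadly monotone: rank correlation strongly negative
        from scipy.stats import spearmanr

        rho, _ = spearmanr(sorted(spread), ordered)
        assert rho < -0.8
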