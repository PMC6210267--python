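"""fAPAR bookkeeping, NDVI-fAPAR relation, phenology detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pricalib import canopy, synth


class TestFapar:
    @pytest.mark.parametrize(
        "t, r, r_s, expected",
        [(0.0, 0.0, 0.5, 1.0), (1.0, 0.0, 0.0, 0.0), (0.2, 0.05, 0.1, 0.77)],
    )
    def test_examples(self, t, r, r_s, expected):
        assert canopy.fapar(t, r, r_s) == pytest.approx(expected)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    def test_bounded_for_physical_inputs(self, t, r, r_s):
        # for t + r <= 1 (energy conservation) fAPAR stays in [0, 1]
        if t + r <= 1.0:
            assert -1e-12 <= canopy.fapar(t, r, r_s) <= 1.0 + 1e-12

    def test_apar_product(self):
        assert canopy.apar(0.8, 1000.0) == pytest.approx(800.0)


class TestNdviFaparFit:
    COEFFS = (-1.9596, 2.954, -0.3484)

    def test_exact_polynomial_recovered(self):
        days = pd.date_range("2015-06-01", periods=60, freq="D")
        x = pd.Series(np.linspace(0.25, 0.74, 60), index=days)
        y = pd.Series(np.polyval(self.COEFFS, x.to_numpy()), index=days)
        coeffs, r2 = canopy.ndvi_fapar_fit(x, y)
        assert np.allclose(coeffs, self.COEFFS, atol=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_saturating_point_worked_example(self):
        """The quadratic evaluated at NDVI 0.65 sits at fAPAR ~ 0.74-0.75."""
        val = float(np.polyval(self.COEFFS, 0.65))
        assert 0.74 <= val <= 0.75

    def test_noisy_curve_recovered_within_10_percent(self):
        rng = np.random.default_rng(11)
        days = pd.date_range("2015-05-01", periods=120, freq="D")
        x = pd.Series(rng.uniform(0.25, 0.74, 120), index=days)
        y = pd.Series(
            np.polyval(self.COEFFS, x.to_numpy()) + rng.normal(0, 0.02, 120),
            index=days,
        )
        coeffs, _ = canopy.ndvi_fapar_fit(x, y)
        assert np.all(np.abs(coeffs / np.array(self.COEFFS) - 1.0) < 0.10)

    def test_fit_is_monotone_over_observed_range(self, season):
        """On generator data built with a saturating curve the fitted
        relation increases over the observed NDVI span."""
        daily = season.truth["daily"]
        rng = np.random.default_rng(5)
        x = daily["ndvi_true"] + rng.normal(0, 0.005, len(daily))
        y = daily["fapar_true"] + rng.normal(0, 0.005, len(daily))
        coeffs, r2 = canopy.ndvi_fapar_fit(x, y)
        grid = np.linspace(x.min(), x.max(), 200)
        fitted = np.polyval(coeffs, grid)
        assert np.all(np.diff(fitted) > 0)
        assert r2 > 0.9

    def test_too_few_days_rejected(self):
        days = pd.date_range("2015-06-01", periods=5, freq="D")
        s = pd.Series(np.linspace(0.3, 0.6, 5), index=days)
        with pytest.raises(ValueError):
            canopy.ndvi_fapar_fit(s, s)

    def test_degenerate_ndvi_rejected(self):
        days = pd.date_range("2015-06-01", periods=20, freq="D")
        x = pd.Series(0.5, index=days)
        y = pd.Series(np.linspace(0.3, 0.6, 20), index=days)
        with pytest.raises(ValueError):
            canopy.ndvi_fapar_fit(x, y)


class TestPhenology:
    def test_logistic_transition_within_3_days(self, config):
        ndvi, true_doy = synth.generate_daily_ndvi(config)
        stage = canopy.phenology_transition(ndvi)
        assert abs(stage.transition_date.dayofyear - true_doy) <= 3
        # stage labels: all maturity before, all senescence from the date
        assert (stage.stages.loc[: stage.transition_date - pd.Timedelta("1D")]
                == "maturity").all()
        assert (stage.stages.loc[stage.transition_date:] == "senescence").all()

    def test_flat_series_has_no_transition(self):
        days = pd.date_range("2015-05-01", periods=100, freq="D")
        stage = canopy.phenology_transition(pd.Series(0.6, index=days))
        assert stage.transition_date is None
        assert (stage.stages == "maturity").all()

    def test_step_decline_located_within_stencil(self):
        """Abrupt step: the curvature detector marks the onset, at most
        one stencil width before the step day."""
        days = pd.date_range("2015-05-01", periods=150, freq="D")
        v = np.where(np.arange(150) < 90, 0.7, 0.4)
        stage = canopy.phenology_transition(pd.Series(v, index=days), d2_step_days=9)
        detected = (stage.transition_date - days[0]).days
        assert 90 - 9 <= detected <= 90 + 3

    def test_short_series_rejected(self):
        days = pd.date_range("2015-05-01", periods=30, freq="D")
        with pytest.raises(ValueError):
            canopy.phenology_transition(pd.Series(0.5, index=days))

    def test_label_for_timestamps(self):
        days = pd.date_range("2015-05-01", periods=100, freq="D")
        v = np.where(np.arange(100) < 60, 0.7, 0.4)
        stage = canopy.phenology_transition(pd.Series(v, index=days))
        stamps = pd.DatetimeIndex(
            ["2015-05-05 12:00", "2015-08-05 12:00"]
        ).tz_localize("UTC")
        labels = stage.label_for(stamps, utc_offset_h=-7)
        assert labels.iloc[0] == "maturity"
        assert labels.iloc[1] == "senescence"


def test_wsn_fractions_recover_generator_truth(season):
    frac = canopy.wsn_canopy_fractions(season.wsn)
    day = frac["ppfd_in"] > 100
    daily = season.truth["daily"]
    # mid-season day: fAPAR close to daily truth
    local_days = frac.index.tz_convert(None) + pd.Timedelta(hours=-7)
    sel = day & (local_days.normalize() == pd.Timestamp("2015-07-15"))
    assert frac.loc[sel, "fapar"].mean() == pytest.approx(
        daily.loc["2015-07-15", "fapar_true"], rel=0.03
    )
    # all season: physical range, no non-physical flags needed
    assert frac.loc[day, "fapar"].between(0, 1).all()
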