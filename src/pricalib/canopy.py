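"""Canopy light absorption (fAPAR/APAR), NDVI-fAPAR relation, phenology.

fAPAR follows the four-stream bookkeeping

    fAPAR = 1 - t - r + t * r_s

with t the fraction of PPFD transmitted through the canopy, r the
canopy-top reflected fraction and r_s the soil reflectance below the
canopy (the t*r_s term returns soil-reflected light to the canopy
absorption budget).

Phenology: the broadband NDVI series tracks canopy greenness; the
maturity -> senescence transition is located where the smoothed daily
NDVI curve bends downward hardest (most negative second derivative in
the post-peak half of the season).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def fapar(t, r, r_s):
    """Fraction of absorbed PAR. Values outside [0, 1] are returned
    unclipped (flag non-physical inputs upstream)."""
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    r_s = np.asarray(r_s, dtype=float)
    out = 1.0 - t - r + t * r_s
    if out.ndim == 0:
        return float(out)
    return out


def apar(fapar_values, ppfd_in):
    """Absorbed PPFD, umol m-2 s-1."""
    return np.asarray(fapar_values, dtype=float) * np.asarray(ppfd_in, dtype=float)


def wsn_canopy_fractions(wsn: pd.DataFrame) -> pd.DataFrame:
    """Derive t, r, r_s and fAPAR from WSN quantum-sensor channels.

    Expects columns ``ppfd_above_down``, ``ppfd_above_up``,
    ``ppfd_below_down``, ``ppfd_below_up`` (umol m-2 s-1). Rows with
    non-positive incident PPFD yield NaN.
    """
    above = wsn["ppfd_above_down"].to_numpy(dtype=float)
    ok = above > 0
    below = wsn["ppfd_below_down"].to_numpy(dtype=float)
    t = np.where(ok, below / np.where(ok, above, 1.0), np.nan)
    r = np.where(ok, wsn["ppfd_above_up"].to_numpy(dtype=float) / np.where(ok, above, 1.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_s = np.where(below > 0, wsn["ppfd_below_up"].to_numpy(dtype=float) / np.where(below > 0, below, 1.0), np.nan)
    out = pd.DataFrame(
        {"t": t, "r": r, "r_s": r_s, "ppfd_in": above}, index=wsn.index
    )
    out["fapar"] = fapar(out["t"], out["r"], out["r_s"])
    out["apar"] = apar(out["fapar"], out["ppfd_in"])
    return out


def daily_near_noon_mean(series: pd.Series, utc_offset_h: float,
                         start_hour: int = 10, end_hour: int = 14) -> pd.Series:
    """Daily mean of near-noon (default 10:00-14:00 local) values.

    Restricting daily NDVI/fAPAR to near-noon hours avoids low-sun
    artefacts in the daily series; index of the result is the local
    civil date.
    """
    local = series.copy()
    idx = series.index
    if idx.tz is not None:
        idx = idx.tz_convert(None)
    local.index = idx + pd.Timedelta(hours=utc_offset_h)
    sel = local.between_time(f"{start_hour:02d}:00", f"{end_hour:02d}:00",
                             inclusive="left")
    return sel.groupby(sel.index.normalize()).mean()


def ndvi_fapar_fit(ndvi_daily: pd.Series, fapar_daily: pd.Series):
    """Quadratic least squares of daily fAPAR (y) on daily NDVI (x).

    Returns ``(coeffs, r2)`` with ``coeffs`` in descending-power order
    (numpy.polyval convention). Requires >= 10 paired days and
    non-degenerate NDVI spread.
    """
    joined = pd.concat(
        {"ndvi": ndvi_daily, "fapar": fapar_daily}, axis=1
    ).dropna()
    if len(joined) < 10:
        raise ValueError(f"need >= 10 paired daily values, got {len(joined)}")
    x = joined["ndvi"].to_numpy()
    y = joined["fapar"].to_numpy()
    if np.ptp(x) < 1e-9:
        raise ValueError("degenerate NDVI spread; quadratic fit is rank-deficient")
    coeffs = np.polyfit(x, y, 2)
    resid = y - np.polyval(coeffs, x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    return coeffs, float(r2)


@dataclass(frozen=True)
class PhenologyStage:
    """Season stage labels: maturity before the transition date,
    senescence from it onward. ``transition_date`` is None when no
    post-peak decline exists."""

    transition_date: pd.Timestamp | None
    stages: pd.Series  # per-day labels "maturity" / "senescence"

    def label_for(self, timestamps, utc_offset_h: float = 0.0) -> pd.Series:
        """Stage label for arbitrary timestamps (by local civil date)."""
        idx = pd.DatetimeIndex(timestamps)
        if idx.tz is not None:
            idx = idx.tz_convert(None)
        days = (idx + pd.Timedelta(hours=utc_offset_h)).normalize()
        if self.transition_date is None:
            return pd.Series("maturity", index=timestamps)
        labels = np.where(days < self.transition_date, "maturity", "senescence")
        return pd.Series(labels, index=timestamps)


def phenology_transition(
    ndvi_daily: pd.Series,
    smooth_days: int = 7,
    d2_step_days: int = 9,
    min_decline: float = 0.05,
) -> PhenologyStage:
    """Locate the maturity -> senescence transition in daily NDVI.

    The series (>= 60 days) is smoothed with a centred moving average,
    the discrete second derivative taken by central differences with a
    ``d2_step_days`` stencil (a 1-day stencil is dominated by day-scale
    noise; a few-day step measures curvature at the senescence-bend
    scale), and the transition placed at its most negative value within
    the post-peak part of the season. A series whose post-peak decline
    is smaller than ``min_decline`` NDVI units carries no transition
    (flagged by a None date; all days labelled maturity).
    """
    s = ndvi_daily.dropna().sort_index()
    if len(s) < 60:
        raise ValueError(f"need a daily series covering >= 60 days, got {len(s)}")
    smooth = s.rolling(smooth_days, center=True, min_periods=1).mean()
    vals = smooth.to_numpy()
    peak_pos = int(np.argmax(vals))
    decline = vals[peak_pos] - vals[-1]
    if decline < min_decline or peak_pos >= len(vals) - 2:
        return PhenologyStage(None, pd.Series("maturity", index=s.index))

    h = max(min(d2_step_days, (len(vals) - 1) // 2), 1)
    d2 = np.full(len(vals), np.nan)
    d2[h:-h] = (vals[2 * h:] - 2 * vals[h:-h] + vals[:-2 * h]) / h**2
    post = np.arange(len(vals)) > peak_pos
    candidates = np.where(post & ~np.isnan(d2))[0]
    if candidates.size == 0:
        return PhenologyStage(None, pd.Series("maturity", index=s.index))
    trans_pos = candidates[np.argmin(d2[candidates])]
    date = s.index[trans_pos]
    stages = pd.Series(
        np.where(s.index < date, "maturity", "senescence"), index=s.index
    )
    return PhenologyStage(pd.Timestamp(date), stages)
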