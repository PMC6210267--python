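"""Flux processing: covariance NEE, u* filter, respiration, light response.

Sign convention is meteorological: NEE = -GPP + Reco, negative NEE is
net CO2 uptake. The light-response model is the rectangular hyperbola
with a Q10 respiration term,

    NEE = -(Amax * alpha * PPFD) / (Amax + alpha * PPFD)
          + R10 * Q10**((Tair - 10) / 10)

fit per 2-day composite diurnal window by Gauss-Newton with step
halving (analytic Jacobian), falling back to scipy's Levenberg-
Marquardt when Gauss-Newton fails to converge. ``alpha`` (apparent
quantum yield, mol CO2 per mol photons) is the hyperbola's initial
slope and the quantity of ecological interest here; ``Amax`` its
saturation, ``R10``/``Q10`` the respiration base rate and temperature
sensitivity.

Ecosystem respiration for GPP partitioning comes from a simplified
nighttime Q10 regression (PPFD < 5 umol m-2 s-1 rows) extrapolated to
daytime — a deliberate, documented simplification of moving-window
partitioning schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

#: PPFD below which a 30-min record counts as nighttime.
NIGHT_PPFD = 5.0

ALPHA_CEILING = 0.125  # theoretical quantum-yield maximum, mol CO2 / mol photons


def covariance_nee(w: np.ndarray, s: np.ndarray, rho_a: float) -> float:
    """Block NEE from vertical wind and mixing-ratio series (demonstration).

    NEE = -rho_a * cov(w', s'), with rho_a dry-air density in mol m-3 and
    s the molar mixing ratio; result in the units of rho_a * w * s
    (mol m-3 * m s-1 * mol/mol -> umol m-2 s-1 when s is in umol/mol).
    Raw-signal corrections (despiking, rotation, WPL...) are out of scope;
    this operation documents the covariance definition only.
    """
    w = np.asarray(w, dtype=float)
    s = np.asarray(s, dtype=float)
    if w.shape != s.shape:
        raise ValueError("wind and scalar series must have equal length")
    if w.size < 2:
        raise ValueError("block length must be >= 2")
    cov = float(np.mean((w - w.mean()) * (s - s.mean())))
    return -rho_a * cov


def ustar_filter(records: pd.DataFrame, threshold: float = 0.21) -> pd.DataFrame:
    """Drop records with u* strictly below the threshold (poor mixing)."""
    if threshold <= 0:
        raise ValueError("u* threshold must be positive")
    return records.loc[records["ustar"] >= threshold]


def _q10_model(tair, r10, q10):
    return r10 * q10 ** ((np.asarray(tair, dtype=float) - 10.0) / 10.0)


def _fit_night_q10(night: pd.DataFrame) -> tuple[float, float]:
    tair = night["tair"].to_numpy()
    if np.ptp(tair) < 1.0:
        raise ValueError("isothermal nights: Q10 unidentifiable")
    nee = night["nee"].to_numpy()
    p0 = (max(float(np.mean(nee)), 0.1), 2.0)
    popt, _ = optimize.curve_fit(
        _q10_model, tair, nee, p0=p0, bounds=([0.0, 1.0], [np.inf, 6.0]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


def nighttime_reco(records: pd.DataFrame, min_night: int = 30):
    """Fit NEE_night = R10 * Q10**((Tair-10)/10) on all nighttime records.

    Returns ``((r10, q10), reco_series)`` where the series extrapolates
    the fit to every record's Tair. Raises on fewer than ``min_night``
    nighttime rows or an isothermal night sample (Q10 unidentifiable).
    """
    night = records.loc[records["ppfd"] < NIGHT_PPFD].dropna(subset=["nee", "tair"])
    if len(night) < min_night:
        raise ValueError(
            f"need >= {min_night} nighttime records, got {len(night)}"
        )
    r10, q10 = _fit_night_q10(night)
    reco = pd.Series(_q10_model(records["tair"].to_numpy(), r10, q10),
                     index=records.index, name="reco")
    return (r10, q10), reco


def windowed_reco(records: pd.DataFrame, window_days: int = 10,
                  min_night: int = 30):
    """Windowed nighttime Q10 regression with neighbour carry-over.

    A season-wide fit confounds the seasonal base-rate trajectory with
    temperature (warm nights co-occur with the productive season),
    inflating Q10; fitting in ``window_days`` blocks lets R10 track the
    season. Windows with fewer than ``min_night`` usable nighttime rows
    (or isothermal nights) inherit the nearest fitted window's
    parameters and are flagged.

    Returns ``(table, reco_series)``: a per-window DataFrame with
    ``r10``, ``q10``, ``n_night``, ``fitted``; and Reco extrapolated to
    every record.
    """
    day0 = records.index.min().normalize()
    widx = ((records.index - day0).days // window_days).astype(int)
    rows = {}
    for w in np.unique(widx):
        block = records.iloc[widx == w]
        night = block.loc[block["ppfd"] < NIGHT_PPFD].dropna(subset=["nee", "tair"])
        try:
            if len(night) < min_night:
                raise ValueError("insufficient nighttime data")
            r10, q10 = _fit_night_q10(night)
            rows[w] = {"r10": r10, "q10": q10, "n_night": len(night), "fitted": True}
        except (ValueError, RuntimeError):
            rows[w] = {"r10": np.nan, "q10": np.nan, "n_night": len(night),
                       "fitted": False}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if not table["fitted"].any():
        raise ValueError("no window had enough nighttime data for a Q10 fit")
    fitted_idx = table.index[table["fitted"]].to_numpy()
    for w in table.index[~table["fitted"]]:
        nearest = fitted_idx[np.argmin(np.abs(fitted_idx - w))]
        table.loc[w, ["r10", "q10"]] = table.loc[nearest, ["r10", "q10"]]
    r10_per = table["r10"].reindex(widx).to_numpy()
    q10_per = table["q10"].reindex(widx).to_numpy()
    reco = pd.Series(_q10_model(records["tair"].to_numpy(), r10_per, q10_per),
                     index=records.index, name="reco")
    table.index = day0 + pd.to_timedelta(table.index * window_days, unit="D")
    return table, reco


def partition_gpp(nee, reco):
    """GPP = Reco - NEE; negative values are clipped to zero."""
    gpp = np.asarray(reco, dtype=float) - np.asarray(nee, dtype=float)
    out = np.clip(gpp, 0.0, None)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class LightResponseParams:
    """Fitted light-response parameters for one 2-day window."""

    amax: float   # umol m-2 s-1
    alpha: float  # mol CO2 / mol photons
    r10: float    # umol m-2 s-1
    q10: float
    window_start: pd.Timestamp | None
    residual_norm: float
    converged: bool
    n: int
    se_alpha: float = float("nan")  # asymptotic standard error of alpha

    @property
    def alpha_identified(self) -> bool:
        """True when alpha is distinguishable from zero (|alpha| > 2 se).

        Windows with little light or vanishing uptake leave the
        hyperbola's initial slope unidentified; their alpha estimates
        are leverage points, not information.
        """
        return bool(np.isfinite(self.se_alpha) and self.alpha > 2.0 * self.se_alpha)

    @property
    def within_bounds(self) -> bool:
        return (
            self.amax > 0
            and 0 < self.alpha <= ALPHA_CEILING
            and self.r10 >= 0
            and 1.0 <= self.q10 <= 4.0
        )

    def gpp(self, ppfd):
        """Hyperbolic GPP at the fitted parameters."""
        p = np.asarray(ppfd, dtype=float)
        return self.amax * self.alpha * p / (self.amax + self.alpha * p)

    def nee(self, ppfd, tair):
        return -self.gpp(ppfd) + _q10_model(tair, self.r10, self.q10)


def _residuals_jacobian(theta, ppfd, tair, nee):
    amax, alpha, r10, q10 = theta
    q10 = max(q10, 1e-6)  # unbounded LM trial steps may cross zero
    denom = amax + alpha * ppfd
    gpp = amax * alpha * ppfd / denom
    model = -gpp + _q10_model(tair, r10, q10)
    resid = nee - model
    x = (tair - 10.0) / 10.0
    jac = np.column_stack(
        [
            (alpha * ppfd) ** 2 / denom**2,        # -d model/d amax
            amax**2 * ppfd / denom**2,             # -d model/d alpha
            -(q10**x),                             # -d model/d r10
            -(r10 * x * q10 ** (x - 1.0)),         # -d model/d q10
        ]
    )
    # resid = nee - model, so d resid/d theta = -d model/d theta; signs above
    # already carry the negation for the uptake term.
    return resid, jac


def _gauss_newton(theta0, ppfd, tair, nee, max_iter=100, tol=1e-10):
    theta = np.asarray(theta0, dtype=float)
    resid, jac = _residuals_jacobian(theta, ppfd, tair, nee)
    sse = float(resid @ resid)
    for _ in range(max_iter):
        step, *_ = np.linalg.lstsq(jac, resid, rcond=None)
        # step halving until SSE decreases (or the step dies out)
        lam = 1.0
        for _ in range(30):
            cand = theta + lam * step
            cand[0] = max(cand[0], 1e-6)   # amax > 0
            cand[1] = max(cand[1], 1e-8)   # alpha > 0
            cand[3] = max(cand[3], 1e-3)   # q10 > 0 keeps powers defined
            r2, j2 = _residuals_jacobian(cand, ppfd, tair, nee)
            s2 = float(r2 @ r2)
            if s2 < sse:
                break
            lam *= 0.5
        else:
            return theta, sse, False
        rel = np.max(np.abs(lam * step) / (np.abs(theta) + 1e-12))
        theta, resid, jac, sse = cand, r2, j2, s2
        if rel < tol:
            return theta, sse, True
    return theta, sse, False


def light_response_fit(window: pd.DataFrame,
                       window_start: pd.Timestamp | None = None) -> LightResponseParams:
    """Fit the rectangular-hyperbola light-response model to one window.

    ``window`` holds the 2-day composite diurnal records with columns
    ``nee``, ``ppfd``, ``tair``. Initialisation: Amax = 95th percentile
    of -NEE, alpha = 0.02, R10 = mean nighttime NEE, Q10 = 2. A window
    whose PPFD never leaves darkness cannot identify Amax/alpha and is
    returned unconverged.
    """
    data = window.dropna(subset=["nee", "ppfd", "tair"])
    ppfd = data["ppfd"].to_numpy(dtype=float)
    tair = data["tair"].to_numpy(dtype=float)
    nee = data["nee"].to_numpy(dtype=float)
    n = len(data)
    if n < 8 or np.nanmax(ppfd, initial=0.0) < NIGHT_PPFD:
        return LightResponseParams(np.nan, np.nan, np.nan, np.nan,
                                   window_start, np.nan, False, n)
    night = nee[ppfd < NIGHT_PPFD]
    r10_0 = float(np.mean(night)) if night.size else 2.0
    theta0 = np.array([
        max(float(np.percentile(-nee, 95)), 1.0),
        0.02,
        max(r10_0, 0.1),
        2.0,
    ])
    theta, sse, converged = _gauss_newton(theta0, ppfd, tair, nee)
    if not converged:
        # Levenberg-Marquardt fallback on the same residuals
        res = optimize.least_squares(
            lambda th: _residuals_jacobian(th, ppfd, tair, nee)[0],
            theta0, method="lm", max_nfev=5000,
        )
        if res.success:
            theta = res.x
            sse = float(2 * res.cost)
            converged = True
    se_alpha = np.nan
    if converged and n > 4:
        _, jac = _residuals_jacobian(theta, ppfd, tair, nee)
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * sse / (n - 4)
            se_alpha = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            pass
    return LightResponseParams(
        amax=float(theta[0]), alpha=float(theta[1]),
        r10=float(theta[2]), q10=float(theta[3]),
        window_start=window_start,
        residual_norm=float(np.sqrt(sse)), converged=bool(converged), n=n,
        se_alpha=se_alpha,
    )


def two_day_composite(records: pd.DataFrame, utc_offset_h: float = 0.0):
    """Split 30-min records into consecutive 2-day blocks and average the
    two days into one composite diurnal cycle per block.

    Yields ``(block_start_date, composite_frame)`` pairs; the composite
    frame is indexed by local time-of-day and averages nee/ppfd/tair over
    the block's matching half-hours.
    """
    idx = records.index
    if idx.tz is not None:
        idx = idx.tz_convert(None)
    local = records.copy()
    local.index = idx + pd.Timedelta(hours=utc_offset_h)
    day0 = local.index.normalize().min()
    block = ((local.index.normalize() - day0).days // 2).astype(int)
    tod = local.index - local.index.normalize()
    for b, grp in local.groupby(block):
        comp = grp.groupby(tod[block == b]).mean(numeric_only=True)
        yield day0 + pd.Timedelta(days=2 * int(b)), comp


def season_light_response(records: pd.DataFrame,
                          utc_offset_h: float = 0.0) -> pd.DataFrame:
    """Fit the light-response model on every 2-day composite window.

    Returns one row per window (indexed by window start date) with the
    fitted parameters and diagnostics; unconverged or out-of-bounds
    windows are flagged, not dropped.
    """
    rows = []
    for start, comp in two_day_composite(records, utc_offset_h):
        params = light_response_fit(comp, window_start=start)
        rows.append(
            {
                "window_start": start,
                "amax": params.amax,
                "alpha": params.alpha,
                "r10": params.r10,
                "q10": params.q10,
                "converged": params.converged,
                "within_bounds": params.within_bounds if params.converged else False,
                "alpha_identified": params.alpha_identified,
                "se_alpha": params.se_alpha,
                "residual_norm": params.residual_norm,
                "n": params.n,
            }
        )
    return pd.DataFrame(rows).set_index("window_start")


def read_flux_csv(path) -> pd.DataFrame:
    """Read the 30-min flux CSV dialect (timestamp, nee, ustar, tair,
    ppfd, qc)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df.set_index("timestamp").sort_index()
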