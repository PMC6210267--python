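"""Light-use efficiency, proxy-driven LUE models, stratified correlations.

LUE = GPP / APAR (mol CO2 per mol absorbed photons). The LUE models
regress efficiency on a proxy (sPRI from the corrected optical stream,
or the apparent quantum yield alpha from the flux light response) and
reconstruct GPP as modelled-LUE x APAR. Stratified correlations split
every comparison by phenological stage (season / maturity / senescence)
to separate facultative (xanthophyll-cycle) from constitutive
(structure/pigment-pool) signal in the PRI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: APAR below this floor (umol m-2 s-1) makes GPP/APAR numerically
#: unstable (dawn/dusk); LUE is flagged missing there.
APAR_FLOOR = 50.0


def lue(gpp, apar, floor: float = APAR_FLOOR):
    """GPP/APAR with below-floor APAR flagged missing (NaN)."""
    g = np.asarray(gpp, dtype=float)
    a = np.asarray(apar, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(a >= floor, g / np.where(a >= floor, a, 1.0), np.nan)
    if np.isscalar(gpp) and out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ModelComparison:
    """One fitted or correlated proxy-target pairing."""

    proxy: str        # "spri" | "alpha" | "apar" | free-form x name
    scope: str        # "season" | "maturity" | "senescence"
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def fit_lue_model(proxy: pd.Series, lue_series: pd.Series,
                  proxy_name: str = "spri", scope: str = "season") -> ModelComparison:
    """Linear least squares lue = a * proxy + b on co-registered series."""
    joined = pd.concat({"x": proxy, "y": lue_series}, axis=1).dropna()
    if len(joined) < 10:
        raise ValueError(f"need >= 10 paired values, got {len(joined)}")
    x = joined["x"].to_numpy()
    if np.std(x) < 1e-12:
        raise ValueError("degenerate proxy variance; model rejected")
    fit = stats.linregress(x, joined["y"].to_numpy())
    return ModelComparison(
        proxy=proxy_name, scope=scope,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue**2), p_value=float(fit.pvalue), n=len(joined),
    )


def predict_gpp(model: ModelComparison, proxy: pd.Series, apar: pd.Series) -> pd.Series:
    """GPP reconstructed as (a * proxy + b) * APAR, clipped at zero."""
    modeled_lue = model.slope * proxy + model.intercept
    gpp = (modeled_lue * apar).clip(lower=0.0)
    gpp.name = f"gpp_{model.proxy}"
    return gpp


def stratified_correlation(
    x: pd.Series,
    y: pd.Series,
    stages: pd.Series | None = None,
    proxy_name: str = "x",
) -> list[ModelComparison]:
    """Pearson r^2, two-sided p and n for season + each stage scope.

    ``stages`` labels each timestamp "maturity"/"senescence"; scopes with
    fewer than 3 paired values are omitted.
    """
    frame = pd.concat({"x": x, "y": y}, axis=1)
    if stages is not None:
        frame["stage"] = stages.reindex(frame.index)
    scopes: list[tuple[str, pd.DataFrame]] = [("season", frame)]
    if stages is not None:
        for name in ("maturity", "senescence"):
            scopes.append((name, frame.loc[frame["stage"] == name]))
    out = []
    for scope, sub in scopes:
        sub = sub.dropna(subset=["x", "y"])
        if len(sub) < 3 or np.std(sub["x"]) < 1e-12 or np.std(sub["y"]) < 1e-12:
            continue
        fit = stats.linregress(sub["x"].to_numpy(), sub["y"].to_numpy())
        out.append(
            ModelComparison(
                proxy=proxy_name, scope=scope,
                slope=float(fit.slope), intercept=float(fit.intercept),
                r2=float(fit.rvalue**2), p_value=float(fit.pvalue), n=len(sub),
            )
        )
    return out


def comparisons_frame(comparisons: list[ModelComparison]) -> pd.DataFrame:
    """Tabulate ModelComparison rows for the results CSV."""
    return pd.DataFrame([vars(c) for c in comparisons])
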