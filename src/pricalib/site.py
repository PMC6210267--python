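"""Site configuration shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SiteConfig:
    """Location, timezone and processing thresholds for a tower site.

    Parameters
    ----------
    latitude_deg, longitude_deg
        Geographic coordinates; longitude negative west of Greenwich.
    altitude_m
        Site altitude above sea level, metres (enters the clear-sky
        optical air-mass correction).
    utc_offset_h
        Civil offset of the logger clock from UTC, hours. Used only at
        I/O boundaries; all internal timestamps are UTC.
    elevation_bin_width_deg
        Width of the solar-elevation bins used by the cross-calibration,
        degrees.
    ustar_threshold_ms
        Friction-velocity threshold below which 30-min fluxes are
        discarded as poorly mixed, m s-1.
    atc
        Atmospheric transmission coefficient of the clear-sky model;
        valid range 0.70-0.91.
    """

    latitude_deg: float
    longitude_deg: float
    altitude_m: float = 0.0
    utc_offset_h: float = 0.0
    elevation_bin_width_deg: float = 3.0
    ustar_threshold_ms: float = 0.21
    atc: float = 0.8

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude_deg}")
        if self.elevation_bin_width_deg <= 0:
            raise ValueError("elevation bin width must be positive")
        if not 0.70 <= self.atc <= 0.91:
            raise ValueError(
                f"atmospheric transmission coefficient {self.atc} outside the "
                "clear-sky model's valid range [0.70, 0.91]"
            )


#: Boreal aspen tower site in the Peace River region (AB, Canada):
#: 56°44'38.10" N, 118°20'38.08" W, 867 m a.s.l., Mountain Standard Time.
DEFAULT_SITE = SiteConfig(
    latitude_deg=56.7439,
    longitude_deg=-118.3439,
    altitude_m=867.0,
    utc_offset_h=-7.0,
)
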