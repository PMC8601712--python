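"""Barometric altimetry under the ICAO standard atmosphere.

Pressure from the loggers is converted to altitude above sea level with the
hypsometric relation for an atmosphere with a linear temperature lapse:

    h(P) = (T0 / L) * (1 - (P / P0)^(R0 * L / g))

with sea-level temperature T0 = 288.15 K, lapse rate L = 0.0065 K/m,
sea-level pressure P0 = 1013.25 hPa, g = 9.8 m/s^2 and specific gas
constant R0 = 287.058 J/(kg K). The mapping is strictly decreasing in P and
algebraically invertible, which the synthetic generator exploits.

This module also provides the two series primitives everything downstream
uses: the centred three-point rolling mean applied before descent and
displacement analyses, and per-interval vertical displacement / rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AtmosphereConstants:
    """Standard-atmosphere constants for the hypsometric conversion."""

    T0: float = 288.15  # sea-level temperature, K
    L: float = 0.0065  # temperature lapse rate, K/m
    P0: float = 1013.25  # sea-level pressure, hPa
    g: float = 9.8  # gravitational acceleration, m/s^2
    R0: float = 287.058  # specific gas constant of air, J/(kg K)

    def __post_init__(self) -> None:
        if min(self.T0, self.L, self.P0, self.g, self.R0) <= 0:
            raise ValueError("atmosphere constants must be strictly positive")

    @property
    def exponent(self) -> float:
        """R0*L/g, the exponent of the pressure ratio (~0.1904)."""
        return self.R0 * self.L / self.g

    @property
    def ceiling_m(self) -> float:
        """T0/L, the altitude where the linear-lapse atmosphere ends."""
        return self.T0 / self.L


STANDARD_ATMOSPHERE = AtmosphereConstants()


@dataclass
class AltitudeSeries:
    """Altitude (masl) on the 5-min logger grid.

    ``provenance`` records whether values are raw conversions or have been
    through the three-point rolling mean.
    """

    timestamps: pd.DatetimeIndex
    altitude: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.altitude = np.asarray(self.altitude, dtype=float)
        if len(self.timestamps) != len(self.altitude):
            raise ValueError("timestamps and altitude must have equal length")
        if len(self.altitude) and not np.all(np.isfinite(self.altitude)):
            raise ValueError("altitude values must be finite")

    def __len__(self) -> int:
        return len(self.altitude)

    def slice_time(self, start: pd.Timestamp, end: pd.Timestamp) -> "AltitudeSeries":
        mask = (self.timestamps >= start) & (self.timestamps <= end)
        return AltitudeSeries(
            self.timestamps[mask], self.altitude[mask], self.provenance
        )


def pressure_to_altitude(
    pressure_hpa, constants: AtmosphereConstants = STANDARD_ATMOSPHERE
):
    """Convert pressure (hPa) to altitude above sea level (m).

    Vectorises over array input; strictly decreasing in pressure. Raises
    for non-positive pressure.
    """
    p = np.asarray(pressure_hpa, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be strictly positive")
    h = (constants.T0 / constants.L) * (
        1.0 - (p / constants.P0) ** constants.exponent
    )
    return h if h.ndim else float(h)


def altitude_to_pressure(
    altitude_m, constants: AtmosphereConstants = STANDARD_ATMOSPHERE
):
    """Exact algebraic inverse of :func:`pressure_to_altitude` (hPa).

    Defined for altitudes below the lapse-layer ceiling T0/L (~44.3 km).
    """
    h = np.asarray(altitude_m, dtype=float)
    if np.any(h >= constants.ceiling_m):
        raise ValueError(
            f"altitude must be below T0/L = {constants.ceiling_m:.0f} m"
        )
    p = constants.P0 * (1.0 - h * constants.L / constants.T0) ** (
        1.0 / constants.exponent
    )
    return p if p.ndim else float(p)


def altitude_series_from_pressure(
    timestamps,
    pressure_hpa,
    constants: AtmosphereConstants = STANDARD_ATMOSPHERE,
) -> AltitudeSeries:
    """Build a raw altitude series from pressure samples."""
    return AltitudeSeries(
        pd.DatetimeIndex(timestamps),
        pressure_to_altitude(np.asarray(pressure_hpa, dtype=float), constants),
        provenance="raw",
    )


def rolling_mean3(series: AltitudeSeries) -> AltitudeSeries:
    """Centred three-point rolling mean of an altitude series.

    Endpoints average the two available points so the series keeps its
    length and sample counts stay comparable with the raw series.
    """
    z = series.altitude
    if len(z) == 0:
        raise ValueError("series must contain at least one sample")
    if len(z) <= 2:
        sm = z.copy() if len(z) == 1 else np.full(2, z.mean())
        return AltitudeSeries(series.timestamps, sm, provenance="smoothed")
    sm = np.empty_like(z)
    sm[1:-1] = (z[:-2] + z[1:-1] + z[2:]) / 3.0
    sm[0] = (z[0] + z[1]) / 2.0
    sm[-1] = (z[-2] + z[-1]) / 2.0
    return AltitudeSeries(series.timestamps, sm, provenance="smoothed")


def vertical_displacement(series: AltitudeSeries) -> pd.DataFrame:
    """Per-interval vertical displacement and rate.

    Returns a DataFrame with columns ``t_start``, ``t_end``, ``dz_m``
    (z[i+1]-z[i]) and ``rate_ms`` (dz over the interval's duration, 300 s on
    a full grid). The displacements telescope: their sum equals the net
    altitude change of the series.
    """
    if len(series) < 2:
        raise ValueError("need at least two samples")
    dt = np.diff(series.timestamps.asi8) / 1e9
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    dz = np.diff(series.altitude)
    return pd.DataFrame(
        {
            "t_start": series.timestamps[:-1],
            "t_end": series.timestamps[1:],
            "dz_m": dz,
            "rate_ms": dz / dt,
            "dt_s": dt,
        }
    )
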