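"""Flight-mechanical benchmarks for a nightjar-sized flapping migrant.

The pipeline needs three reference quantities against which the observed
vertical rates are judged:

* a **maximum sustainable climb rate** V_z(V) = (P_max - P(V)) / (m g),
  the power margin over the level-flight power curve converted to climb;
* a **glide polar** summarised by the best glide ratio, giving the sink
  rate -V / (L/D) of a non-flapping descent;
* the **cost-of-transport penalty** of a vertical excursion (climb then
  return to cruise altitude) relative to uninterrupted level flight over
  the same horizontal distance, for a gliding versus a powered descent.

The power curve is the classical three-term fixed-wing decomposition
P(V) = k (mg)^2 / (2 rho V Sd) + rho V^3 (Sb CDb + S CDpro) / 2 with disk
area Sd = pi b^2 / 4 and the allometric body frontal area
Sb = 0.00813 m^0.666. The default induced-power factor and profile drag
coefficient are calibrated once so that, with P_max matched to a climb rate
of 1.16 m/s at 10 m/s airspeed, the curve reproduces the published
aerodynamic-model benchmarks for this morphology: 1.29 m/s at 8.65 m/s and
a maximum climb of ~1.35 m/s at 7.02 m/s. See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

GRAVITY = 9.8  # consistent with the altimetry constant


@dataclass(frozen=True)
class Morphology:
    """Bird biometrics; defaults are the study population's averages."""

    mass: float = 0.0708  # kg
    wingspan: float = 0.5747  # m
    wing_area: float = 0.04239  # m^2, including the body between the wings

    def __post_init__(self) -> None:
        if min(self.mass, self.wingspan, self.wing_area) <= 0:
            raise ValueError("morphology values must be positive")

    @property
    def disk_area(self) -> float:
        return math.pi * self.wingspan**2 / 4.0

    @property
    def body_frontal_area(self) -> float:
        # Pennycuick's allometric frontal area
        return 0.00813 * self.mass**0.666

    @property
    def weight(self) -> float:
        return self.mass * GRAVITY


@dataclass
class PowerCurve:
    """Level-flight mechanical power P(V) and the available-power ceiling.

    ``max_power`` may be set directly or calibrated from a known climb
    rate at a reference airspeed (:meth:`calibrate`).
    """

    morphology: Morphology = field(default_factory=Morphology)
    air_density: float = 1.225  # kg/m^3
    induced_factor: float = 3.63
    body_drag_coeff: float = 0.1
    profile_drag_coeff: float = 0.0112
    max_power: float | None = None

    @property
    def _induced_coeff(self) -> float:
        m = self.morphology
        return self.induced_factor * m.weight**2 / (2 * self.air_density * m.disk_area)

    @property
    def _drag_coeff(self) -> float:
        m = self.morphology
        return (
            0.5
            * self.air_density
            * (
                m.body_frontal_area * self.body_drag_coeff
                + m.wing_area * self.profile_drag_coeff
            )
        )

    def power(self, V) -> float:
        """Mechanical power (W) for level flapping flight at airspeed V."""
        V = np.asarray(V, dtype=float)
        if np.any(V <= 0):
            raise ValueError("airspeed must be positive")
        P = self._induced_coeff / V + self._drag_coeff * V**3
        return P if P.ndim else float(P)

    @property
    def min_power_speed(self) -> float:
        """Airspeed minimising P(V) (closed form for the two-term curve)."""
        return (self._induced_coeff / (3 * self._drag_coeff)) ** 0.25

    def calibrate(self, airspeed: float = 10.0, climb_rate: float = 1.16) -> "PowerCurve":
        """Return a copy with max_power solved so V_z(airspeed) == climb_rate."""
        p_max = self.power(airspeed) + self.morphology.weight * climb_rate
        return replace(self, max_power=p_max)

    def max_climb_rate(self, V) -> float:
        """Maximum sustained climb rate (m/s) at airspeed V, floored at 0."""
        if self.max_power is None:
            raise ValueError(
                "max_power unset: call calibrate() or set it explicitly"
            )
        P = self.power(V)
        vz = (self.max_power - np.asarray(P)) / self.morphology.weight
        vz = np.maximum(vz, 0.0)
        return vz if vz.ndim else float(vz)


@dataclass(frozen=True)
class GlidePolar:
    """Gliding performance summarised by the best glide ratio."""

    glide_ratio: float = 11.0  # best (L/D)
    best_glide_speed: float = 10.0  # m/s forward airspeed

    def __post_init__(self) -> None:
        if self.glide_ratio <= 0 or self.best_glide_speed <= 0:
            raise ValueError("glide polar parameters must be positive")

    @property
    def sink_rate(self) -> float:
        return glide_sink_rate(self.best_glide_speed, self.glide_ratio)


def glide_sink_rate(V: float, glide_ratio: float) -> float:
    """Sink rate (m/s, negative) at forward speed V and glide ratio L/D."""
    if V <= 0 or glide_ratio <= 0:
        raise ValueError("speed and glide ratio must be positive")
    return -V / glide_ratio


def exploratory_cot_penalty(
    curve: PowerCurve,
    polar: GlidePolar,
    climb_rate: float,
    excursion_height: float = 1000.0,
    descent_mode: str = "glide",
    cruise_speed: float = 10.0,
    level_distance: float = 50_000.0,
    glide_power_fraction: float = 0.4,
    recovery_efficiency: float = 1.0,
    power_floor: float = 0.0,
) -> float:
    """Percent increase in cost of transport caused by a vertical excursion.

    A flight of fixed horizontal distance ``level_distance`` contains one
    climb of ``excursion_height`` at ``climb_rate`` followed by a return to
    the starting altitude, either by gliding at the polar's best-glide
    speed (metabolic cost a fraction of level-flight power) or by powered
    descent at the same vertical rate with the potential energy recovered
    into thrust at ``recovery_efficiency`` (power floored at
    ``power_floor``). During climbing and powered descent the bird keeps
    its cruise airspeed, so ground speed is the horizontal component
    sqrt(V^2 - v_vert^2). Returns 100 * (E_excursion / E_level - 1).
    """
    if climb_rate < 0 or excursion_height < 0:
        raise ValueError("climb_rate and excursion_height must be non-negative")
    if excursion_height == 0:
        return 0.0
    if climb_rate == 0:
        raise ValueError("a positive excursion needs a positive climb rate")
    if climb_rate >= cruise_speed:
        raise ValueError("climb rate must be below the cruise airspeed")
    if descent_mode not in ("glide", "active"):
        raise ValueError("descent_mode must be 'glide' or 'active'")
    P_level = curve.power(cruise_speed)
    H = excursion_height
    # climb leg
    t_climb = H / climb_rate
    ground_climb = math.sqrt(cruise_speed**2 - climb_rate**2) * t_climb
    E_climb = (P_level + curve.morphology.weight * climb_rate) * t_climb
    # descent leg
    if descent_mode == "glide":
        sink = -glide_sink_rate(polar.best_glide_speed, polar.glide_ratio)
        t_desc = H / sink
        ground_desc = math.sqrt(polar.best_glide_speed**2 - sink**2) * t_desc
        E_desc = glide_power_fraction * P_level * t_desc
    else:
        sink = climb_rate
        t_desc = H / sink
        ground_desc = math.sqrt(cruise_speed**2 - sink**2) * t_desc
        P_desc = max(
            P_level - curve.morphology.weight * sink * recovery_efficiency,
            power_floor,
        )
        E_desc = P_desc * t_desc
    remaining = level_distance - ground_climb - ground_desc
    if remaining < 0:
        raise ValueError(
            "infeasible geometry: excursion legs exceed the level distance"
        )
    E_total = E_climb + E_desc + P_level * remaining / cruise_speed
    E_level = P_level * level_distance / cruise_speed
    return 100.0 * (E_total / E_level - 1.0)


def default_benchmarks() -> dict:
    """The calibrated benchmark numbers used across the pipeline."""
    curve = PowerCurve().calibrate()
    polar = GlidePolar()
    return {
        "vz_at_10_ms": curve.max_climb_rate(10.0),
        "vz_at_8p65_ms": curve.max_climb_rate(8.65),
        "vz_at_7p02_ms": curve.max_climb_rate(7.02),
        "min_power_speed_ms": curve.min_power_speed,
        "glide_sink_at_10_ms": round(glide_sink_rate(10.0, polar.glide_ratio), 2),
        "cot_penalty_glide_pct": exploratory_cot_penalty(
            curve, polar, climb_rate=1.0, descent_mode="glide"
        ),
        "cot_penalty_active_pct": exploratory_cot_penalty(
            curve, polar, climb_rate=1.0, descent_mode="active"
        ),
    }
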