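"""Synthetic multisensor-logger generator with known ground truth.

Emulates the instrument the field study used: a 5-min activity score (a
binomial draw of the flapping duty cycle over 10 or 5 accelerometer
sub-measurements), 5-min barometric pressure obtained by inverting the
hypsometric formula on the true altitude and adding Gaussian sensor noise
(default s.d. 0.5 hPa, inside the sensor's +/-1 hPa accuracy bound), and a
daily latitude. Birds are nocturnal migrants: flights of 1-10 h at night
with an initial ascent, a cruising phase (optionally with planted
near-level runs and exploratory to-and-fro movements) and a terminal
descent; days are spent at rest on the ground.

The altitude path of every flight is built from its plan on a 1-s lattice
and sampled at the 5-min grid, so every downstream quantity (episode
boundaries, level fractions, tortuosity, planted events, descent modes)
has a deterministic ground truth.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .altimetry import (
    AltitudeSeries,
    AtmosphereConstants,
    STANDARD_ATMOSPHERE,
    altitude_to_pressure,
    rolling_mean3,
)
from .dynamics import level_fraction_summary, vertical_tortuosity
from .io import LoggerDataset

STEP_S = 300
MAX_SUSTAINED_RATE = 2.0  # m/s, the observed ceiling region for this species


class GenerationError(ValueError):
    """Raised when a scenario's flight plan is physically inconsistent."""


@dataclass(frozen=True)
class Segment:
    """One piecewise-linear piece of a flight plan."""

    duration_s: float
    displacement_m: float  # signed vertical change over the segment
    duty: float = 0.95  # flapping duty cycle while in this segment

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise GenerationError("segment duration must be positive")
        if not 0.0 <= self.duty <= 1.0:
            raise GenerationError("duty must be in [0, 1]")

    @property
    def rate_ms(self) -> float:
        return self.displacement_m / self.duration_s


def climb(displacement_m: float, rate_ms: float, duty: float = 0.95) -> Segment:
    if displacement_m <= 0 or rate_ms <= 0:
        raise GenerationError("climb needs positive displacement and rate")
    return Segment(displacement_m / rate_ms, displacement_m, duty)


def descend(displacement_m: float, rate_ms: float, duty: float = 0.95) -> Segment:
    if displacement_m <= 0 or rate_ms <= 0:
        raise GenerationError("descend needs positive displacement and rate")
    return Segment(displacement_m / rate_ms, -displacement_m, duty)


def hold(duration_s: float, duty: float = 0.95) -> Segment:
    return Segment(duration_s, 0.0, duty)


def wiggly_cruise(
    duration_s: float,
    amplitude_m: float = 60.0,
    duty: float = 0.95,
    level_every: int = 0,
) -> list[Segment]:
    """A cruise that alternates small climbs and descents every 5 min.

    ``level_every`` > 0 inserts a flat 5-min interval after every that many
    wiggle intervals (planting near-level samples at a known rate).
    """
    n = int(round(duration_s / STEP_S))
    segs: list[Segment] = []
    direction = 1
    since_level = 0
    net = 0.0
    for _ in range(n):
        if level_every and since_level >= level_every:
            segs.append(hold(STEP_S, duty))
            since_level = 0
        else:
            segs.append(Segment(STEP_S, direction * amplitude_m, duty))
            net += direction * amplitude_m
            direction = -direction
            since_level += 1
    if net != 0.0:  # keep the cruise altitude-neutral
        for i in range(len(segs) - 1, -1, -1):
            if segs[i].displacement_m == net:
                segs[i] = hold(STEP_S, duty)
                break
    return segs


@dataclass
class PlantedEvent:
    kind: str  # "terminated" | "midflight"
    descent_first: bool = False


@dataclass
class NightPlan:
    """One night's flight: start instant and the segment sequence."""

    date: dt.date
    start_hour_utc: float  # decimal hour, on the 5-min grid
    segments: list[Segment]
    planted_events: list[PlantedEvent] = field(default_factory=list)
    glide_descents: int = 0  # number of planted low-duty descents

    @property
    def start(self) -> pd.Timestamp:
        minutes = int(round(self.start_hour_utc * 60))
        if minutes % 5 != 0:
            raise GenerationError("night start must sit on the 5-min grid")
        return pd.Timestamp(self.date, tz="UTC") + pd.Timedelta(minutes=minutes)

    @property
    def duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.duration_s)


@dataclass
class BirdPlan:
    bird_id: str
    scale_max: int = 10
    nights: list[NightPlan] = field(default_factory=list)
    latitude_by_date: dict = field(default_factory=dict)
    rest_duty: float = 0.02


@dataclass
class ScenarioSpec:
    """Full description of a simulated deployment."""

    birds: list[BirdPlan]
    pressure_noise_sd_hpa: float = 0.5
    ground_elevation_m: float = 200.0
    activity_dropout: float = 0.0
    rng_seed: int = 0
    constants: AtmosphereConstants = field(default_factory=AtmosphereConstants)

    def validate(self) -> None:
        if not 0.0 <= self.activity_dropout < 1.0:
            raise GenerationError("activity_dropout must be in [0, 1)")
        if self.pressure_noise_sd_hpa < 0:
            raise GenerationError("pressure noise s.d. must be non-negative")
        for bird in self.birds:
            if bird.scale_max not in (5, 10):
                raise GenerationError(
                    f"{bird.bird_id}: scale_max must be 5 or 10"
                )
            last_end = None
            for night in sorted(bird.nights, key=lambda n: n.start):
                alt = self.ground_elevation_m
                for seg in night.segments:
                    if abs(seg.rate_ms) > MAX_SUSTAINED_RATE + 1e-9:
                        raise GenerationError(
                            f"{bird.bird_id} night {night.date}: sustained "
                            f"rate {seg.rate_ms:.2f} m/s exceeds "
                            f"{MAX_SUSTAINED_RATE} m/s"
                        )
                    alt += seg.displacement_m
                    if alt < self.ground_elevation_m - 1e-6:
                        raise GenerationError(
                            f"{bird.bird_id} night {night.date}: altitude "
                            "drops below ground"
                        )
                if abs(alt - self.ground_elevation_m) > 1.0:
                    raise GenerationError(
                        f"{bird.bird_id} night {night.date}: plan does not "
                        "return to ground"
                    )
                if last_end is not None and night.start < last_end:
                    raise GenerationError(
                        f"{bird.bird_id} night {night.date}: overlaps the "
                        "previous night"
                    )
                last_end = night.end


@dataclass
class TrueNight:
    """Ground truth for one planted flight."""

    bird_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration_s: float
    planted_events: list[PlantedEvent]
    glide_descents: int
    level_fraction: float
    tortuosity: float
    n_samples: int


@dataclass
class GroundTruth:
    nights: list[TrueNight]

    def table(self) -> pd.DataFrame:
        rows = []
        for n in self.nights:
            rows.append(
                {
                    "bird_id": n.bird_id,
                    "start": n.start,
                    "end": n.end,
                    "duration_s": n.duration_s,
                    "n_terminated": sum(
                        1 for e in n.planted_events if e.kind == "terminated"
                    ),
                    "n_midflight": sum(
                        1 for e in n.planted_events if e.kind == "midflight"
                    ),
                    "glide_descents": n.glide_descents,
                    "level_fraction": n.level_fraction,
                    "tortuosity": n.tortuosity,
                    "n_samples": n.n_samples,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        records = []
        for n in self.nights:
            records.append(
                {
                    "bird_id": n.bird_id,
                    "start": n.start.isoformat(),
                    "end": n.end.isoformat(),
                    "duration_s": n.duration_s,
                    "events": [
                        {"kind": e.kind, "descent_first": e.descent_first}
                        for e in n.planted_events
                    ],
                    "glide_descents": n.glide_descents,
                    "level_fraction": n.level_fraction,
                    "tortuosity": n.tortuosity,
                    "n_samples": n.n_samples,
                }
            )
        with open(path, "w") as fh:
            json.dump({"nights": records}, fh, indent=1)


def _night_altitude_profile(night: NightPlan, ground: float) -> tuple[np.ndarray, np.ndarray]:
    """True altitude on a 1-s lattice across the flight."""
    durations = np.array([s.duration_s for s in night.segments])
    displacements = np.array([s.displacement_m for s in night.segments])
    t_break = np.r_[0.0, np.cumsum(durations)]
    z_break = ground + np.r_[0.0, np.cumsum(displacements)]
    lattice = np.arange(0.0, t_break[-1] + 1.0)
    return lattice, np.interp(lattice, t_break, z_break)


def _night_duty_at(night: NightPlan, offsets_s: np.ndarray) -> np.ndarray:
    durations = np.array([s.duration_s for s in night.segments])
    duties = np.array([s.duty for s in night.segments])
    edges = np.cumsum(durations)
    idx = np.searchsorted(edges, offsets_s, side="right")
    idx = np.clip(idx, 0, len(duties) - 1)
    return duties[idx]


def generate_dataset(
    spec: ScenarioSpec, seed: int | None = None
) -> tuple[list[LoggerDataset], GroundTruth]:
    """Simulate logger streams for every bird in the scenario.

    Deterministic for a fixed (spec, seed); ``seed`` defaults to
    ``spec.rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    datasets: list[LoggerDataset] = []
    truths: list[TrueNight] = []
    for bird in sorted(spec.birds, key=lambda b: b.bird_id):
        nights = sorted(bird.nights, key=lambda n: n.start)
        if nights:
            t0 = nights[0].start.normalize()
            t1 = (nights[-1].end + pd.Timedelta(days=1)).normalize()
        else:
            t0 = t1 = pd.Timestamp("2000-01-01", tz="UTC")
        grid = pd.date_range(t0, t1, freq="5min", inclusive="left")
        alt = np.full(len(grid), spec.ground_elevation_m)
        duty = np.full(len(grid), bird.rest_duty)
        for night in nights:
            lattice, z = _night_altitude_profile(night, spec.ground_elevation_m)
            in_flight = (grid >= night.start) & (grid <= night.end)
            offs = (grid[in_flight].asi8 - night.start.value) / 1e9
            alt[in_flight] = z[offs.astype(int)]
            duty[in_flight] = _night_duty_at(night, offs)
            true_series = AltitudeSeries(grid[in_flight], alt[in_flight])
            if len(true_series) >= 3:
                lf = level_fraction_summary(true_series)["level_fraction"]
                tort = vertical_tortuosity(rolling_mean3(true_series))
            else:
                lf, tort = float("nan"), float("nan")
            truths.append(
                TrueNight(
                    bird_id=bird.bird_id,
                    start=night.start,
                    end=night.end,
                    duration_s=night.duration_s,
                    planted_events=list(night.planted_events),
                    glide_descents=night.glide_descents,
                    level_fraction=lf,
                    tortuosity=tort,
                    n_samples=int(in_flight.sum()),
                )
            )
        pressure = altitude_to_pressure(alt, spec.constants)
        if spec.pressure_noise_sd_hpa > 0:
            pressure = pressure + rng.normal(
                0.0, spec.pressure_noise_sd_hpa, len(pressure)
            )
        scores = rng.binomial(bird.scale_max, duty)
        keep = np.ones(len(grid), dtype=bool)
        if spec.activity_dropout > 0:
            keep = rng.random(len(grid)) >= spec.activity_dropout
        activity = pd.DataFrame(
            {
                "timestamp": grid[keep],
                "score": scores[keep],
                "scale_max": bird.scale_max,
            }
        )
        pressure_df = pd.DataFrame(
            {"timestamp": grid, "pressure_hpa": pressure}
        )
        datasets.append(
            LoggerDataset(
                bird_id=bird.bird_id,
                activity=activity,
                pressure=pressure_df,
                daily_latitude=dict(bird.latitude_by_date),
            )
        )
    return datasets, GroundTruth(truths)


# ---------------------------------------------------------------------------
# Plan builders for the study-like conditions


def _snap(duration_s: float) -> float:
    """Round a duration to the 5-min sampling grid (at least one step)."""
    return max(STEP_S, round(duration_s / STEP_S) * STEP_S)


def migratory_night(
    date: dt.date,
    start_hour_utc: float = 20.0,
    duration_h: float = 6.0,
    cruise_alt_m: float = 1500.0,
    climb_rate_ms: float = 0.5,
    descent_rate_ms: float = 0.5,
    duty: float = 0.95,
    wiggle_m: float = 60.0,
    level_every: int = 2,
) -> NightPlan:
    """An ordinary migratory flight: ascent, structured cruise, descent.

    Segment boundaries are snapped to the 5-min grid so the planted cruise
    structure (level runs, wiggles) survives sampling; climb and descent
    rates are adjusted accordingly.
    """
    t_up = _snap(cruise_alt_m / climb_rate_ms)
    t_down = _snap(cruise_alt_m / descent_rate_ms)
    t_cruise = _snap(duration_h * 3600) - t_up - t_down
    if t_cruise < STEP_S:
        raise GenerationError("flight too short for its climb and descent")
    segments = [
        Segment(t_up, cruise_alt_m, duty),
        *wiggly_cruise(t_cruise, wiggle_m, duty, level_every),
        Segment(t_down, -cruise_alt_m, duty),
    ]
    return NightPlan(date, start_hour_utc, segments)


def terminated_exploratory_night(
    date: dt.date,
    start_hour_utc: float = 21.0,
    height_m: float = 600.0,
    ascent_min: float = 40.0,
    descent_min: float = 30.0,
    duty: float = 0.95,
) -> NightPlan:
    """A short flight that is one climb then one descent, then landing."""
    t_up = _snap(ascent_min * 60)
    t_down = _snap(descent_min * 60)
    return NightPlan(
        date,
        start_hour_utc,
        [Segment(t_up, height_m, duty), Segment(t_down, -height_m, duty)],
        planted_events=[PlantedEvent("terminated")],
    )


def midflight_exploratory_night(
    date: dt.date,
    start_hour_utc: float = 19.0,
    duration_h: float = 7.0,
    cruise_alt_m: float = 2000.0,
    excursion_m: float = 700.0,
    descent_first: bool = True,
    duty: float = 0.95,
) -> NightPlan:
    """A migratory flight holding one planted to-and-fro excursion."""
    t_edge = _snap(cruise_alt_m / 0.5)
    t_leg = _snap(excursion_m / 0.4)
    t_cruise = _snap(duration_h * 3600) - 2 * t_edge - 2 * t_leg
    if t_cruise < 2 * STEP_S:
        raise GenerationError("flight too short for the planted excursion")
    sign = -1 if descent_first else 1
    segments = [
        Segment(t_edge, cruise_alt_m, duty),
        *wiggly_cruise(_snap(t_cruise / 2), 60.0, duty),
        Segment(t_leg, sign * excursion_m, duty),
        Segment(t_leg, -sign * excursion_m, duty),
        *wiggly_cruise(_snap(t_cruise / 2), 60.0, duty),
        Segment(t_edge, -cruise_alt_m, duty),
    ]
    return NightPlan(
        date,
        start_hour_utc,
        segments,
        planted_events=[PlantedEvent("midflight", descent_first=descent_first)],
    )


def glide_descent_night(
    date: dt.date,
    start_hour_utc: float = 20.0,
    cruise_alt_m: float = 1800.0,
    sink_rate_ms: float = 0.91,
    duration_h: float = 4.0,
    duty: float = 0.95,
    glide_duty: float = 0.1,
) -> NightPlan:
    """A flight whose terminal descent is a low-activity glide."""
    t_up = _snap(cruise_alt_m / 0.5)
    t_down = _snap(cruise_alt_m / sink_rate_ms)
    t_cruise = _snap(duration_h * 3600) - t_up - t_down
    if t_cruise < STEP_S:
        raise GenerationError("flight too short for its glide descent")
    # flat cruise: the descent run then starts cleanly at the glide, so the
    # recovered sink rate is limited only by the 5-min discretisation
    segments = [
        Segment(t_up, cruise_alt_m, duty),
        hold(t_cruise, duty),
        Segment(t_down, -cruise_alt_m, glide_duty),
    ]
    return NightPlan(date, start_hour_utc, segments, glide_descents=1)


def level_fraction_night(
    date: dt.date,
    level_fraction: float,
    start_hour_utc: float = 20.0,
    duration_h: float = 8.0,
    cruise_alt_m: float = 1500.0,
    wiggle_m: float = 100.0,
    duty: float = 0.95,
) -> NightPlan:
    """A flight whose cruise interleaves flat and wiggling 5-min intervals
    so that a target fraction of intervals is near-level.

    The exact realised fraction (including the non-level climb and descent
    intervals) is what the generated ground truth records.
    """
    if not 0.0 <= level_fraction <= 1.0:
        raise GenerationError("level_fraction must be in [0, 1]")
    t_edge = _snap(cruise_alt_m / 0.5)
    t_cruise = _snap(duration_h * 3600) - 2 * t_edge
    n = int(t_cruise / STEP_S)
    if n < 4:
        raise GenerationError("flight too short for a structured cruise")
    segs: list[Segment] = [Segment(t_edge, cruise_alt_m, duty)]
    direction = 1
    net = 0.0
    acc = 0.0
    for _ in range(n):
        acc += level_fraction
        if acc >= 1.0:  # Bresenham-style spreading of the level intervals
            acc -= 1.0
            segs.append(hold(STEP_S, duty))
        else:
            segs.append(Segment(STEP_S, direction * wiggle_m, duty))
            net += direction * wiggle_m
            direction = -direction
    if net != 0.0:
        for i in range(len(segs) - 1, 0, -1):
            if segs[i].displacement_m == net:
                segs[i] = hold(STEP_S, duty)
                break
    segs.append(Segment(t_edge, -cruise_alt_m, duty))
    return NightPlan(date, start_hour_utc, segs)


def migration_scenario(
    n_birds: int = 4,
    nights_per_bird: int = 5,
    season: str = "autumn",
    rng_seed: int = 0,
    pressure_noise_sd_hpa: float = 0.5,
    activity_dropout: float = 0.0,
) -> ScenarioSpec:
    """A deployment-like scenario mixing the study's flight types.

    Each bird flies ``nights_per_bird`` nights: mostly ordinary migratory
    flights of 4-9 h at 1000-2500 m cruise, plus one terminated exploratory
    short flight and one mid-flight excursion per bird. Autumn birds track
    south from 55N toward 5N (spring reversed); logger scales alternate
    between 10 and 5 across birds.
    """
    rng = np.random.default_rng(rng_seed)
    start = dt.date(2018, 9, 10) if season == "autumn" else dt.date(2019, 4, 5)
    birds: list[BirdPlan] = []
    for b in range(n_birds):
        bird_id = f"bird{b:02d}"
        scale = 10 if b % 2 == 0 else 5
        nights: list[NightPlan] = []
        lat_path = {}
        lat0, lat1 = (55.0, 5.0) if season == "autumn" else (5.0, 55.0)
        for k in range(nights_per_bird):
            date = start + dt.timedelta(days=2 * k + b)
            frac = k / max(nights_per_bird - 1, 1)
            lat_path[date] = lat0 + frac * (lat1 - lat0)
            if k == 1:
                nights.append(terminated_exploratory_night(date))
            elif k == 2:
                nights.append(
                    midflight_exploratory_night(
                        date, descent_first=bool(rng.integers(2))
                    )
                )
            else:
                nights.append(
                    migratory_night(
                        date,
                        duration_h=float(rng.uniform(4.0, 9.0)),
                        cruise_alt_m=float(rng.uniform(1000.0, 2500.0)),
                    )
                )
        birds.append(
            BirdPlan(
                bird_id=bird_id,
                scale_max=scale,
                nights=nights,
                latitude_by_date=lat_path,
            )
        )
    return ScenarioSpec(
        birds=birds,
        pressure_noise_sd_hpa=pressure_noise_sd_hpa,
        activity_dropout=activity_dropout,
        rng_seed=rng_seed,
    )
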