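"""Exploratory movements, windowed ascent maxima and descent segments.

A bird unable to judge winds aloft from the ground may climb, sample the
conditions, and either abort the flight (a *terminated* exploratory
movement: one ascent directly followed by one descent, after which the
flight ends) or continue cruising (a *mid-flight* exploratory movement: two
consecutive opposite vertical displacements embedded in a longer flight).
Both use the same thresholds: a 500-m minimum displacement and a mean
vertical rate above 0.1 m/s.

Also here: the per-episode maximum ascent rate over 5- and 20-min windows
with the total-climb inclusion filter, and >=10-min descent segments
classified as active or gliding from the activity duty cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .altimetry import AltitudeSeries, rolling_mean3, vertical_displacement
from .config import PipelineConfig
from .dynamics import run_decomposition
from .segmentation import FlightEpisode, is_flight_level

STEP_S = 300


@dataclass(frozen=True)
class EventLeg:
    direction: int  # +1 ascent, -1 descent
    displacement_m: float
    duration_s: float
    rate_ms: float  # mean |rate| over the leg's active span


@dataclass
class ExploratoryEvent:
    episode_id: str
    kind: str  # "terminated" | "midflight"
    leg1: EventLeg
    leg2: EventLeg
    descent_first: bool
    t_start: pd.Timestamp
    t_end: pd.Timestamp


@dataclass
class DescentSegment:
    episode_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration_s: float
    rate_ms: float  # negative, from endpoint-trimmed run
    mode: str  # "active" | "glide"
    mean_duty: float
    n_samples: int


@dataclass
class AscentMaxima:
    episode_id: str
    window_s: int
    max_rate_ms: float  # nan when the series is shorter than the window
    total_climb_m: float
    passes_filter: bool
    defined: bool


def _legs_from_runs(runs: pd.DataFrame) -> list[EventLeg]:
    legs = []
    for _, r in runs.iterrows():
        legs.append(
            EventLeg(
                direction=int(r["direction"]),
                displacement_m=float(r["displacement_m"]),
                duration_s=float(r["duration_s"]),
                rate_ms=float(r["active_rate_ms"]),
            )
        )
    return legs


def detect_terminated_exploratory(
    episodes: Iterable[FlightEpisode], config: PipelineConfig | None = None
) -> list[ExploratoryEvent]:
    """Terminated exploratory movements among flights of <= 3 h.

    A short flight qualifies when its smoothed profile is exactly one
    ascent run followed by one descent run, the climb reaches the 500-m
    minimum (both legs if ``terminated_require_both_legs``), and the rate
    criterion (> 0.1 m/s) holds flight-wide (default) or per leg.
    """
    config = config or PipelineConfig()
    out: list[ExploratoryEvent] = []
    for ep in episodes:
        if ep.duration_s > config.min_flight_duration_s:
            continue
        if len(ep.altitude) < 3:
            warnings.warn(
                f"episode {ep.episode_id}: no usable altitude data, skipped"
            )
            continue
        smoothed = rolling_mean3(ep.altitude)
        runs = run_decomposition(smoothed)
        if len(runs) != 2:
            continue
        if not (runs.iloc[0]["direction"] == 1 and runs.iloc[1]["direction"] == -1):
            continue
        ascent, descent = _legs_from_runs(runs)
        min_disp = config.exploratory_min_displacement_m
        if ascent.displacement_m < min_disp:
            continue
        if config.terminated_require_both_legs and abs(descent.displacement_m) < min_disp:
            continue
        if config.terminated_rate_scope == "flight":
            disp = vertical_displacement(smoothed)
            mean_rate = float(disp["rate_ms"].abs().mean())
            if not mean_rate > config.exploratory_min_rate_ms:
                continue
        else:
            if not all(
                leg.rate_ms > config.exploratory_min_rate_ms
                for leg in (ascent, descent)
            ):
                continue
        out.append(
            ExploratoryEvent(
                episode_id=ep.episode_id,
                kind="terminated",
                leg1=ascent,
                leg2=descent,
                descent_first=False,
                t_start=smoothed.timestamps[int(runs.iloc[0]["i_start"])],
                t_end=smoothed.timestamps[int(runs.iloc[1]["i_end"])],
            )
        )
    return out


def detect_midflight_exploratory(
    episodes: Iterable[FlightEpisode], config: PipelineConfig | None = None
) -> list[ExploratoryEvent]:
    """Mid-flight to-and-fro movements inside migratory episodes.

    Scans the smoothed run decomposition for adjacent opposite-direction
    interior runs (the episode's first and last runs are the ordinary
    initial climb and terminal descent and never form an event), each with
    |displacement| >= 500 m and a leg rate > 0.1 m/s. Overlapping
    candidates resolve greedily left to right.
    """
    config = config or PipelineConfig()
    out: list[ExploratoryEvent] = []
    for ep in episodes:
        if ep.duration_s <= config.min_flight_duration_s:
            continue
        if len(ep.altitude) < 5:
            continue
        smoothed = rolling_mean3(ep.altitude)
        runs = run_decomposition(smoothed)
        if len(runs) < 4:
            continue
        legs = _legs_from_runs(runs)
        min_disp = config.exploratory_min_displacement_m
        min_rate = config.exploratory_min_rate_ms
        if config.midflight_rate_scope == "flight":
            disp = vertical_displacement(smoothed)
            flight_ok = float(disp["rate_ms"].abs().mean()) > min_rate
        i = 1
        while i + 1 <= len(legs) - 2:
            a, b = legs[i], legs[i + 1]
            pair_ok = (
                a.direction != 0
                and b.direction == -a.direction
                and abs(a.displacement_m) >= min_disp
                and abs(b.displacement_m) >= min_disp
            )
            if pair_ok:
                if config.midflight_rate_scope == "leg":
                    pair_ok = a.rate_ms > min_rate and b.rate_ms > min_rate
                else:
                    pair_ok = flight_ok
            if pair_ok:
                out.append(
                    ExploratoryEvent(
                        episode_id=ep.episode_id,
                        kind="midflight",
                        leg1=a,
                        leg2=b,
                        descent_first=a.direction == -1,
                        t_start=smoothed.timestamps[int(runs.iloc[i]["i_start"])],
                        t_end=smoothed.timestamps[int(runs.iloc[i + 1]["i_end"])],
                    )
                )
                i += 2
            else:
                i += 1
    return out


def max_ascent_rate(
    series: AltitudeSeries,
    window_s: int,
    benchmark_climb_rate_ms: float = 1.16,
    episode_id: str = "",
) -> AscentMaxima:
    """Maximum ascent rate over aligned windows of ``window_s`` seconds.

    The maximum runs over every start index whose window spans exactly
    ``window_s`` on the 5-min grid (gaps invalidate a window). The segment
    passes the inclusion filter when the flight's total climb exceeds the
    altitude a bird climbing at the theoretical maximum rate would cover in
    one window — guarding against trivially small climbs saturating the
    statistic.
    """
    if window_s % STEP_S != 0:
        raise ValueError("window must be a multiple of 300 s")
    k = window_s // STEP_S
    z = series.altitude
    t = series.timestamps.asi8 / 1e9
    dz = np.diff(z)
    total_climb = float(dz[dz > 0].sum()) if len(dz) else 0.0
    if len(z) < k + 1:
        return AscentMaxima(
            episode_id=episode_id,
            window_s=window_s,
            max_rate_ms=float("nan"),
            total_climb_m=total_climb,
            passes_filter=False,
            defined=False,
        )
    spans = t[k:] - t[:-k]
    gains = z[k:] - z[:-k]
    valid = spans == window_s
    if not valid.any():
        return AscentMaxima(
            episode_id=episode_id,
            window_s=window_s,
            max_rate_ms=float("nan"),
            total_climb_m=total_climb,
            passes_filter=False,
            defined=False,
        )
    max_rate = float(np.max(gains[valid]) / window_s)
    return AscentMaxima(
        episode_id=episode_id,
        window_s=window_s,
        max_rate_ms=max_rate,
        total_climb_m=total_climb,
        passes_filter=total_climb > benchmark_climb_rate_ms * window_s,
        defined=True,
    )


def ascent_maxima_for_episode(
    episode: FlightEpisode, config: PipelineConfig | None = None
) -> list[AscentMaxima]:
    config = config or PipelineConfig()
    if len(episode.altitude) < 2:
        return []
    return [
        max_ascent_rate(
            episode.altitude,
            w,
            config.benchmark_climb_rate_ms,
            episode.episode_id,
        )
        for w in config.ascent_windows_s
    ]


def extract_descents(
    episode: FlightEpisode, config: PipelineConfig | None = None
) -> list[DescentSegment]:
    """Descent segments within one episode's attached streams.

    Gliding terminal descents often continue past the episode boundary
    (low activity no longer counts as flight), so pipelines searching for
    glides should prefer :func:`find_descent_segments` on the full per-bird
    streams.
    """
    return find_descent_segments(
        episode.altitude, episode.activity, config, episode.episode_id
    )


def find_descent_segments(
    altitude: AltitudeSeries,
    activity: pd.DataFrame,
    config: PipelineConfig | None = None,
    episode_id: str = "",
) -> list[DescentSegment]:
    """Descent segments of >= 10 min following flight-level activity.

    Operates on the three-point smoothed altitude. A segment is a maximal
    run of non-increasing smoothed altitude (single-interval plateaus
    tolerated unless ``descent_strictly_decreasing``) whose start follows a
    flight-level activity sample. The first and last record of each run are
    excluded — they may include time still in powered cruise or after
    landing — before the rate is computed from the remaining endpoints, so
    usable runs have at least four records. Mode is "glide" when the mean
    activity duty over the run is below the flapping threshold.
    """
    config = config or PipelineConfig()
    if len(altitude) < 4:
        return []
    smoothed = rolling_mean3(altitude)
    dz = np.diff(smoothed.altitude)
    dt = np.diff(smoothed.timestamps.asi8) / 1e9
    on_grid = dt == STEP_S  # gaps break a run
    neg = (dz < 0) & on_grid
    if config.descent_strictly_decreasing:
        ok = neg
    else:
        # a single zero interval inside a descent is tolerated (brief
        # intermittent flight or an updraft); runs still start and end on
        # strictly decreasing intervals
        zero = (dz == 0) & on_grid
        ok = neg.copy()
        for m in np.flatnonzero(zero):
            if 0 < m < len(dz) - 1 and neg[m - 1] and neg[m + 1]:
                ok[m] = True
    act = activity
    duty = (
        act["score"].to_numpy() / act["scale_max"].to_numpy()
        if len(act)
        else np.array([])
    )
    level = (
        is_flight_level(
            act["score"].to_numpy(),
            act["scale_max"].to_numpy(),
            config.activity_duty_threshold,
        )
        if len(act)
        else np.array([], dtype=bool)
    )
    act_ts = (
        act["timestamp"].dt.tz_convert(None).to_numpy()
        if len(act)
        else np.array([], dtype="datetime64[ns]")
    )
    out: list[DescentSegment] = []
    i = 0
    n = len(ok)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        # run covers samples i .. j+1
        i0, i1 = i, j + 1
        t0, t1 = smoothed.timestamps[i0], smoothed.timestamps[i1]
        span = (t1 - t0).total_seconds()
        n_samples = i1 - i0 + 1
        if span >= config.descent_min_duration_s and n_samples >= 4:
            preceding = act_ts <= np.datetime64(t0.tz_convert(None))
            starts_after_flight = bool(level[preceding][-1]) if preceding.any() else False
            if starts_after_flight:
                za, zb = smoothed.altitude[i0 + 1], smoothed.altitude[i1 - 1]
                ta, tb = smoothed.timestamps[i0 + 1], smoothed.timestamps[i1 - 1]
                rate = (zb - za) / (tb - ta).total_seconds()
                if rate < 0:
                    in_run = (act_ts >= np.datetime64(t0.tz_convert(None))) & (
                        act_ts <= np.datetime64(t1.tz_convert(None))
                    )
                    mean_duty = float(duty[in_run].mean()) if in_run.any() else 1.0
                    out.append(
                        DescentSegment(
                            episode_id=episode_id,
                            start=t0,
                            end=t1,
                            duration_s=span,
                            rate_ms=float(rate),
                            mode=(
                                "glide"
                                if mean_duty < config.activity_duty_threshold
                                else "active"
                            ),
                            mean_duty=mean_duty,
                            n_samples=n_samples,
                        )
                    )
        i = j + 1
    return out


def events_table(events: Sequence[ExploratoryEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "episode_id": ev.episode_id,
                "kind": ev.kind,
                "descent_first": ev.descent_first,
                "t_start": ev.t_start,
                "t_end": ev.t_end,
                "leg1_direction": ev.leg1.direction,
                "leg1_displacement_m": ev.leg1.displacement_m,
                "leg1_duration_s": ev.leg1.duration_s,
                "leg1_rate_ms": ev.leg1.rate_ms,
                "leg2_direction": ev.leg2.direction,
                "leg2_displacement_m": ev.leg2.displacement_m,
                "leg2_duration_s": ev.leg2.duration_s,
                "leg2_rate_ms": ev.leg2.rate_ms,
            }
        )
    return pd.DataFrame(rows)


def descents_table(descents: Sequence[DescentSegment]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in descents])


def ascents_table(ascents: Sequence[AscentMaxima]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in ascents])
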