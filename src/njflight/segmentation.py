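"""Flight-episode extraction from 5-min activity scores.

Sustained flapping flight shows up as high activity scores. Extraction is
two-step: (1) clock-hours with at least 7 flight-level registrations (score
at or above 60% of the logger's scale, i.e. >=6 of 10 or >=3 of 5) are core
flight hours, and maximal runs of consecutive core hours form the core
period; (2) the boundary is extended into the single adjacent hour on each
side by 5 min per qualifying registration found there. Episodes strictly
longer than 3 h are classed migratory; shorter ones are kept as "short"
flights because terminated exploratory movements live there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .altimetry import (
    AltitudeSeries,
    AtmosphereConstants,
    STANDARD_ATMOSPHERE,
    altitude_series_from_pressure,
)
from .config import PipelineConfig
from .io import ActivitySample, LoggerDataset

HOUR_S = 3600
STEP_S = 300

REGION_EUROPE = "Europe"
REGION_SAHARA = "Sahara"
REGION_SUBSAHARAN = "subSaharan"
REGION_UNKNOWN = "unknown"


@dataclass
class FlightEpisode:
    """One contiguous flight, core hours plus pre/post extensions."""

    bird_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    core_hours: list
    n_pre: int
    n_post: int
    altitude: AltitudeSeries
    activity: pd.DataFrame
    region: str = REGION_UNKNOWN
    season: str = ""
    episode_id: str = ""

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    def is_migratory(self, min_duration_s: float = 10800.0) -> bool:
        return self.duration_s > min_duration_s

    @property
    def flight_class(self) -> str:
        return "migratory" if self.is_migratory() else "short"


def is_flight_level(
    sample, scale_max: int | None = None, duty_threshold: float = 0.6
):
    """True where an activity score indicates flapping flight.

    Accepts an :class:`ActivitySample`, or ``(score, scale_max)`` scalars or
    arrays. A sample is flight-level when score/scale_max >= duty_threshold,
    i.e. score >=6 on the 0-10 scale and >=3 on the 0-5 scale at the 0.6
    default.
    """
    if isinstance(sample, ActivitySample):
        score, scale = sample.score, sample.scale_max
    else:
        if scale_max is None:
            raise TypeError("scale_max required when passing a bare score")
        score, scale = sample, scale_max
    score = np.asarray(score, dtype=float)
    scale = np.asarray(scale, dtype=float)
    out = score / scale >= duty_threshold
    return bool(out) if out.ndim == 0 else out


def find_core_hours(
    activity: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DatetimeIndex:
    """Clock-hours (UTC, hour starts) qualifying as core flight hours.

    An hour is core when at least ``core_hour_min_count`` of its (at most
    12) 5-min samples are flight-level.
    """
    config = config or PipelineConfig()
    if len(activity) == 0:
        return pd.DatetimeIndex([], tz="UTC")
    level = is_flight_level(
        activity["score"].to_numpy(),
        activity["scale_max"].to_numpy(),
        config.activity_duty_threshold,
    )
    hours = activity["timestamp"].dt.floor("h")
    counts = pd.Series(level.astype(int)).groupby(hours.to_numpy()).sum()
    core = counts[counts >= config.core_hour_min_count].index
    return pd.DatetimeIndex(sorted(core))


def _qualifying_in_hour(
    activity: pd.DataFrame,
    hour_start: pd.Timestamp,
    config: PipelineConfig,
    side: str,
) -> int:
    """Count flight-level samples in one adjacent hour.

    In contiguous mode only the samples forming an unbroken 5-min chain
    against the core boundary count.
    """
    hour_end = hour_start + pd.Timedelta(seconds=HOUR_S)
    mask = (activity["timestamp"] >= hour_start) & (activity["timestamp"] < hour_end)
    sub = activity.loc[mask]
    if len(sub) == 0:
        return 0
    level = is_flight_level(
        sub["score"].to_numpy(),
        sub["scale_max"].to_numpy(),
        config.activity_duty_threshold,
    )
    if not config.pre_post_contiguous:
        return int(level.sum())
    ts = sub["timestamp"].to_numpy()
    order = np.argsort(ts)
    ts, level = ts[order], level[order]
    if side == "pre":
        ts, level = ts[::-1], level[::-1]
        anchor = hour_end - pd.Timedelta(seconds=STEP_S)
        step = -STEP_S
    else:
        anchor = hour_start
        step = STEP_S
    count = 0
    expected = pd.Timestamp(anchor)
    for t, lv in zip(ts, level):
        if pd.Timestamp(t) != expected or not lv:
            break
        count += 1
        expected = expected + pd.Timedelta(seconds=step)
    return count


def assign_region(
    latitude: float | None, breaks: Sequence[float] = (8.0, 38.0)
) -> str:
    """Region label from latitude: >38N Europe, 8-38N Sahara belt, <8N
    sub-Saharan Africa; missing latitude gives "unknown"."""
    if latitude is None or (isinstance(latitude, float) and np.isnan(latitude)):
        return REGION_UNKNOWN
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    low, high = breaks
    if latitude > high:
        return REGION_EUROPE
    if latitude < low:
        return REGION_SUBSAHARAN
    return REGION_SAHARA


def assign_season(
    when: pd.Timestamp,
    daily_latitude: dict | None = None,
    rule: str = "calendar",
) -> str:
    """Season of a flight: autumn or spring.

    The calendar rule maps July-December to autumn and January-June to
    spring. The direction rule uses the net latitude change over the week
    around the date (southbound -> autumn, northbound -> spring) and falls
    back to the calendar rule when no net movement is resolvable.
    """
    if rule == "direction" and daily_latitude:
        date = when.date()
        before = [d for d in daily_latitude if 0 < (date - d).days <= 3]
        after = [d for d in daily_latitude if 0 <= (d - date).days <= 3]
        if before and after:
            lat0 = daily_latitude[min(before, key=lambda d: (date - d).days)]
            lat1 = daily_latitude[max(after, key=lambda d: (d - date).days)]
            if lat1 < lat0:
                return "autumn"
            if lat1 > lat0:
                return "spring"
    return "autumn" if when.month >= 7 else "spring"


def extract_flight_episodes(
    dataset: LoggerDataset,
    config: PipelineConfig | None = None,
    constants: AtmosphereConstants = STANDARD_ATMOSPHERE,
) -> list[FlightEpisode]:
    """All flight episodes of one bird, migratory and short.

    One episode per maximal run of consecutive core hours, extended by the
    qualifying samples of the single hour on each side; altitude samples
    within the episode are attached (converted from pressure).
    """
    config = config or PipelineConfig()
    core = find_core_hours(dataset.activity, config)
    episodes: list[FlightEpisode] = []
    if len(core) == 0:
        return episodes
    altitude_full = altitude_series_from_pressure(
        dataset.pressure["timestamp"],
        dataset.pressure["pressure_hpa"],
        constants,
    )
    # split core hours into consecutive runs
    gaps = np.flatnonzero(np.diff(core.asi8) > HOUR_S * 1e9)
    starts = np.r_[0, gaps + 1]
    ends = np.r_[gaps, len(core) - 1]
    for k, (i0, i1) in enumerate(zip(starts, ends)):
        run = core[i0 : i1 + 1]
        core_start = run[0]
        core_end = run[-1] + pd.Timedelta(seconds=HOUR_S)
        n_pre = _qualifying_in_hour(
            dataset.activity,
            core_start - pd.Timedelta(seconds=HOUR_S),
            config,
            "pre",
        )
        n_post = _qualifying_in_hour(dataset.activity, core_end, config, "post")
        start = core_start - pd.Timedelta(seconds=STEP_S * n_pre)
        end = core_end + pd.Timedelta(seconds=STEP_S * n_post)
        act_mask = (dataset.activity["timestamp"] >= start) & (
            dataset.activity["timestamp"] <= end
        )
        mid = start + (end - start) / 2
        lat = dataset.latitude_at(mid)
        ep = FlightEpisode(
            bird_id=dataset.bird_id,
            start=start,
            end=end,
            core_hours=list(run),
            n_pre=n_pre,
            n_post=n_post,
            altitude=altitude_full.slice_time(start, end),
            activity=dataset.activity.loc[act_mask].reset_index(drop=True),
            region=assign_region(lat, config.region_lat_breaks_degN),
            season=assign_season(
                mid, dataset.daily_latitude, config.season_rule
            ),
            episode_id=f"{dataset.bird_id}:{k:03d}",
        )
        episodes.append(ep)
    return episodes


def episodes_table(
    episodes: Sequence[FlightEpisode], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Summary table of episodes (one row each)."""
    config = config or PipelineConfig()
    rows = []
    for ep in episodes:
        rows.append(
            {
                "episode_id": ep.episode_id,
                "bird_id": ep.bird_id,
                "start": ep.start,
                "end": ep.end,
                "duration_s": ep.duration_s,
                "n_core_hours": len(ep.core_hours),
                "class": (
                    "migratory"
                    if ep.duration_s > config.min_flight_duration_s
                    else "short"
                ),
                "region": ep.region,
                "season": ep.season,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "episode_id",
            "bird_id",
            "start",
            "end",
            "duration_s",
            "n_core_hours",
            "class",
            "region",
            "season",
        ],
    )
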