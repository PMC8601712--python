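"""Pipeline configuration.

Every behavioural threshold of the pipeline is a named key with the study's
value as default, so a run is fully described by one small YAML mapping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds of the flight-altitude pipeline.

    Parameters
    ----------
    level_threshold_m
        Absolute 5-min altitude change (m) below which an interval counts as
        near-level flight (strict ``<``); 30 m corresponds to <0.1 m/s.
    exploratory_min_displacement_m
        Minimum vertical displacement (m) of an exploratory-movement leg.
    exploratory_min_rate_ms
        Minimum mean absolute vertical rate (m/s) for exploratory movements
        (strict ``>``).
    core_hour_min_count
        Number of flight-level 5-min samples (out of <=12) that make a
        clock-hour a core flight hour.
    activity_duty_threshold
        Fraction of accelerometer sub-measurements active at or above which a
        sample counts as flapping flight (>=6 of 10 or >=3 of 5).
    min_flight_duration_s
        Episodes strictly longer than this are classed migratory (3 h).
    descent_min_duration_s
        Minimum span of a descent run to be analysed (10 min).
    ascent_windows_s
        Window lengths for windowed maximum ascent rates.
    benchmark_climb_rate_ms
        Theoretical maximum sustained climb rate (m/s) used by the
        total-climb inclusion filter for ascent maxima.
    region_lat_breaks_degN
        Latitude breaks (deg N) separating sub-Saharan Africa / Sahara belt /
        Europe.
    season_rule
        "calendar" (Jul-Dec autumn, Jan-Jun spring) or "direction"
        (net latitude change over the surrounding week).
    pre_post_contiguous
        If True, pre/post-core extension counts only samples contiguous with
        the core period instead of all qualifying samples in the hour.
    hour_alignment
        "utc" clock-hours (default) or "local" (offset by longitude when
        available; falls back to UTC).
    level_basis / delta_basis
        Which altitude series ("raw" or "smoothed") feeds near-level
        classification and the displacement statistics respectively.
    terminated_rate_scope / midflight_rate_scope
        Whether the 0.1 m/s exploratory rate test applies to the whole
        flight ("flight") or each leg ("leg").
    terminated_require_both_legs
        If True both legs of a terminated event must reach the 500-m
        displacement; default requires only the ascent.
    descent_strictly_decreasing
        If True descent runs exclude internal zero-change plateaus.
    rng_seed
        Seed for any stochastic step (simulation, permutation tests).
    """

    level_threshold_m: float = 30.0
    large_threshold_m: float = 300.0
    exploratory_min_displacement_m: float = 500.0
    exploratory_min_rate_ms: float = 0.1
    core_hour_min_count: int = 7
    activity_duty_threshold: float = 0.6
    min_flight_duration_s: float = 10800.0
    descent_min_duration_s: float = 600.0
    ascent_windows_s: tuple[int, ...] = (300, 1200)
    benchmark_climb_rate_ms: float = 1.16
    region_lat_breaks_degN: tuple[float, float] = (8.0, 38.0)
    season_rule: str = "calendar"
    pre_post_contiguous: bool = False
    hour_alignment: str = "utc"
    level_basis: str = "raw"
    delta_basis: str = "smoothed"
    terminated_rate_scope: str = "flight"
    midflight_rate_scope: str = "leg"
    terminated_require_both_legs: bool = False
    descent_strictly_decreasing: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "level_threshold_m",
            "large_threshold_m",
            "exploratory_min_displacement_m",
            "exploratory_min_rate_ms",
            "activity_duty_threshold",
            "min_flight_duration_s",
            "descent_min_duration_s",
            "benchmark_climb_rate_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.core_hour_min_count <= 0:
            raise ValueError("core_hour_min_count must be positive")
        breaks = tuple(float(b) for b in self.region_lat_breaks_degN)
        if list(breaks) != sorted(breaks):
            raise ValueError("region_lat_breaks_degN must be ascending")
        self.region_lat_breaks_degN = breaks
        self.ascent_windows_s = tuple(int(w) for w in self.ascent_windows_s)
        if any(w % 300 != 0 for w in self.ascent_windows_s):
            raise ValueError("ascent windows must be multiples of 300 s")
        if self.season_rule not in ("calendar", "direction"):
            raise ValueError("season_rule must be 'calendar' or 'direction'")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ascent_windows_s"] = list(self.ascent_windows_s)
        d["region_lat_breaks_degN"] = list(self.region_lat_breaks_degN)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
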