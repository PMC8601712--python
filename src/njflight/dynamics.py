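"""Within-flight altitude-variation statistics.

Three descriptors summarise how much a flight departs from level cruising:

* the fraction of 5-min intervals with an absolute altitude change below
  30 m (near-level flight, <0.1 m/s on average), with companion classes
  30-300 m (intermediate) and >=300 m (large, >=1 m/s);
* the mean vertical speed, the average of |dz|/dt over the intervals;
* the vertical tortuosity, the number of ascent<->descent direction shifts
  divided by (number of altitude recordings - 1), 0 for a monotone profile
  and approaching 1 for a continuous zigzag.

Because the initial climb and final descent can dominate these numbers,
each statistic also has a cruise-phase variant computed after trimming the
first and last maximal monotone runs.

Interval direction uses a zero-carry rule: a zero altitude change inherits
the previous (or, at the start, the next) non-zero direction, so plateaus
inside a climb neither count as shifts nor split the run. The same
decomposition defines the legs used by the exploratory-event detectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .altimetry import AltitudeSeries, rolling_mean3, vertical_displacement
from .config import PipelineConfig
from .segmentation import FlightEpisode


def interval_directions(dz: np.ndarray) -> np.ndarray:
    """Sign of each interval's altitude change with zero-carry.

    Zeros take the previous non-zero sign; leading zeros take the first
    non-zero sign. An all-zero input stays all zero.
    """
    dz = np.asarray(dz, dtype=float)
    signs = np.sign(dz).astype(int)
    nz = np.flatnonzero(signs)
    if len(nz) == 0:
        return signs
    # forward-fill non-zero signs, then back-fill the leading zeros
    idx = np.maximum.accumulate(np.where(signs != 0, np.arange(len(signs)), -1))
    out = np.where(idx >= 0, signs[np.clip(idx, 0, None)], signs[nz[0]])
    return out.astype(int)


def count_direction_shifts(dz: np.ndarray) -> int:
    """Number of ascent<->descent shifts under the zero-carry rule."""
    d = interval_directions(dz)
    d = d[d != 0]
    if len(d) < 2:
        return 0
    return int(np.sum(d[1:] != d[:-1]))


def run_decomposition(series: AltitudeSeries) -> pd.DataFrame:
    """Maximal monotone-direction runs of an altitude series.

    Each run spans consecutive intervals sharing the same carried
    direction. Columns: sample indices ``i_start``/``i_end``, ``direction``
    (+1/-1/0), ``displacement_m`` (signed, end minus start), ``duration_s``,
    ``rate_ms`` (|displacement|/duration) and ``active_rate_ms``, the rate
    over the run's first-to-last non-zero interval (so plateaus absorbed by
    the zero-carry rule do not dilute a leg's climb or descent rate).
    """
    if len(series) < 2:
        return pd.DataFrame(
            columns=[
                "i_start",
                "i_end",
                "direction",
                "displacement_m",
                "duration_s",
                "rate_ms",
                "active_rate_ms",
            ]
        )
    disp = vertical_displacement(series)
    dz = disp["dz_m"].to_numpy()
    dirs = interval_directions(dz)
    breaks = np.flatnonzero(dirs[1:] != dirs[:-1])
    run_starts = np.r_[0, breaks + 1]  # first interval index of each run
    run_ends = np.r_[breaks, len(dirs) - 1]  # last interval index
    t = series.timestamps
    z = series.altitude
    rows = []
    for a, b in zip(run_starts, run_ends):
        i0, i1 = int(a), int(b) + 1  # sample indices
        dur = (t[i1] - t[i0]).total_seconds()
        d = z[i1] - z[i0]
        nz = np.flatnonzero(dz[a : b + 1] != 0)
        if len(nz):
            j0, j1 = a + nz[0], a + nz[-1] + 1
            active_dur = (t[j1] - t[j0]).total_seconds()
        else:
            active_dur = dur
        rows.append(
            {
                "i_start": i0,
                "i_end": i1,
                "direction": int(dirs[a]),
                "displacement_m": float(d),
                "duration_s": float(dur),
                "rate_ms": abs(d) / dur if dur > 0 else 0.0,
                "active_rate_ms": abs(d) / active_dur if active_dur > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def classify_level_intervals(
    series: AltitudeSeries,
    level_threshold_m: float = 30.0,
    large_threshold_m: float = 300.0,
) -> pd.DataFrame:
    """Label every 5-min interval level / intermediate / large.

    Level means |dz| strictly below the 30-m threshold; large means |dz| at
    or above 300 m; the rest are intermediate. The three counts partition
    the intervals exactly.
    """
    disp = vertical_displacement(series)
    adz = disp["dz_m"].abs().to_numpy()
    labels = np.where(
        adz < level_threshold_m,
        "level",
        np.where(adz < large_threshold_m, "intermediate", "large"),
    )
    disp = disp.assign(label=labels)
    return disp


def level_fraction_summary(
    series: AltitudeSeries,
    level_threshold_m: float = 30.0,
    large_threshold_m: float = 300.0,
) -> dict:
    """Class counts and fractions of the displacement classes."""
    labelled = classify_level_intervals(series, level_threshold_m, large_threshold_m)
    n = len(labelled)
    counts = labelled["label"].value_counts()
    out = {
        "n_intervals": n,
        "n_level": int(counts.get("level", 0)),
        "n_intermediate": int(counts.get("intermediate", 0)),
        "n_large": int(counts.get("large", 0)),
    }
    out["level_fraction"] = out["n_level"] / n
    out["intermediate_fraction"] = out["n_intermediate"] / n
    out["large_fraction"] = out["n_large"] / n
    return out


def mean_vertical_speed(series: AltitudeSeries) -> float:
    """Mean of |dz|/dt over the series' intervals (m/s, unsigned)."""
    disp = vertical_displacement(series)
    return float(disp["rate_ms"].abs().mean())


def vertical_tortuosity(series: AltitudeSeries) -> float:
    """Direction shifts divided by (number of recordings - 1).

    0 for a monotone climb or descent (and for an all-level profile);
    bounded above by (N-2)/(N-1) < 1 for N recordings — the denominator is
    taken literally, without renormalising to the attainable maximum.
    """
    if len(series) < 2:
        raise ValueError("need at least two recordings")
    disp = vertical_displacement(series)
    shifts = count_direction_shifts(disp["dz_m"].to_numpy())
    return shifts / (len(series) - 1)


class TrimResult(NamedTuple):
    series: AltitudeSeries
    untrimmable: bool


def trim_cruise(series: AltitudeSeries) -> TrimResult:
    """Drop the initial and final maximal monotone runs of a flight.

    What remains is the presumed cruising phase. Profiles that are a single
    run (pure climbs/descents) or whose interior holds fewer than two
    samples are flagged untrimmable and return an empty series.
    """
    if len(series) < 4:
        return TrimResult(
            AltitudeSeries(series.timestamps[:0], series.altitude[:0], series.provenance),
            True,
        )
    runs = run_decomposition(series)
    if len(runs) < 2:
        return TrimResult(
            AltitudeSeries(series.timestamps[:0], series.altitude[:0], series.provenance),
            True,
        )
    i0 = int(runs.iloc[0]["i_end"])  # last sample of the first run
    i1 = int(runs.iloc[-1]["i_start"])  # first sample of the last run
    if i1 - i0 + 1 < 2:
        return TrimResult(
            AltitudeSeries(series.timestamps[:0], series.altitude[:0], series.provenance),
            True,
        )
    return TrimResult(
        AltitudeSeries(
            series.timestamps[i0 : i1 + 1],
            series.altitude[i0 : i1 + 1],
            series.provenance,
        ),
        False,
    )


@dataclass
class FlightAltitudeMetrics:
    """Per-episode altitude-variation summary (one variant)."""

    episode_id: str
    variant: str  # "full" or "cruise"
    level_fraction: float
    mean_vz: float
    tortuosity: float
    max_alt: float
    median_alt: float
    n_level: int
    n_intermediate: int
    n_large: int
    n_intervals: int
    untrimmable: bool = False
    region: str = "unknown"
    season: str = ""
    bird_id: str = ""


def compute_metrics(
    episode: FlightEpisode, config: PipelineConfig | None = None
) -> list[FlightAltitudeMetrics]:
    """Full-flight and cruise-phase metrics for one episode.

    Near-level classification runs on the raw altitude series; the
    displacement statistics (mean vertical speed, tortuosity) run on the
    three-point smoothed series. Both bases are configurable.
    """
    config = config or PipelineConfig()
    raw = episode.altitude
    if len(raw) < 3:
        return []
    smoothed = rolling_mean3(raw)
    level_series = raw if config.level_basis == "raw" else smoothed
    delta_series = smoothed if config.delta_basis == "smoothed" else raw

    def build(variant: str, lv: AltitudeSeries, dl: AltitudeSeries, untrimmable=False):
        summary = level_fraction_summary(
            lv, config.level_threshold_m, config.large_threshold_m
        )
        return FlightAltitudeMetrics(
            episode_id=episode.episode_id,
            variant=variant,
            level_fraction=summary["level_fraction"],
            mean_vz=mean_vertical_speed(dl),
            tortuosity=vertical_tortuosity(dl),
            max_alt=float(np.max(raw.altitude)),
            median_alt=float(np.median(raw.altitude)),
            n_level=summary["n_level"],
            n_intermediate=summary["n_intermediate"],
            n_large=summary["n_large"],
            n_intervals=summary["n_intervals"],
            untrimmable=untrimmable,
            region=episode.region,
            season=episode.season,
            bird_id=episode.bird_id,
        )

    out = [build("full", level_series, delta_series)]
    trimmed = trim_cruise(delta_series)
    if not trimmed.untrimmable and len(trimmed.series) >= 3:
        lv_trim = trim_cruise(level_series)
        lv = (
            lv_trim.series
            if not lv_trim.untrimmable and len(lv_trim.series) >= 2
            else trimmed.series
        )
        out.append(build("cruise", lv, trimmed.series))
    return out


def metrics_table(metrics: list[FlightAltitudeMetrics]) -> pd.DataFrame:
    """One row per episode x variant."""
    return pd.DataFrame([vars(m) for m in metrics])
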