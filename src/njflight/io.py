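"""Logger data model and flat-CSV interchange.

Multisensor biologgers used on nocturnal migrants store, per bird, a 5-min
activity score (an integer count of accelerometer sub-measurements that
registered movement, out of 10 for older loggers or 5 for newer ones), a
5-min barometric pressure reading (hPa), and an approximate daily latitude
from light-level geolocation. The on-disk format here is a single flat CSV
with one row per 5-min timestamp:

    bird_id, timestamp_utc, activity_score, activity_scale_max,
    pressure_hpa, latitude

Either sensor field may be empty on a given row (gaps are absent values,
never NaN rows fabricated by the reader), and latitude is carried on every
row of its date. Rows are sorted by bird then time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SAMPLE_INTERVAL_S = 300
VALID_SCALES = (5, 10)
PRESSURE_MIN_HPA = 300.0
PRESSURE_MAX_HPA = 1100.0


class ValidationError(ValueError):
    """Raised when logger data violate a structural invariant."""


@dataclass(frozen=True)
class ActivitySample:
    """One 5-min activity registration."""

    timestamp: pd.Timestamp
    score: int
    scale_max: int

    def __post_init__(self) -> None:
        if self.scale_max not in VALID_SCALES:
            raise ValidationError(f"scale_max must be in {VALID_SCALES}")
        if not 0 <= self.score <= self.scale_max:
            raise ValidationError(
                f"score {self.score} outside [0, {self.scale_max}]"
            )

    @property
    def duty(self) -> float:
        """Fraction of sub-measurements that registered activity."""
        return self.score / self.scale_max


@dataclass(frozen=True)
class PressureSample:
    """One 5-min barometric registration (hPa)."""

    timestamp: pd.Timestamp
    pressure: float

    def __post_init__(self) -> None:
        if not PRESSURE_MIN_HPA < self.pressure < PRESSURE_MAX_HPA:
            raise ValidationError(
                f"pressure {self.pressure} hPa outside "
                f"({PRESSURE_MIN_HPA}, {PRESSURE_MAX_HPA})"
            )


@dataclass
class LoggerDataset:
    """Per-bird logger streams.

    ``activity`` has columns (timestamp, score, scale_max); ``pressure`` has
    (timestamp, pressure_hpa); ``daily_latitude`` maps dates to degrees
    north. Timestamps are tz-aware UTC on a 5-min grid; gaps are simply
    missing rows.
    """

    bird_id: str
    activity: pd.DataFrame
    pressure: pd.DataFrame
    daily_latitude: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activity = _normalise_frame(
            self.activity, ["timestamp", "score", "scale_max"]
        )
        self.pressure = _normalise_frame(
            self.pressure, ["timestamp", "pressure_hpa"]
        )
        self.daily_latitude = {
            _as_date(k): float(v) for k, v in self.daily_latitude.items()
        }
        self.validate()

    def validate(self) -> None:
        for name, frame in (("activity", self.activity), ("pressure", self.pressure)):
            ts = frame["timestamp"]
            if ts.isna().any():
                raise ValidationError(f"{name}: missing timestamps")
            if not ts.is_monotonic_increasing or ts.duplicated().any():
                bad = int(np.flatnonzero(ts.diff().dt.total_seconds().fillna(1) <= 0)[0])
                raise ValidationError(
                    f"{name}: timestamps not strictly increasing at row {bad}"
                )
            off_grid = (ts.dt.second != 0) | (ts.dt.minute % 5 != 0)
            if off_grid.any():
                raise ValidationError(
                    f"{name}: timestamp off the 5-min grid at row "
                    f"{int(np.flatnonzero(off_grid)[0])}"
                )
        if len(self.activity):
            scales = self.activity["scale_max"]
            if not scales.isin(VALID_SCALES).all():
                raise ValidationError("activity: scale_max must be 5 or 10")
            bad = (self.activity["score"] < 0) | (self.activity["score"] > scales)
            if bad.any():
                raise ValidationError(
                    f"activity: score outside [0, scale_max] at row "
                    f"{int(np.flatnonzero(bad)[0])}"
                )
        if len(self.pressure):
            p = self.pressure["pressure_hpa"]
            bad = ~((p > PRESSURE_MIN_HPA) & (p < PRESSURE_MAX_HPA))
            if bad.any():
                raise ValidationError(
                    f"pressure: value outside ({PRESSURE_MIN_HPA}, "
                    f"{PRESSURE_MAX_HPA}) hPa at row {int(np.flatnonzero(bad)[0])}"
                )
        for lat in self.daily_latitude.values():
            if not -90.0 <= lat <= 90.0:
                raise ValidationError(f"latitude {lat} outside [-90, 90]")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LoggerDataset):
            return NotImplemented
        return (
            self.bird_id == other.bird_id
            and self.activity.equals(other.activity)
            and np.allclose(
                self.pressure["pressure_hpa"], other.pressure["pressure_hpa"]
            )
            and self.pressure["timestamp"].equals(other.pressure["timestamp"])
            and self.daily_latitude.keys() == other.daily_latitude.keys()
            and all(
                abs(self.daily_latitude[k] - other.daily_latitude[k]) < 1e-9
                for k in self.daily_latitude
            )
        )

    def latitude_at(self, when: pd.Timestamp) -> float | None:
        """Latitude of the date nearest in time to ``when``, if any."""
        if not self.daily_latitude:
            return None
        target = when.date()
        best = min(
            self.daily_latitude, key=lambda d: abs((d - target).days)
        )
        return self.daily_latitude[best]


def _as_date(value):
    import datetime as _dt

    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return pd.Timestamp(value).date()


def _normalise_frame(frame: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    if frame is None or len(frame) == 0:
        frame = pd.DataFrame({c: [] for c in columns})
    frame = frame.loc[:, columns].reset_index(drop=True)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"], utc=True)
    for c in columns:
        if c in ("score", "scale_max"):
            frame[c] = frame[c].astype(np.int64)
        elif c != "timestamp":
            frame[c] = frame[c].astype(float)
    return frame


CSV_COLUMNS = [
    "bird_id",
    "timestamp_utc",
    "activity_score",
    "activity_scale_max",
    "pressure_hpa",
    "latitude",
]


def write_logger_csv(
    datasets: LoggerDataset | Iterable[LoggerDataset], path: str | Path
) -> None:
    """Write one or more bird datasets to a flat CSV, sorted by bird then time.

    Missing values (sensor gaps, unknown latitude) are written as empty
    fields. Timestamps are ISO-8601 UTC.
    """
    if isinstance(datasets, LoggerDataset):
        datasets = [datasets]
    rows = []
    for ds in datasets:
        act = ds.activity.set_index("timestamp")
        pres = ds.pressure.set_index("timestamp")
        merged = act.join(pres, how="outer")
        merged = merged.sort_index()
        for ts, row in merged.iterrows():
            lat = ds.daily_latitude.get(ts.date())
            has_act = not pd.isna(row.get("score"))
            rows.append(
                {
                    "bird_id": ds.bird_id,
                    "timestamp_utc": ts.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "activity_score": int(row["score"]) if has_act else "",
                    "activity_scale_max": int(row["scale_max"]) if has_act else "",
                    "pressure_hpa": (
                        repr(float(row["pressure_hpa"]))
                        if not pd.isna(row.get("pressure_hpa"))
                        else ""
                    ),
                    "latitude": repr(float(lat)) if lat is not None else "",
                }
            )
    out = pd.DataFrame(rows, columns=CSV_COLUMNS)
    out = out.sort_values(["bird_id", "timestamp_utc"], kind="stable")
    out.to_csv(path, index=False)


def read_logger_csv(path: str | Path) -> list[LoggerDataset]:
    """Read a flat logger CSV into validated per-bird datasets.

    Raises :class:`ValidationError` naming the first offending data row
    (1-based, counting the header as row 1) when any row violates a type
    invariant or timestamps are non-monotone within a bird and stream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != CSV_COLUMNS:
        raise ValidationError(
            f"malformed header: expected {CSV_COLUMNS}, got {list(raw.columns)}"
        )
    if len(raw) == 0:
        return []
    rownum = raw.index.to_numpy() + 2  # 1-based file rows, after the header

    def fail(mask: np.ndarray, message: str) -> None:
        if mask.any():
            raise ValidationError(
                f"row {int(rownum[np.flatnonzero(mask)[0]])}: {message}"
            )

    ts = pd.to_datetime(raw["timestamp_utc"], errors="coerce", utc=True)
    fail(ts.isna().to_numpy(), "unparseable timestamp_utc")

    has_act = (raw["activity_score"].str.strip() != "").to_numpy()
    has_scale = (raw["activity_scale_max"].str.strip() != "").to_numpy()
    fail(has_act != has_scale, "activity_score and activity_scale_max must co-occur")
    score = pd.to_numeric(raw["activity_score"], errors="coerce")
    scale = pd.to_numeric(raw["activity_scale_max"], errors="coerce")
    fail(has_act & score.isna().to_numpy(), "non-numeric activity_score")
    fail(has_act & ~scale.isin(VALID_SCALES).to_numpy(), "activity_scale_max must be 5 or 10")
    fail(
        (has_act & ((score < 0) | (score > scale))).to_numpy(),
        "activity_score outside [0, activity_scale_max]",
    )

    has_p = (raw["pressure_hpa"].str.strip() != "").to_numpy()
    pres = pd.to_numeric(raw["pressure_hpa"], errors="coerce")
    fail(has_p & pres.isna().to_numpy(), "non-numeric pressure_hpa")
    fail(
        (has_p & ~((pres > PRESSURE_MIN_HPA) & (pres < PRESSURE_MAX_HPA))).to_numpy(),
        f"pressure_hpa outside ({PRESSURE_MIN_HPA}, {PRESSURE_MAX_HPA})",
    )

    has_lat = (raw["latitude"].str.strip() != "").to_numpy()
    lat = pd.to_numeric(raw["latitude"], errors="coerce")
    fail(has_lat & lat.isna().to_numpy(), "non-numeric latitude")
    fail((has_lat & (lat.abs() > 90)).to_numpy(), "latitude outside [-90, 90]")

    datasets: list[LoggerDataset] = []
    frame = pd.DataFrame(
        {
            "bird_id": raw["bird_id"],
            "timestamp": ts,
            "score": score,
            "scale_max": scale,
            "pressure_hpa": pres,
            "latitude": lat,
            "_row": rownum,
        }
    )
    for bird_id, grp in frame.groupby("bird_id", sort=True):
        dt = grp["timestamp"].diff().dt.total_seconds()
        nonmono = (dt <= 0).to_numpy()
        if nonmono.any():
            bad_row = int(grp["_row"].to_numpy()[np.flatnonzero(nonmono)[0]])
            raise ValidationError(
                f"row {bad_row}: non-monotone timestamps for bird {bird_id}"
            )
        act = grp.loc[grp["score"].notna(), ["timestamp", "score", "scale_max"]]
        pr = grp.loc[grp["pressure_hpa"].notna(), ["timestamp", "pressure_hpa"]]
        lat_rows = grp.loc[grp["latitude"].notna()]
        daily = {}
        for _, r in lat_rows.iterrows():
            daily.setdefault(r["timestamp"].date(), float(r["latitude"]))
        datasets.append(
            LoggerDataset(
                bird_id=str(bird_id),
                activity=act,
                pressure=pr,
                daily_latitude=daily,
            )
        )
    return datasets
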