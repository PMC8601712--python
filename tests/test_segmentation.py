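"""Core-hour rules, episode extraction, region and season labels."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from njflight.config import PipelineConfig
from njflight.io import LoggerDataset
from njflight.segmentation import (
    assign_region,
    assign_season,
    episodes_table,
    extract_flight_episodes,
    find_core_hours,
    is_flight_level,
)
from njflight.synthetic import generate_dataset, migration_scenario

from conftest import T0, activity_frame, grid


class TestFlightLevel:
    @pytest.mark.parametrize(
        "score,scale,expected",
        [
            (6, 10, True),  # "category 6 or above" on the 11-grade scale
            (5, 10, False),
            (10, 10, True),
            (3, 5, True),  # same 0.6 duty threshold on the 6-grade scale
            (2, 5, False),
            (0, 10, False),
        ],
    )
    def test_duty_threshold(self, score, scale, expected):
        assert is_flight_level(score, scale) is expected

    def test_vectorised(self):
        out = is_flight_level(np.array([6, 5]), np.array([10, 10]))
        assert out.tolist() == [True, False]


def hour_of_scores(n_level, start, scale=10):
    """One clock-hour of activity: n_level flight-level samples then rest."""
    level_score = 6 if scale == 10 else 3
    scores = [level_score] * n_level + [0] * (12 - n_level)
    return activity_frame(scores, scale, start)


class TestCoreHours:
    @pytest.mark.parametrize("n_level,is_core", [(8, True), (7, True), (6, False)])
    def test_seven_of_twelve_rule(self, n_level, is_core):
        act = hour_of_scores(n_level, T0)
        core = find_core_hours(act)
        assert (len(core) == 1) is is_core

    def test_all_rest_has_no_core_hours(self):
        act = activity_frame([0] * 36)
        assert len(find_core_hours(act)) == 0


class TestEpisodeExtraction:
    def make_dataset(self, hours_levels, scale=10, lat=None):
        """hours_levels: per consecutive clock-hour, # flight-level samples."""
        frames = []
        for k, n_level in enumerate(hours_levels):
            frames.append(
                hour_of_scores(n_level, T0 + pd.Timedelta(hours=k), scale)
            )
        activity = pd.concat(frames, ignore_index=True)
        lat_map = {}
        if lat is not None:
            for d in {t.date() for t in activity["timestamp"]}:
                lat_map[d] = lat
        return LoggerDataset("b1", activity, pd.DataFrame(), lat_map)

    def test_pre_post_extension_arithmetic(self):
        # 4 core hours, 3 qualifying pre-core and 2 post-core samples:
        # 4 h core + 5 x 5 min = 4 h 25 min, migratory
        ds = self.make_dataset([3, 12, 12, 12, 12, 2, 0])
        eps = extract_flight_episodes(ds)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.n_pre == 3 and ep.n_post == 2
        assert ep.duration_s == 4 * 3600 + 5 * 300
        assert ep.flight_class == "migratory"
        assert len(ep.core_hours) == 4

    def test_two_core_hours_without_neighbours_is_short(self):
        ds = self.make_dataset([0, 12, 12, 0])
        eps = extract_flight_episodes(ds)
        assert len(eps) == 1
        assert eps[0].duration_s == 2 * 3600
        assert eps[0].flight_class == "short"

    def test_no_core_hours_no_episodes(self):
        ds = self.make_dataset([3, 4, 5])
        assert extract_flight_episodes(ds) == []

    def test_separate_core_runs_make_separate_episodes(self):
        ds = self.make_dataset([12, 12, 0, 12, 12, 12, 0])
        eps = extract_flight_episodes(ds)
        assert len(eps) == 2
        assert eps[0].end <= eps[1].start  # never overlapping

    def test_six_grade_scale_uses_same_duty(self):
        ds = self.make_dataset([0, 12, 12, 12, 12, 0], scale=5)
        eps = extract_flight_episodes(ds)
        assert len(eps) == 1

    def test_episode_table_columns(self):
        ds = self.make_dataset([0, 12, 12, 12, 12, 0], lat=20.0)
        tab = episodes_table(extract_flight_episodes(ds))
        assert tab.loc[0, "region"] == "Sahara"
        assert tab.loc[0, "class"] == "migratory"


class TestRegion:
    @pytest.mark.parametrize(
        "lat,region",
        [
            (45.0, "Europe"),
            (38.5, "Europe"),
            (38.0, "Sahara"),
            (20.0, "Sahara"),
            (8.0, "Sahara"),
            (5.0, "subSaharan"),
            (-15.0, "subSaharan"),
        ],
    )
    def test_latitude_bands(self, lat, region):
        assert assign_region(lat) == region

    def test_missing_latitude_unknown(self):
        assert assign_region(None) == "unknown"
        assert assign_region(float("nan")) == "unknown"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_region(100.0)


class TestSeason:
    def test_calendar_rule(self):
        assert assign_season(pd.Timestamp("2019-04-14T02:00:00Z")) == "spring"
        assert assign_season(pd.Timestamp("2018-08-01T22:00:00Z")) == "autumn"
        assert assign_season(pd.Timestamp("2018-10-15T22:00:00Z")) == "autumn"

    def test_direction_rule_southbound_is_autumn(self):
        when = pd.Timestamp("2018-10-15T22:00:00Z")
        lats = {
            dt.date(2018, 10, 13): 40.0,
            dt.date(2018, 10, 17): 35.0,
        }
        assert assign_season(when, lats, rule="direction") == "autumn"
        lats_north = {
            dt.date(2018, 10, 13): 35.0,
            dt.date(2018, 10, 17): 40.0,
        }
        assert assign_season(when, lats_north, rule="direction") == "spring"

    def test_direction_rule_falls_back_to_calendar(self):
        when = pd.Timestamp("2018-08-01T22:00:00Z")
        assert assign_season(when, {}, rule="direction") == "autumn"


class TestPlantedFlightRecovery:
    def _match(self, episodes, truth_night):
        for ep in episodes:
            start = max(ep.start, truth_night.start)
            end = min(ep.end, truth_night.end)
            overlap = max((end - start).total_seconds(), 0.0)
            if overlap > 0.5 * truth_night.duration_s:
                return ep
        return None

    def test_noise_free_recall_and_precision_are_one(self):
        spec = migration_scenario(
            n_birds=3, nights_per_bird=4, rng_seed=5, pressure_noise_sd_hpa=0.0
        )
        datasets, truth = generate_dataset(spec)
        episodes = []
        for ds in datasets:
            episodes.extend(extract_flight_episodes(ds))
        assert len(episodes) == len(truth.nights)
        for night in truth.nights:
            assert self._match(episodes, night) is not None

    def test_recall_under_activity_dropout(self):
        spec = migration_scenario(
            n_birds=4, nights_per_bird=4, rng_seed=6, activity_dropout=0.10
        )
        datasets, truth = generate_dataset(spec)
        episodes = []
        for ds in datasets:
            episodes.extend(extract_flight_episodes(ds))
        hits = sum(
            1 for night in truth.nights if self._match(episodes, night) is not None
        )
        assert hits / len(truth.nights) >= 0.9
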