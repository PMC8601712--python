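"""Near-level classification, vertical speed, tortuosity, cruise trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from njflight.dynamics import (
    classify_level_intervals,
    compute_metrics,
    count_direction_shifts,
    interval_directions,
    level_fraction_summary,
    mean_vertical_speed,
    run_decomposition,
    trim_cruise,
    vertical_tortuosity,
)

from conftest import episode, series


def brute_force_shifts(z):
    """Independent shift counter: drop flat intervals, count sign changes."""
    signs = [np.sign(d) for d in np.diff(z) if d != 0]
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


altitude_lists = st.lists(
    st.integers(min_value=0, max_value=50).map(lambda k: 10.0 * k),
    min_size=3,
    max_size=60,
)


class TestLevelClassification:
    @pytest.mark.parametrize(
        "dz,label",
        [
            (29.0, "level"),  # strictly below the 30-m threshold
            (-29.9, "level"),
            (30.0, "intermediate"),
            (-150.0, "intermediate"),
            (299.9, "intermediate"),
            (300.0, "large"),  # >=300 m per 5 min, i.e. >=1 m/s
            (-600.0, "large"),
        ],
    )
    def test_thresholds(self, dz, label):
        labelled = classify_level_intervals(series([1000.0, 1000.0 + dz]))
        assert labelled["label"].iloc[0] == label

    def test_constant_altitude_is_all_level(self):
        out = level_fraction_summary(series([800.0] * 10))
        assert out["level_fraction"] == 1.0

    @given(z=altitude_lists)
    @settings(max_examples=100, deadline=None)
    def test_fractions_partition_exactly(self, z):
        out = level_fraction_summary(series(z))
        assert out["n_level"] + out["n_intermediate"] + out["n_large"] == out[
            "n_intervals"
        ]
        assert (
            out["level_fraction"]
            + out["intermediate_fraction"]
            + out["large_fraction"]
            == pytest.approx(1.0)
        )


class TestMeanVerticalSpeed:
    def test_constant_is_zero(self):
        assert mean_vertical_speed(series([500.0] * 6)) == 0.0

    def test_alternating_150m_is_half_metre_per_second(self):
        z = [1000.0, 1150.0, 1000.0, 1150.0, 1000.0]
        assert mean_vertical_speed(series(z)) == pytest.approx(0.5)

    def test_even_climb_1800m_in_one_hour(self):
        z = np.linspace(0.0, 1800.0, 13)  # 12 intervals of 150 m
        assert mean_vertical_speed(series(z)) == pytest.approx(0.5)


class TestTortuosity:
    def test_monotone_ascent_is_zero(self):
        assert vertical_tortuosity(series([0.0, 100.0, 250.0, 400.0])) == 0.0

    def test_worked_example(self):
        # 3 shifts over 4 possible
        assert vertical_tortuosity(series([0, 100, 50, 150, 100])) == 0.75

    def test_maximal_zigzag_approaches_one(self):
        n = 41
        z = [1000.0 + 50.0 * (i % 2) for i in range(n)]
        assert vertical_tortuosity(series(z)) == (n - 2) / (n - 1)

    def test_staircase_counts_no_shifts(self):
        # plateaus carry the previous direction: a staircase stays monotone
        z = [0.0, 100.0, 100.0, 200.0, 200.0, 300.0]
        assert vertical_tortuosity(series(z)) == 0.0

    def test_all_level_is_zero(self):
        assert vertical_tortuosity(series([100.0] * 8)) == 0.0

    @given(z=altitude_lists)
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, z):
        shifts = count_direction_shifts(np.diff(z))
        assert shifts == brute_force_shifts(z)
        assert vertical_tortuosity(series(z)) == shifts / (len(z) - 1)


class TestDirections:
    def test_zero_carry_forward_and_backfill(self):
        dz = np.array([0.0, 0.0, 5.0, 0.0, -3.0, 0.0])
        assert interval_directions(dz).tolist() == [1, 1, 1, 1, -1, -1]

    def test_all_zero_stays_zero(self):
        assert interval_directions(np.zeros(4)).tolist() == [0, 0, 0, 0]


class TestTrimCruise:
    def test_climb_plateau_descent_keeps_plateau(self):
        z = [0.0, 100, 200, 300, 310, 290, 310, 290, 200, 100, 0.0]
        trimmed = trim_cruise(series(z))
        assert not trimmed.untrimmable
        assert trimmed.series.altitude.tolist() == [310, 290, 310]

    def test_pure_monotone_climb_untrimmable(self):
        trimmed = trim_cruise(series([0.0, 100, 200, 300, 400]))
        assert trimmed.untrimmable
        assert len(trimmed.series) == 0

    def test_single_interval_first_ascent(self):
        z = [0.0, 100, 50, 150, 100, 200, 100, 0.0]
        trimmed = trim_cruise(series(z))
        assert trimmed.series.altitude.tolist() == [100, 50, 150, 100, 200]

    def test_short_series_untrimmable(self):
        assert trim_cruise(series([0.0, 10.0, 0.0])).untrimmable


class TestEpisodeMetrics:
    def test_cruise_variant_on_trimmed_profile(self):
        # climb, wiggly cruise, descent: cruise-phase tortuosity exceeds
        # the full-flight value because monotone edge runs are removed
        z = (
            list(np.linspace(0, 1000, 11))
            + [1000 + 60 * ((-1) ** i) for i in range(20)]
            + list(np.linspace(1000, 0, 11))
        )
        ep = episode(z)
        full, cruise = compute_metrics(ep)
        assert full.variant == "full" and cruise.variant == "cruise"
        assert cruise.tortuosity >= full.tortuosity
        assert full.mean_vz > 0
        assert 0 <= full.level_fraction <= 1

    def test_metrics_partition_invariant(self):
        z = list(np.linspace(0, 600, 7)) + [600, 640, 600, 640] + list(
            np.linspace(600, 0, 7)
        )
        ep = episode(z)
        for m in compute_metrics(ep):
            assert m.n_level + m.n_intermediate + m.n_large == m.n_intervals


class TestLevelFractionRecovery:
    @pytest.mark.parametrize("target", [0.3, 0.6, 0.9])
    def test_recovered_within_five_points(self, target):
        import datetime as dt

        from njflight.segmentation import extract_flight_episodes
        from njflight.synthetic import (
            BirdPlan,
            ScenarioSpec,
            generate_dataset,
            level_fraction_night,
        )

        night = level_fraction_night(dt.date(2018, 9, 12), target)
        spec = ScenarioSpec(
            birds=[BirdPlan("b0", 10, [night])],
            pressure_noise_sd_hpa=0.5,
            rng_seed=11,
        )
        datasets, truth = generate_dataset(spec)
        eps = extract_flight_episodes(datasets[0])
        assert len(eps) == 1
        full = compute_metrics(eps[0])[0]
        assert full.level_fraction == pytest.approx(
            truth.nights[0].level_fraction, abs=0.05
        )
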