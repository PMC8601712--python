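"""Exploratory-event detectors, ascent maxima, descent extraction."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from njflight.config import PipelineConfig
from njflight.events import (
    detect_midflight_exploratory,
    detect_terminated_exploratory,
    find_descent_segments,
    max_ascent_rate,
)
from njflight.segmentation import extract_flight_episodes

from conftest import episode, series


def climb_profile(*legs, start_alt=0.0):
    """Build altitudes from (n_intervals, step_m) legs."""
    z = [start_alt]
    for n, step in legs:
        for _ in range(n):
            z.append(z[-1] + step)
    return z


class TestTerminatedExploratory:
    def test_textbook_event_detected(self):
        # 80-min short flight: +600 m over 40 min, -600 m over 30 min
        z = climb_profile((8, 75.0), (6, -100.0))
        ev = detect_terminated_exploratory([episode(z)])
        assert len(ev) == 1
        e = ev[0]
        assert e.kind == "terminated"
        assert not e.descent_first
        assert e.leg1.direction == 1 and e.leg2.direction == -1
        assert e.leg1.displacement_m >= 500.0

    def test_small_excursion_rejected(self):
        z = climb_profile((8, 50.0), (8, -50.0))  # only 400 m each way
        assert detect_terminated_exploratory([episode(z)]) == []

    def test_level_short_flight_rejected(self):
        assert detect_terminated_exploratory([episode([500.0] * 16)]) == []

    def test_slow_drift_fails_rate_criterion(self):
        # 510 m up and down over 10 h: mean rate ~0.028 m/s < 0.1
        z = climb_profile((60, 8.5), (60, -8.5))
        eps = episode(z)
        eps.end = eps.start + pd.Timedelta(hours=3)  # force short class
        assert detect_terminated_exploratory([eps]) == []

    def test_migratory_flights_not_scanned(self):
        z = climb_profile((8, 75.0), (6, -100.0))
        ep = episode(z)
        ep.end = ep.start + pd.Timedelta(hours=4)
        assert detect_terminated_exploratory([ep]) == []


def migratory_episode(z):
    ep = episode(z)
    ep.end = ep.start + pd.Timedelta(seconds=300 * (len(z) - 1))
    assert ep.duration_s > 10800, "fixture must be migratory"
    return ep


class TestMidflightExploratory:
    def base_flight(self, mid_legs):
        """Climb to 2000, cruise, mid legs, cruise, descend."""
        wiggle = [(1, 40.0), (1, -40.0)] * 6
        return climb_profile(
            (10, 200.0), *wiggle, *mid_legs, *wiggle, (10, -200.0)
        )

    def test_descent_first_event(self):
        z = self.base_flight([(7, -100.0), (8, 100.0)])
        ev = detect_midflight_exploratory([migratory_episode(z)])
        assert len(ev) == 1
        assert ev[0].kind == "midflight"
        assert ev[0].descent_first

    def test_ascent_first_event(self):
        z = self.base_flight([(8, 100.0), (7, -100.0)])
        ev = detect_midflight_exploratory([migratory_episode(z)])
        assert len(ev) == 1
        assert not ev[0].descent_first

    def test_edge_runs_never_form_events(self):
        # monotone climb then descent only: the edges are ordinary
        z = climb_profile((24, 100.0), (24, -100.0))
        assert detect_midflight_exploratory([migratory_episode(z)]) == []

    def test_sub_threshold_excursion_ignored(self):
        z = self.base_flight([(4, -100.0), (4, 100.0)])  # 400 m legs
        assert detect_midflight_exploratory([migratory_episode(z)]) == []

    def test_event_legs_all_exceed_minimum(self):
        z = self.base_flight([(7, -100.0), (8, 100.0)])
        for ev in detect_midflight_exploratory([migratory_episode(z)]):
            assert abs(ev.leg1.displacement_m) >= 500.0
            assert abs(ev.leg2.displacement_m) >= 500.0


class TestMaxAscentRate:
    def test_five_minute_window(self):
        out = max_ascent_rate(series([0.0, 200.0, 500.0, 600.0]), 300)
        assert out.max_rate_ms == pytest.approx(1.0)  # 300 m in 5 min

    def test_twenty_minute_window(self):
        out = max_ascent_rate(series([0.0, 200.0, 500.0, 600.0, 600.0]), 1200)
        assert out.max_rate_ms == pytest.approx(0.5)  # 600 m in 20 min

    def test_constant_series(self):
        out = max_ascent_rate(series([100.0] * 6), 300)
        assert out.max_rate_ms == 0.0
        assert not out.passes_filter

    def test_short_series_flagged_undefined(self):
        out = max_ascent_rate(series([0.0, 100.0]), 1200)
        assert not out.defined
        assert np.isnan(out.max_rate_ms)

    def test_total_climb_filter(self):
        # climbs 400 m total; 5-min window needs > 1.16*300 = 348 m
        up = series(climb_profile((4, 100.0)))
        assert max_ascent_rate(up, 300).passes_filter
        assert not max_ascent_rate(up, 1200).passes_filter  # needs >1392 m

    @given(
        z=st.lists(
            st.floats(min_value=0.0, max_value=3000.0), min_size=2, max_size=40
        ),
        k=st.integers(min_value=1, max_value=6),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force(self, z, k):
        window = 300 * k
        out = max_ascent_rate(series(z), window)
        if len(z) < k + 1:
            assert not out.defined
            return
        brute = max((z[i + k] - z[i]) / window for i in range(len(z) - k))
        assert out.max_rate_ms == pytest.approx(brute)


class TestDescents:
    def descent_episode(self, n_down, step, duty_cruise=0.9, duty_down=0.9):
        z = [2000.0] * 4 + climb_profile((n_down, -step), start_alt=2000.0)[1:]
        duties = [duty_cruise] * 4 + [duty_down] * n_down
        return episode(z, duties)

    def test_active_descent_rate_from_trimmed_endpoints(self):
        # 20-min descent of 400 m at duty 0.9
        ep = self.descent_episode(4, 100.0)
        segs = find_descent_segments(ep.altitude, ep.activity, episode_id="e")
        assert len(segs) == 1
        seg = segs[0]
        assert seg.mode == "active"
        assert seg.rate_ms < 0
        assert seg.duration_s >= 600

    def test_low_duty_descent_is_glide(self):
        ep = self.descent_episode(5, 80.0, duty_down=0.1)
        segs = find_descent_segments(ep.altitude, ep.activity)
        assert len(segs) == 1
        assert segs[0].mode == "glide"

    def test_sub_ten_minute_descent_rejected(self):
        # a 2-interval (10-min span) descent leaves no interior pair after
        # endpoint exclusion, so no rate is computable and it is dropped
        z = [1800.0, 1900.0, 2000.0, 1900.0, 1800.0, 1900.0, 2000.0]
        ep = episode(z)
        assert find_descent_segments(ep.altitude, ep.activity) == []

    def test_descent_without_preceding_flight_ignored(self):
        ep = self.descent_episode(4, 100.0, duty_cruise=0.1, duty_down=0.1)
        assert find_descent_segments(ep.altitude, ep.activity) == []

    def test_all_rates_negative_invariant(self):
        rng = np.random.default_rng(3)
        z = np.cumsum(rng.normal(0, 120, 80)) + 2000.0
        z = np.maximum(z, 0.0)
        ep = episode(list(z))
        for seg in find_descent_segments(ep.altitude, ep.activity):
            assert seg.rate_ms < 0
            assert seg.duration_s >= 600

    def test_glide_sink_rate_recovered_from_polar_profile(self):
        from njflight.mechanics import GlidePolar
        from njflight.synthetic import (
            BirdPlan,
            ScenarioSpec,
            generate_dataset,
            glide_descent_night,
        )

        polar = GlidePolar()
        night = glide_descent_night(
            dt.date(2018, 9, 12),
            cruise_alt_m=3000.0,
            duration_h=6.0,
            sink_rate_ms=-polar.sink_rate,
        )
        spec = ScenarioSpec(
            birds=[BirdPlan("b0", 10, [night])],
            pressure_noise_sd_hpa=0.0,
            rng_seed=4,
        )
        datasets, truth = generate_dataset(spec)
        ds = datasets[0]
        from njflight.altimetry import altitude_series_from_pressure

        full = altitude_series_from_pressure(
            ds.pressure["timestamp"], ds.pressure["pressure_hpa"]
        )
        segs = find_descent_segments(full, ds.activity)
        glides = [s for s in segs if s.mode == "glide"]
        assert len(glides) == 1
        # within the discretisation error of the 5-min grid
        assert glides[0].rate_ms == pytest.approx(polar.sink_rate, abs=0.1)
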