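"""Journey simulation: departure, energetics, gauging, stopovers, fates."""

import numpy as np
import pytest
from scipy import stats

from magmigrate.flight import CompassMode
from magmigrate.geomag import FieldSample
from magmigrate.migration import (
    CAPACITY_MAX_H,
    CAPACITY_MIN_H,
    DEPARTURE_EARLIEST_DOY,
    DEPARTURE_LATEST_DOY,
    DEPARTURE_MEAN_DOY,
    Genome,
    Individual,
    OVERWATER_MORTALITY,
    POLEWARD_EXIT,
    Precisions,
    STATUS_LABELS,
    draw_departure_date,
    draw_flight_capacity,
    gauge_signpost,
    simulate_cohort,
    simulate_journey,
    stopover_policy,
)
from magmigrate.world import sample_natal_locations

ZERO_NOISE = Precisions(flight_sigma_deg=0.0, inclination_sigma_deg=0.0,
                        intensity_rel_sd=0.0, declination_sigma_deg=0.0)


class TestDepartureDate:
    def test_zero_sd_collapses_to_mean(self, rng):
        assert draw_departure_date(rng, sd_days=0.0) == DEPARTURE_MEAN_DOY

    def test_truncation_window_and_mean(self, rng):
        draws = np.array([draw_departure_date(rng) for _ in range(2000)])
        assert draws.min() >= DEPARTURE_EARLIEST_DOY
        assert draws.max() <= DEPARTURE_LATEST_DOY
        a = (DEPARTURE_EARLIEST_DOY - DEPARTURE_MEAN_DOY) / 5.0
        b = (DEPARTURE_LATEST_DOY - DEPARTURE_MEAN_DOY) / 5.0
        oracle_mean = stats.truncnorm.mean(a, b, loc=DEPARTURE_MEAN_DOY, scale=5.0)
        assert draws.mean() == pytest.approx(oracle_mean, abs=0.3)

    def test_large_sample_mean_against_truncated_normal_oracle(self):
        rng = np.random.default_rng(99)
        a = (DEPARTURE_EARLIEST_DOY - DEPARTURE_MEAN_DOY) / 5.0
        b = (DEPARTURE_LATEST_DOY - DEPARTURE_MEAN_DOY) / 5.0
        draws = stats.truncnorm.rvs(a, b, loc=DEPARTURE_MEAN_DOY, scale=5.0,
                                    size=100_000, random_state=rng)
        oracle_mean = stats.truncnorm.mean(a, b, loc=DEPARTURE_MEAN_DOY, scale=5.0)
        assert draws.mean() == pytest.approx(oracle_mean, abs=0.1)
        assert draws.min() >= DEPARTURE_EARLIEST_DOY and draws.max() <= DEPARTURE_LATEST_DOY


class TestFlightCapacity:
    def test_uniform_window_and_mean(self):
        rng = np.random.default_rng(7)
        draws = np.array([draw_flight_capacity(rng) for _ in range(100_000)])
        assert draws.min() >= CAPACITY_MIN_H and draws.max() <= CAPACITY_MAX_H
        assert draws.mean() == pytest.approx(60.0, abs=0.1)

    def test_floor_above_window_wins(self, rng):
        assert draw_flight_capacity(rng, floor=80.0) == 80.0

    def test_floor_at_window_edge(self, rng):
        for _ in range(100):
            assert CAPACITY_MIN_H <= draw_flight_capacity(rng, floor=48.0) <= CAPACITY_MAX_H

    def test_negative_floor_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_flight_capacity(rng, floor=-1.0)


class TestGaugeSignpost:
    def test_exact_perception_above_threshold_no_switch(self, rng):
        g = Genome(theta1=150.0, signpost_type="inclination", signpost_value=60.0)
        field = FieldSample(0.0, 70.0, 50_000.0)
        assert not gauge_signpost(g, field, rng, ZERO_NOISE)

    def test_exact_perception_below_threshold_switches(self, rng):
        g = Genome(theta1=150.0, signpost_type="intensity", signpost_value=45_000.0)
        field = FieldSample(0.0, 60.0, 40_000.0)
        assert gauge_signpost(g, field, rng, ZERO_NOISE)

    def test_magnitude_comparison_in_southern_hemisphere(self, rng):
        # inclination -70 deg has magnitude 70 > threshold 60: no switch
        g = Genome(theta1=150.0, signpost_type="inclination", signpost_value=60.0)
        field = FieldSample(0.0, -70.0, 50_000.0)
        assert not gauge_signpost(g, field, rng, ZERO_NOISE)

    def test_none_type_is_noop(self, rng):
        g = Genome(theta1=150.0, signpost_type="none")
        assert not gauge_signpost(g, FieldSample(0.0, 10.0, 31_000.0), rng)

    def test_switch_frequency_half_at_threshold(self):
        # symmetric gauging noise at the exact threshold flips a fair coin
        rng = np.random.default_rng(21)
        g = Genome(theta1=150.0, signpost_type="inclination", signpost_value=60.0)
        field = FieldSample(0.0, 60.0, 50_000.0)
        hits = sum(gauge_signpost(g, field, rng) for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)


class TestStopoverPolicy:
    def make(self, capacity, sea=False, switched=False):
        return Individual(natal_lat=60.0, natal_lon=0.0, genome=Genome(theta1=180.0),
                          lat=50.0, lon=10.0, date_doy=250.0, flight_capacity_h=capacity,
                          last_flight_began_at_sea=sea, switched_at_landing=switched)

    def test_low_capacity_triggers_five_day_stopover(self, uniform_world):
        assert stopover_policy(self.make(20.0), uniform_world) == ("stopover", 5)

    def test_ample_capacity_continues(self, uniform_world):
        assert stopover_policy(self.make(40.0), uniform_world) == ("continue", None)

    def test_sea_begun_flight_forces_stopover(self, uniform_world):
        assert stopover_policy(self.make(40.0, sea=True), uniform_world) == ("stopover", 5)

    def test_signpost_landing_extends_to_fourteen_days(self, uniform_world):
        action = stopover_policy(self.make(20.0, switched=True), uniform_world)
        assert action == ("stopover", 14)


class TestJourneys:
    def test_short_hop_to_goal_succeeds(self, uniform_world, uniform_field):
        # natal cell just north of the goal region, exact compass, heading south
        ind = Individual(natal_lat=16.5, natal_lon=0.5, genome=Genome(theta1=180.0),
                         departure_doy=232.0)
        out = simulate_journey(ind, uniform_world, uniform_field, CompassMode(),
                               ZERO_NOISE, year=1900.0, seed=5)
        assert out.success
        assert uniform_world.goal_region.contains(out.arrival_lat, out.arrival_lon)

    def test_poleward_flight_exits(self, uniform_world, uniform_field):
        ind = Individual(natal_lat=79.5, natal_lon=0.5, genome=Genome(theta1=0.0),
                         departure_doy=232.0)
        out = simulate_journey(ind, uniform_world, uniform_field, CompassMode(),
                               ZERO_NOISE, year=1900.0, seed=5)
        assert out.status == STATUS_LABELS[POLEWARD_EXIT]

    def test_heading_into_open_ocean_is_lethal(self, barrier_world, barrier_field):
        # due south from the western natal mainland: thousands of km of water
        ind = Individual(natal_lat=65.5, natal_lon=-45.5, genome=Genome(theta1=180.0),
                         departure_doy=232.0)
        out = simulate_journey(ind, barrier_world, barrier_field, CompassMode(),
                               ZERO_NOISE, year=1900.0, seed=5)
        assert out.status == STATUS_LABELS[OVERWATER_MORTALITY]

    def test_outcomes_exhaustive_and_exclusive(self, barrier_world, barrier_field):
        rng = np.random.default_rng(10)
        n = 400
        lat, lon = sample_natal_locations(barrier_world, n, rng)
        res = simulate_cohort(lat, lon, rng.uniform(90, 270, n), rng.uniform(90, 270, n),
                              rng.uniform(35_000, 55_000, n), "intensity",
                              barrier_world, barrier_field, CompassMode(), Precisions(),
                              field_year=1900.0, seed=3)
        assert set(np.unique(res.status)) <= set(STATUS_LABELS)
        assert np.all(res.status != 0)  # every journey reaches a terminal fate
        assert res.arrival_fraction + res.overwater_fraction <= 1.0
        # switched implies a recorded switch location
        assert np.all(np.isfinite(res.zugknick_lat[res.switched]))
        assert np.all(np.isnan(res.zugknick_lat[~res.switched]))

    def test_zero_noise_runs_bitwise_reproducible(self, uniform_world, uniform_field):
        rng = np.random.default_rng(11)
        n = 50
        lat, lon = sample_natal_locations(uniform_world, n, rng)
        theta = rng.uniform(160, 200, n)
        kwargs = dict(signpost_value=np.zeros(n), signpost_type="none",
                      world=uniform_world, field_provider=uniform_field,
                      mode=CompassMode(), precisions=ZERO_NOISE,
                      field_year=1900.0, seed=17, departure_doy=232.0)
        a = simulate_cohort(lat, lon, theta, np.zeros(n), **kwargs)
        b = simulate_cohort(lat, lon, theta, np.zeros(n), **kwargs)
        np.testing.assert_array_equal(a.status, b.status)
        np.testing.assert_allclose(a.final_lat, b.final_lat, atol=1e-9)
        np.testing.assert_allclose(a.final_lon, b.final_lon, atol=1e-9)

    def test_track_recording_does_not_alter_outcomes(self, uniform_world, uniform_field):
        rng = np.random.default_rng(12)
        n = 60
        lat, lon = sample_natal_locations(uniform_world, n, rng)
        theta = rng.uniform(150, 210, n)
        kwargs = dict(signpost_value=np.zeros(n), signpost_type="none",
                      world=uniform_world, field_provider=uniform_field,
                      mode=CompassMode(), precisions=Precisions(),
                      field_year=1900.0, seed=23)
        plain = simulate_cohort(lat, lon, theta, np.zeros(n), **kwargs)
        tracked = simulate_cohort(lat, lon, theta, np.zeros(n), record_tracks=True, **kwargs)
        np.testing.assert_array_equal(plain.status, tracked.status)
        np.testing.assert_array_equal(plain.final_lat, tracked.final_lat)
        assert tracked.tracks and len(tracked.tracks) >= n  # at least a departure each


class TestGenomeValidation:
    def test_headings_normalized(self):
        g = Genome(theta1=-30.0, theta2=370.0)
        assert g.theta1 == 330.0 and g.theta2 == 10.0

    def test_bad_signpost_type_rejected(self):
        with pytest.raises(ValueError):
            Genome(theta1=0.0, signpost_type="azimuth")

    def test_intensity_signpost_must_be_positive(self):
        with pytest.raises(ValueError):
            Genome(theta1=0.0, signpost_type="intensity", signpost_value=0.0)
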