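"""Selection, inheritance, self-adaptation, spin-up and run driver."""

import numpy as np
import pytest
from scipy import stats

from magmigrate.circular import circular_dispersion, circular_mean
from magmigrate.evolution import (
    PopulationState,
    RunConfig,
    SPINUP_RANGES,
    _repopulate,
    inherit_genome,
    initialize_spinup_population,
    run_simulation,
    run_spin_up,
    select_parents,
    self_adapt_sigmas,
)
from magmigrate.geodesy import wrap_angle
from magmigrate.migration import Genome


def halfnormal_weight(d_km, mean_km):
    """Brute-force half-normal density oracle with the kernel mean = D_N."""
    s = mean_km * np.sqrt(np.pi / 2.0)
    return np.sqrt(2.0 / np.pi) / s * np.exp(-(d_km**2) / (2.0 * s**2))


class TestSelectParents:
    def test_equal_distances_select_uniformly(self):
        rng = np.random.default_rng(1)
        # four candidates due N/S/E/W of the focal point at equal distance
        pool_lat = np.array([60.5, 59.5, 60.0, 60.0])
        pool_lon = np.array([0.0, 0.0, 1.0, -1.0])
        pool_lat[2] = pool_lat[3] = 60.0
        d0 = 0.5 * 111.19493
        pool_lon[2] = d0 / (111.19493 * np.cos(np.deg2rad(60.0)))
        pool_lon[3] = -pool_lon[2]
        counts = np.zeros(4)
        for _ in range(5_000):
            a, b = select_parents((60.0, 0.0), pool_lat, pool_lon, 20.0, rng)
            counts[a] += 1
            counts[b] += 1
        chi2 = np.sum((counts - counts.mean()) ** 2 / counts.mean())
        assert stats.chi2.sf(chi2, df=3) > 1e-3

    def test_two_candidate_ratio_matches_density_oracle(self):
        rng = np.random.default_rng(2)
        d_n = 20.0
        far = 3.0 * d_n  # km
        pool_lat = np.array([60.0, 60.0 + far / 111.19493])
        pool_lon = np.zeros(2)
        w = halfnormal_weight(np.array([0.0, far]), d_n)
        p_far = w[1] / w.sum()
        # the density ratio at 3*D_N is exp(-9/pi) under the mean-D_N scale
        assert w[1] / w[0] == pytest.approx(np.exp(-9.0 / np.pi), rel=1e-12)
        picks = np.array([select_parents((60.0, 0.0), pool_lat, pool_lon, d_n, rng)
                          for _ in range(10_000)]).ravel()
        freq_far = np.mean(picks == 1)
        assert freq_far == pytest.approx(p_far, abs=3 * np.sqrt(p_far / 20_000) + 0.005)

    def test_frequencies_match_enumerated_weights(self):
        rng = np.random.default_rng(3)
        d_n = 30.0
        offsets_km = np.array([5.0, 20.0, 45.0, 80.0, 130.0])
        pool_lat = 60.0 + offsets_km / 111.19493
        pool_lon = np.zeros(5)
        w = halfnormal_weight(offsets_km, d_n)
        p = w / w.sum()
        picks = np.array([select_parents((60.0, 0.0), pool_lat, pool_lon, d_n, rng)
                          for _ in range(5_000)]).ravel()
        counts = np.bincount(picks, minlength=5)
        expected = p * len(picks)
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=4) > 1e-3

    def test_pool_of_one_selfs(self):
        rng = np.random.default_rng(4)
        a, b = select_parents((60.0, 0.0), np.array([61.0]), np.array([0.0]), 10.0, rng)
        assert a == b == 0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_parents((60.0, 0.0), np.array([]), np.array([]), 10.0,
                           np.random.default_rng(0))


class TestInheritGenome:
    def test_perfect_inheritance_averages_exactly(self, rng):
        pa = Genome(theta1=130.0, theta2=200.0, signpost_type="intensity",
                    signpost_value=50_000.0)
        pb = Genome(theta1=140.0, theta2=220.0, signpost_type="intensity",
                    signpost_value=52_000.0)
        child = inherit_genome(pa, pb, "perfect", rng)
        assert child.theta1 == pytest.approx(135.0)
        assert child.theta2 == pytest.approx(210.0)
        assert child.signpost_value == pytest.approx(51_000.0)

    def test_perfect_averaging_wraps_correctly(self, rng):
        pa = Genome(theta1=350.0)
        pb = Genome(theta1=10.0)
        assert inherit_genome(pa, pb, "perfect", rng).theta1 == pytest.approx(0.0)

    def test_antipodal_headings_resolve_to_first_parent(self, rng):
        pa = Genome(theta1=0.0)
        pb = Genome(theta1=180.0)
        assert inherit_genome(pa, pb, "perfect", rng).theta1 == pytest.approx(0.0)

    def test_intrinsic_heading_dispersion_recovers_sigma(self):
        # identical parents: offspring dispersion equals the intrinsic sigma
        rng = np.random.default_rng(6)
        sigma = 2.6  # the model-evolved heading variability scale
        parent = Genome(theta1=150.0, sigma_theta=sigma)
        thetas = np.array([inherit_genome(parent, parent, "intrinsic", rng).theta1
                           for _ in range(100_000)])
        assert circular_dispersion(thetas) == pytest.approx(sigma, rel=0.05)
        assert abs(wrap_angle(circular_mean(thetas) - 150.0)) < 0.1

    def test_intensity_signpost_inheritance_moments(self):
        rng = np.random.default_rng(7)
        pa = Genome(theta1=0.0, signpost_type="intensity", signpost_value=50_000.0,
                    sigma_signpost=0.53)
        pb = Genome(theta1=0.0, signpost_type="intensity", signpost_value=52_000.0,
                    sigma_signpost=0.53)
        vals = np.array([inherit_genome(pa, pb, "intrinsic", rng).signpost_value
                         for _ in range(100_000)])
        assert vals.mean() == pytest.approx(51_000.0, abs=10.0)
        assert vals.std() == pytest.approx(0.0053 * 51_000.0, rel=0.03)

    def test_mismatched_signpost_types_rejected(self, rng):
        pa = Genome(theta1=0.0, signpost_type="inclination", signpost_value=60.0)
        pb = Genome(theta1=0.0, signpost_type="intensity", signpost_value=50_000.0)
        with pytest.raises(ValueError):
            inherit_genome(pa, pb, "intrinsic", rng)


class TestSelfAdaptation:
    def test_mutation_disabled_returns_parental_mean(self, rng):
        got = self_adapt_sigmas(2.0, 3.0, 0.4, (0.1, 10.0), rng, mutate=False)
        assert got == pytest.approx(2.5)

    def test_lognormal_mutation_median_is_one(self):
        rng = np.random.default_rng(8)
        parent = 1.0
        tau = 1.0 / np.sqrt(6.0)
        muts = self_adapt_sigmas(np.full(100_000, parent), np.full(100_000, parent),
                                 tau, (1e-6, 1e6), rng)
        assert np.median(muts) == pytest.approx(1.0, rel=0.01)

    def test_clipping_at_range_bounds(self, rng):
        got = self_adapt_sigmas(np.full(100, 5.0), np.full(100, 5.0), 0.5,
                                (0.025, 5.0), rng)
        assert np.max(got) <= 5.0
        assert np.min(got) >= 0.025


class TestInitialization:
    def test_initial_headings_point_toward_goal(self, uniform_world, uniform_field):
        cfg = RunConfig(population=300, n_years=5, signpost_type="inclination", seed=9)
        state = initialize_spinup_population(uniform_world, uniform_field, cfg)
        # natal region is due north of the goal: bearings scatter around south
        mean = circular_mean(state.theta1)
        assert abs(wrap_angle(mean - 180.0)) < 15.0

    def test_initial_signposts_bounded_by_endpoint_components(self, uniform_world,
                                                              uniform_field):
        cfg = RunConfig(population=300, n_years=5, signpost_type="inclination", seed=9)
        state = initialize_spinup_population(uniform_world, uniform_field, cfg)
        # inclination decreases from natal (>72 deg) to goal (<35 deg) latitudes
        assert np.all(state.signpost > 5.0) and np.all(state.signpost < 85.0)

    def test_dispersal_within_spinup_range(self, uniform_world, uniform_field):
        cfg = RunConfig(population=500, n_years=5, signpost_type="none", seed=9)
        state = initialize_spinup_population(uniform_world, uniform_field, cfg)
        lo, hi = SPINUP_RANGES["dispersal_km"]
        assert np.all((state.dispersal_km >= lo) & (state.dispersal_km <= hi))
        lo, hi = SPINUP_RANGES["sigma_theta"]
        assert np.all((state.sigma_theta >= lo) & (state.sigma_theta <= hi))


@pytest.fixture(scope="module")
def small_spinup(barrier_world, barrier_field):
    cfg = RunConfig(population=300, n_years=8, signpost_type="intensity", seed=2,
                    spinup_random_gens=6, spinup_fixed_gens=3, start_year=1900)
    init = initialize_spinup_population(barrier_world, barrier_field, cfg)
    viable = run_spin_up(init.copy(), barrier_world, barrier_field, cfg)
    return cfg, init, viable


class TestSpinUp:
    def test_selection_improves_arrival_success(self, small_spinup):
        _, _, viable = small_spinup
        hist = viable.spinup_success_history
        assert np.mean(hist[-3:]) > hist[0]

    def test_variability_traits_frozen_to_population_scalars(self, small_spinup):
        _, _, viable = small_spinup
        assert viable.frozen
        assert np.ptp(viable.sigma_theta) == 0.0
        assert np.ptp(viable.sigma_signpost) == 0.0
        assert np.isfinite(viable.frozen_dispersal_km)
        lo, hi = SPINUP_RANGES["dispersal_km"]
        assert lo <= viable.frozen_dispersal_km <= hi

    def test_comma_strategy_discards_parents(self, small_spinup):
        # every generation rebuilds the genome arrays: nothing is carried over
        cfg, init, viable = small_spinup
        assert viable.generation == cfg.spinup_random_gens + cfg.spinup_fixed_gens
        assert viable.theta1 is not init.theta1
        assert not np.array_equal(viable.theta1, init.theta1)

    def test_natal_locations_are_immutable(self, small_spinup):
        _, init, viable = small_spinup
        np.testing.assert_array_equal(init.natal_lat, viable.natal_lat)
        np.testing.assert_array_equal(init.natal_lon, viable.natal_lon)


class TestMixingDrift:
    def test_uniform_selection_mean_heading_random_walk_is_unbiased(self):
        """With selection off (uniform parent choice) the population mean
        heading drifts without systematic direction."""
        cfg = RunConfig(population=200, n_years=5, signpost_type="none", seed=0,
                        uniform_selection=True)
        displacements = []
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            n = cfg.population
            state = PopulationState(
                natal_lat=np.full(n, 60.0) + rng.uniform(-2, 2, n),
                natal_lon=rng.uniform(-5, 5, n),
                theta1=np.full(n, 150.0), theta2=np.zeros(n),
                signpost=np.zeros(n), signpost_type="none",
                sigma_theta=np.full(n, 2.6), sigma_signpost=np.full(n, 0.5),
                dispersal_km=np.full(n, 16.0), sigma_dispersal_km=np.full(n, 0.1),
                frozen=True, frozen_dispersal_km=16.0,
            )
            for gen in range(10):
                state = _repopulate(state, np.arange(n), cfg, rng, spinup=False)
            displacements.append(wrap_angle(circular_mean(state.theta1) - 150.0))
        displacements = np.asarray(displacements, dtype=float)
        se = displacements.std(ddof=1) / np.sqrt(len(displacements))
        assert abs(displacements.mean()) < 4.0 * se + 0.05


class TestRunDriver:
    def test_population_and_locations_constant_every_year(self, barrier_world,
                                                          barrier_field, small_spinup):
        cfg, _, viable = small_spinup
        res = run_simulation(viable.copy(), barrier_world, barrier_field, cfg)
        assert res.final_state.size == cfg.population
        np.testing.assert_array_equal(res.final_state.natal_lat, viable.natal_lat)
        assert len(res.p_y) == cfg.n_years
        assert np.all((res.p_y >= 0) & (res.p_y <= 1))

    def test_year_orderings(self):
        cfg = RunConfig(population=10, start_year=1900, n_years=3)
        assert cfg.year_sequence() == [1900, 1901, 1902]
        assert RunConfig(population=10, start_year=1900, n_years=3,
                         year_order="reversed").year_sequence() == [1902, 1901, 1900]
        assert RunConfig(population=10, start_year=1900, n_years=3,
                         year_order="fixed").year_sequence() == [1900, 1900, 1900]

    def test_reversed_equals_forward_on_static_field(self, uniform_world, uniform_field):
        """On a time-invariant field the geomagnetic year ordering is
        irrelevant: seed-matched forward and reversed runs coincide."""
        results = {}
        for order in ("forward", "reversed"):
            cfg = RunConfig(population=150, n_years=4, signpost_type="none", seed=31,
                            year_order=order, spinup_random_gens=2, spinup_fixed_gens=1)
            state = initialize_spinup_population(uniform_world, uniform_field, cfg)
            state = run_spin_up(state, uniform_world, uniform_field, cfg)
            results[order] = run_simulation(state, uniform_world, uniform_field, cfg)
        np.testing.assert_array_equal(results["forward"].p_y, results["reversed"].p_y)
        np.testing.assert_allclose(results["forward"].final_state.theta1,
                                   results["reversed"].final_state.theta1)
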