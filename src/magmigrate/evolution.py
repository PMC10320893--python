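"""Population-level evolutionary loop: selection, inheritance, spin-up, runs.

Each simulated year every natal location is repopulated with one naive
offspring bred from two successful migrants of the previous year (a
comma-strategy: parents are discarded). Parent selection is weighted by a
half-normal natal-dispersal kernel of the great-circle distance between the
candidate's natal site and the focal location; trait inheritance centres
offspring traits on parental means with intrinsic (stochastic) variability.
A model spin-up evolves viable headings, signposts, dispersal and the
intrinsic variabilities themselves (self-adaptation with log-normal sigma
mutation); the subsequent experiment freezes the variabilities at their
evolved population averages and tracks yearly arrival success across the
configured geomagnetic year ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import circular
from .flight import CompassMode, MAGNETIC
from .geodesy import great_circle_distance, initial_bearing, normalize_lon
from .migration import (
    DEPARTURE_MEAN_DOY,
    Genome,
    Precisions,
    simulate_cohort,
)
from .world import World, sample_natal_locations

__all__ = [
    "PopulationState",
    "RunConfig",
    "SimulationResult",
    "SpinupExtinctionError",
    "HALF_NORMAL_SCALE_FACTOR",
    "SPINUP_RANGES",
    "select_parents",
    "inherit_genome",
    "self_adapt_sigmas",
    "initialize_spinup_population",
    "run_spin_up",
    "run_simulation",
]

# half-normal with scale s has mean s*sqrt(2/pi); the kernel is parameterized
# by its mean D_N, so s = D_N * sqrt(pi/2)
HALF_NORMAL_SCALE_FACTOR = float(np.sqrt(np.pi / 2.0))

# spin-up sampling ranges (km for dispersal; degrees or percent for sigmas)
SPINUP_RANGES = {
    "sigma_theta": (0.025, 5.0),          # deg
    "sigma_signpost_angular": (0.1, 1.0),  # deg (inclination/declination)
    "sigma_signpost_intensity": (0.1, 1.0),  # percent
    "dispersal_km": (0.025, 25.0),
    "sigma_dispersal_km": (0.0025, 1.0),
}


class SpinupExtinctionError(RuntimeError):
    """Raised when a spin-up generation produces no successful migrant."""


@dataclass
class PopulationState:
    """Current population: fixed natal locations plus per-location genomes."""

    natal_lat: np.ndarray
    natal_lon: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    signpost: np.ndarray
    signpost_type: str
    sigma_theta: np.ndarray
    sigma_signpost: np.ndarray
    dispersal_km: np.ndarray
    sigma_dispersal_km: np.ndarray
    generation: int = 0
    frozen: bool = False
    frozen_dispersal_km: float = np.nan

    @property
    def size(self) -> int:
        return len(self.natal_lat)

    def copy(self) -> "PopulationState":
        return PopulationState(
            natal_lat=self.natal_lat.copy(), natal_lon=self.natal_lon.copy(),
            theta1=self.theta1.copy(), theta2=self.theta2.copy(),
            signpost=self.signpost.copy(), signpost_type=self.signpost_type,
            sigma_theta=self.sigma_theta.copy(), sigma_signpost=self.sigma_signpost.copy(),
            dispersal_km=self.dispersal_km.copy(),
            sigma_dispersal_km=self.sigma_dispersal_km.copy(),
            generation=self.generation, frozen=self.frozen,
            frozen_dispersal_km=self.frozen_dispersal_km,
        )


@dataclass
class RunConfig:
    """Experiment settings (defaults mirror the full-scale study conditions)."""

    population: int = 50_000
    start_year: int = 1900
    n_years: int = 124
    year_order: str = "forward"          # forward | reversed | fixed
    signpost_type: str = "intensity"     # none | inclination | intensity | declination
    mode: CompassMode = dc_field(default_factory=CompassMode)
    precisions: Precisions = dc_field(default_factory=Precisions)
    inheritance: str = "intrinsic"       # intrinsic | perfect
    seed: int = 0
    spinup_random_gens: int = 50
    spinup_fixed_gens: int = 25
    uniform_selection: bool = False      # selection off (drift experiments)
    dispersal_override_km: Optional[float] = None  # fixed-kernel sensitivity runs

    def __post_init__(self):
        if self.year_order not in ("forward", "reversed", "fixed"):
            raise ValueError(f"year_order: {self.year_order}")
        if self.inheritance not in ("intrinsic", "perfect"):
            raise ValueError(f"inheritance: {self.inheritance}")

    def year_sequence(self) -> list[int]:
        years = list(range(self.start_year, self.start_year + self.n_years))
        if self.year_order == "reversed":
            return years[::-1]
        if self.year_order == "fixed":
            return [self.start_year] * self.n_years
        return years

    @property
    def n_adaptive_traits(self) -> int:
        return 2 if self.signpost_type == "none" else 3

    @property
    def tau(self) -> float:
        return 1.0 / np.sqrt(2.0 * self.n_adaptive_traits)

    def sigma_signpost_range(self):
        if self.signpost_type == "intensity":
            return SPINUP_RANGES["sigma_signpost_intensity"]
        return SPINUP_RANGES["sigma_signpost_angular"]


# ---------------------------------------------------------------------------
# Selection and inheritance
# ---------------------------------------------------------------------------


def _dispersal_log_weights(dist_km, scale_km):
    """Log half-normal density (up to a constant) at distances ``dist_km``."""
    scale = np.maximum(np.asarray(scale_km, dtype=float), 1e-9)
    return -0.5 * (np.asarray(dist_km) / scale) ** 2 - np.log(scale)


def select_parents(location, pool_lat, pool_lon, dispersal_mean_km, rng,
                   uniform: bool = False):
    """Select two parents (with replacement) for one natal location.

    Candidates are all successful migrants; each is weighted by the
    half-normal dispersal density at the distance from its natal site to the
    focal location, with scale = D_N * sqrt(pi/2) so the kernel mean is D_N.
    ``dispersal_mean_km`` may be a scalar (frozen population value) or a
    per-candidate array (spin-up, where D_N is an evolving individual
    trait). Returns a pair of candidate indices.
    """
    pool_lat = np.asarray(pool_lat, dtype=float)
    pool_lon = np.asarray(pool_lon, dtype=float)
    if pool_lat.size == 0:
        raise ValueError("empty successful pool: local extinction")
    lat, lon = location
    d = great_circle_distance(lat, lon, pool_lat, pool_lon)
    if uniform:
        w = np.ones_like(d)
    else:
        logw = _dispersal_log_weights(d, np.asarray(dispersal_mean_km) * HALF_NORMAL_SCALE_FACTOR)
        w = np.exp(logw - logw.max())
    w = w / w.sum()
    picks = rng.choice(pool_lat.size, size=2, replace=True, p=w)
    return int(picks[0]), int(picks[1])


def _pairwise_circular_mean(a_deg, b_deg, tie_to_first=True):
    """Circular mean of two angle arrays; antipodal ties take the first parent."""
    ar = np.deg2rad(a_deg)
    br = np.deg2rad(b_deg)
    c = np.cos(ar) + np.cos(br)
    s = np.sin(ar) + np.sin(br)
    mean = np.rad2deg(np.arctan2(s, c)) % 360.0
    degenerate = np.hypot(c, s) < 1e-9
    if tie_to_first:
        return np.where(degenerate, np.asarray(a_deg) % 360.0, mean)
    return mean, degenerate


def self_adapt_sigmas(sigma_a, sigma_b, tau, bounds, rng, mutate: bool = True):
    """Offspring intrinsic-variability trait (spin-up self-adaptation).

    The parental mean is multiplied by a log-normal mutation
    exp(tau * N(0, 1)) (median multiplicative change 1) and clipped to the
    spin-up sampling range. ``mutate=False`` returns the parental mean.
    """
    mean = 0.5 * (np.asarray(sigma_a, dtype=float) + np.asarray(sigma_b, dtype=float))
    if mutate and tau > 0:
        mean = mean * np.exp(tau * rng.standard_normal(np.shape(mean) or None))
    return np.clip(mean, bounds[0], bounds[1])


def inherit_genome(parent_a: Genome, parent_b: Genome, mode: str, rng) -> Genome:
    """Breed one offspring genome from two parents.

    ``mode`` is "intrinsic" (offspring traits sampled around parental means
    with the parents' intrinsic variability: von Mises for headings and
    angular signposts, relative normal for intensity signposts) or
    "perfect" (exact averaging, zero noise). Antipodal parental headings
    deterministically resolve to the first parent's angle.
    """
    if parent_a.signpost_type != parent_b.signpost_type:
        raise ValueError("parents must share a signpost type")
    sigma_theta = 0.5 * (parent_a.sigma_theta + parent_b.sigma_theta)
    sigma_sp = 0.5 * (parent_a.sigma_signpost + parent_b.sigma_signpost)
    dispersal = 0.5 * (parent_a.dispersal_km + parent_b.dispersal_km)

    def heading(a, b):
        try:
            mean = circular.circular_mean([a, b])
        except circular.DegenerateMeanError:
            mean = a % 360.0
        if mode == "perfect" or sigma_theta <= 0:
            return mean
        kappa = circular.sigma_to_kappa(sigma_theta)
        return float(circular.sample_von_mises(mean, kappa, None, rng))

    theta1 = heading(parent_a.theta1, parent_b.theta1)
    theta2 = heading(parent_a.theta2, parent_b.theta2)

    sp_type = parent_a.signpost_type
    sp_mean = 0.5 * (parent_a.signpost_value + parent_b.signpost_value)
    if sp_type == "none" or mode == "perfect" or sigma_sp <= 0:
        signpost = sp_mean
    elif sp_type == "intensity":
        signpost = sp_mean * (1.0 + sigma_sp / 100.0 * rng.standard_normal())
    else:
        noise = circular.sample_von_mises(0.0, circular.sigma_to_kappa(sigma_sp), None, rng)
        signpost = sp_mean + float(normalize_lon(noise))
        if sp_type == "inclination":
            signpost = float(np.clip(signpost, -90.0, 90.0))
    return Genome(
        theta1=theta1, theta2=theta2, signpost_type=sp_type, signpost_value=signpost,
        sigma_theta=sigma_theta, sigma_signpost=sigma_sp, dispersal_km=dispersal,
        sigma_dispersal_km=0.5 * (parent_a.sigma_dispersal_km + parent_b.sigma_dispersal_km),
    )


def _sample_vm_array(mu_deg, kappa, rng):
    """Per-element von Mises draws (degrees) with a safe large-kappa branch."""
    mu = np.asarray(mu_deg, dtype=float)
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), mu.shape).copy()
    out = np.empty_like(mu)
    big = kappa >= 1e6
    if np.any(big):
        out[big] = mu[big] + np.rad2deg(rng.standard_normal(big.sum()) / np.sqrt(kappa[big]))
    if np.any(~big):
        out[~big] = mu[~big] + np.rad2deg(rng.vonmises(0.0, np.maximum(kappa[~big], 1e-12)))
    return out % 360.0


def _repopulate(state: PopulationState, success_idx: np.ndarray, cfg: RunConfig,
                rng, spinup: bool) -> PopulationState:
    """Breed next year's population (vectorized over natal locations).

    If some location's pool is empty (never happens here: the pool is global),
    the global successful pool serves all locations; zero global successes
    must be handled by the caller before calling this.
    """
    n = state.size
    pool = success_idx
    pool_lat = state.natal_lat[pool]
    pool_lon = state.natal_lon[pool]
    if spinup:
        scale = state.dispersal_km[pool] * HALF_NORMAL_SCALE_FACTOR
    else:
        d_n = cfg.dispersal_override_km if cfg.dispersal_override_km is not None \
            else state.frozen_dispersal_km
        scale = float(d_n) * HALF_NORMAL_SCALE_FACTOR

    u = rng.random((n, 2))
    pa = np.empty(n, dtype=int)
    pb = np.empty(n, dtype=int)
    chunk = max(1, int(4e6 // max(len(pool), 1)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = great_circle_distance(state.natal_lat[lo:hi, None], state.natal_lon[lo:hi, None],
                                  pool_lat[None, :], pool_lon[None, :])
        if cfg.uniform_selection:
            w = np.ones_like(d)
        else:
            logw = _dispersal_log_weights(d, scale)
            w = np.exp(logw - logw.max(axis=1, keepdims=True))
        cs = np.cumsum(w, axis=1)
        tot = cs[:, -1:]
        pa[lo:hi] = np.minimum((cs < u[lo:hi, 0:1] * tot).sum(axis=1), len(pool) - 1)
        pb[lo:hi] = np.minimum((cs < u[lo:hi, 1:2] * tot).sum(axis=1), len(pool) - 1)
    pa = pool[pa]
    pb = pool[pb]

    perfect = cfg.inheritance == "perfect" and not spinup

    # intrinsic-variability traits
    if spinup:
        tau = cfg.tau
        sigma_theta = self_adapt_sigmas(state.sigma_theta[pa], state.sigma_theta[pb],
                                        tau, SPINUP_RANGES["sigma_theta"], rng)
        sigma_sp = self_adapt_sigmas(state.sigma_signpost[pa], state.sigma_signpost[pb],
                                     tau, cfg.sigma_signpost_range(), rng)
        sigma_disp = self_adapt_sigmas(state.sigma_dispersal_km[pa], state.sigma_dispersal_km[pb],
                                       tau, SPINUP_RANGES["sigma_dispersal_km"], rng)
        dispersal = 0.5 * (state.dispersal_km[pa] + state.dispersal_km[pb]) \
            + sigma_disp * rng.standard_normal(n)
        dispersal = np.clip(dispersal, *SPINUP_RANGES["dispersal_km"])
    else:
        sigma_theta = state.sigma_theta.copy()
        sigma_sp = state.sigma_signpost.copy()
        sigma_disp = state.sigma_dispersal_km.copy()
        dispersal = state.dispersal_km.copy()

    # headings
    mean1 = _pairwise_circular_mean(state.theta1[pa], state.theta1[pb])
    mean2 = _pairwise_circular_mean(state.theta2[pa], state.theta2[pb])
    if perfect:
        theta1, theta2 = mean1, mean2
    else:
        kappa = (180.0 / np.pi) ** 2 / np.maximum(sigma_theta, 1e-9) ** 2
        theta1 = _sample_vm_array(mean1, kappa, rng)
        theta2 = _sample_vm_array(mean2, kappa, rng)

    # signposts
    sp_mean = 0.5 * (state.signpost[pa] + state.signpost[pb])
    if state.signpost_type == "none" or perfect:
        signpost = sp_mean
    elif state.signpost_type == "intensity":
        signpost = sp_mean * (1.0 + sigma_sp / 100.0 * rng.standard_normal(n))
    else:
        kappa_sp = (180.0 / np.pi) ** 2 / np.maximum(sigma_sp, 1e-9) ** 2
        noise = normalize_lon(_sample_vm_array(np.zeros(n), kappa_sp, rng))
        signpost = sp_mean + noise
        if state.signpost_type == "inclination":
            signpost = np.clip(signpost, -90.0, 90.0)

    return PopulationState(
        natal_lat=state.natal_lat, natal_lon=state.natal_lon,
        theta1=theta1 % 360.0, theta2=theta2 % 360.0, signpost=signpost,
        signpost_type=state.signpost_type, sigma_theta=sigma_theta,
        sigma_signpost=sigma_sp, dispersal_km=dispersal,
        sigma_dispersal_km=sigma_disp, generation=state.generation + 1,
        frozen=state.frozen, frozen_dispersal_km=state.frozen_dispersal_km,
    )


# ---------------------------------------------------------------------------
# Spin-up
# ---------------------------------------------------------------------------


def initialize_spinup_population(world: World, field_provider, cfg: RunConfig,
                                 rng=None) -> PopulationState:
    """Create the initial spin-up population.

    Headings point from each natal site toward an independently drawn random
    goal-region point (as great-circle initial bearings, offset by natal
    declination for magnetic inherited frames); signposts are uniform
    between the field-component values at the natal site and the goal point
    on the initial year's mean departure date; intrinsic-variability traits
    and mean dispersal are uniform within the spin-up ranges.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 11]))
    n = cfg.population
    natal_lat, natal_lon = sample_natal_locations(world, n, rng)
    goal = world.goal_region
    t0 = cfg.start_year + DEPARTURE_MEAN_DOY / 365.25

    def headings():
        glat = rng.uniform(goal.lat_min, goal.lat_max, n)
        glon = rng.uniform(goal.lon_min, goal.lon_max, n)
        bearing = initial_bearing(natal_lat, natal_lon, glat, glon)
        if cfg.mode.inherited_frame == MAGNETIC:
            d, _, _ = field_provider.sample(natal_lat, natal_lon, t0)
            bearing = (bearing - np.asarray(d, dtype=float).reshape(n)) % 360.0
        return bearing, glat, glon

    theta1, glat1, glon1 = headings()
    theta2, _, _ = headings()

    if cfg.signpost_type == "none":
        signpost = np.zeros(n)
    else:
        dn, inat, fn = field_provider.sample(natal_lat, natal_lon, t0)
        dg, igoal, fg = field_provider.sample(glat1, glon1, t0)
        comp = {"inclination": (inat, igoal), "intensity": (fn, fg),
                "declination": (dn, dg)}[cfg.signpost_type]
        a = np.asarray(comp[0], dtype=float).reshape(n)
        b = np.asarray(comp[1], dtype=float).reshape(n)
        lo_v, hi_v = np.minimum(a, b), np.maximum(a, b)
        signpost = rng.uniform(lo_v, hi_v)

    return PopulationState(
        natal_lat=natal_lat, natal_lon=natal_lon, theta1=theta1, theta2=theta2,
        signpost=signpost, signpost_type=cfg.signpost_type,
        sigma_theta=rng.uniform(*SPINUP_RANGES["sigma_theta"], n),
        sigma_signpost=rng.uniform(*cfg.sigma_signpost_range(), n),
        dispersal_km=rng.uniform(*SPINUP_RANGES["dispersal_km"], n),
        sigma_dispersal_km=rng.uniform(*SPINUP_RANGES["sigma_dispersal_km"], n),
    )


def _simulate_year(state: PopulationState, world, field_provider, cfg: RunConfig,
                   field_year: int, year_index: int):
    return simulate_cohort(
        state.natal_lat, state.natal_lon, state.theta1, state.theta2,
        state.signpost, state.signpost_type, world, field_provider,
        cfg.mode, cfg.precisions, field_year=float(field_year),
        seed=cfg.seed, year_index=year_index,
    )


def run_spin_up(state: PopulationState, world: World, field_provider,
                cfg: RunConfig, progress=None) -> PopulationState:
    """Evolve a viable population, then freeze its variability traits.

    First ``spinup_random_gens`` generations draw the geomagnetic year
    uniformly from the experiment period, then ``spinup_fixed_gens``
    generations use the initial year. Afterwards each sigma trait and the
    mean natal dispersal are set to their evolved population averages.
    """
    year_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    random_years = year_rng.integers(cfg.start_year, cfg.start_year + cfg.n_years,
                                     size=cfg.spinup_random_gens)
    schedule = list(random_years) + [cfg.start_year] * cfg.spinup_fixed_gens
    history = []
    for gen, field_year in enumerate(schedule):
        result = _simulate_year(state, world, field_provider, cfg, int(field_year),
                                year_index=100_000 + gen)
        success = np.nonzero(result.success)[0]
        history.append(result.arrival_fraction)
        if len(success) == 0:
            raise SpinupExtinctionError(
                f"spin-up generation {gen} (field year {field_year}): no successful "
                f"migrant among {state.size}; arrival history {history}")
        mix_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17, gen]))
        state = _repopulate(state, success, cfg, mix_rng, spinup=True)
        if progress is not None:
            progress(gen, len(schedule), history[-1])

    state = state.copy()
    state.sigma_theta[:] = state.sigma_theta.mean()
    state.sigma_signpost[:] = state.sigma_signpost.mean()
    state.sigma_dispersal_km[:] = state.sigma_dispersal_km.mean()
    state.frozen_dispersal_km = float(state.dispersal_km.mean())
    state.dispersal_km[:] = state.frozen_dispersal_km
    state.frozen = True
    state.spinup_success_history = history  # type: ignore[attr-defined]
    return state


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Yearly metric series plus per-individual start/end trait records."""

    years: list
    p_y: np.ndarray
    overwater: np.ndarray
    mean_theta1: np.ndarray
    dispersion_theta1: np.ndarray
    mean_signpost: np.ndarray
    mean_zugknick_lat: np.ndarray
    switched_fraction: np.ndarray
    terminated_early: bool
    final_state: PopulationState
    dheading: np.ndarray        # wrapped per-location theta1 change, last - first
    ddecl_natal: np.ndarray     # declination change at natal sites over the run
    dsignpost: np.ndarray

    @property
    def geometric_mean_success(self) -> float:
        from .metrics import geometric_mean_success
        return geometric_mean_success(self.p_y)

    @property
    def mean_heading_shift(self) -> float:
        """Population-mean inherited-heading change (deg, cw) over the run."""
        return float(np.rad2deg(np.angle(np.mean(np.exp(1j * np.deg2rad(self.dheading))))))


def run_simulation(state: PopulationState, world: World, field_provider,
                   cfg: RunConfig, progress=None) -> SimulationResult:
    """Run the multi-year experiment from a viable (post-spin-up) population."""
    years = cfg.year_sequence()
    theta1_start = state.theta1.copy()
    signpost_start = state.signpost.copy()
    t0 = years[0] + DEPARTURE_MEAN_DOY / 365.25
    t1 = years[-1] + DEPARTURE_MEAN_DOY / 365.25
    d0, _, _ = field_provider.sample(state.natal_lat, state.natal_lon, t0)

    p_y, overwater, mean_t1, disp_t1 = [], [], [], []
    mean_sp, mean_zk, sw_frac = [], [], []
    terminated = False
    for iy, field_year in enumerate(years):
        result = _simulate_year(state, world, field_provider, cfg, field_year,
                                year_index=iy)
        p_y.append(result.arrival_fraction)
        overwater.append(result.overwater_fraction)
        try:
            mean_t1.append(circular.circular_mean(state.theta1))
        except circular.DegenerateMeanError:
            mean_t1.append(np.nan)
        disp_t1.append(circular.circular_dispersion(state.theta1))
        mean_sp.append(float(state.signpost.mean()))
        zk = result.zugknick_lat[result.success & result.switched]
        mean_zk.append(float(np.mean(zk)) if len(zk) else np.nan)
        sw_frac.append(float(np.mean(result.switched)))
        success = np.nonzero(result.success)[0]
        if len(success) == 0:
            terminated = True
            break
        mix_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 19, iy]))
        state = _repopulate(state, success, cfg, mix_rng, spinup=False)
        if progress is not None:
            progress(iy, len(years), p_y[-1])

    d1, _, _ = field_provider.sample(state.natal_lat, state.natal_lon, t1)
    dheading = np.asarray(normalize_lon(state.theta1 - theta1_start))
    ddecl = np.asarray(normalize_lon(np.asarray(d1, float) - np.asarray(d0, float)))
    return SimulationResult(
        years=years[: len(p_y)], p_y=np.asarray(p_y), overwater=np.asarray(overwater),
        mean_theta1=np.asarray(mean_t1), dispersion_theta1=np.asarray(disp_t1),
        mean_signpost=np.asarray(mean_sp), mean_zugknick_lat=np.asarray(mean_zk),
        switched_fraction=np.asarray(sw_frac), terminated_early=terminated,
        final_state=state, dheading=dheading, ddecl_natal=ddecl,
        dsignpost=state.signpost - signpost_start,
    )
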