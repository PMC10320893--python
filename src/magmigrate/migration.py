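"""Simulation of individual autumn journeys from natal site to goal area.

One journey: depart the natal site in a mid-August window, fly nightly
steps under the configured compass mode with per-flight-step directional
noise, gauge the inherited geomagnetic signpost on each landing (switching
to the second heading once its perceived magnitude falls below the
threshold), refuel at stopovers, search for coastline when caught over
water at dawn, and end in one of five fates: success (goal area reached
within 90 days of departure), over-water mortality, overshoot, poleward
exit, or timeout.

The engine is a synchronous day-by-day cohort simulation vectorized over
individuals; ``simulate_journey`` runs a cohort of one. All randomness is
drawn from counter-based streams keyed by (seed, year index, day), in a
fixed order and at fixed population size, so outcomes are independent of
iteration order and of which individuals are still active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from . import circular
from .flight import (
    KM_PER_FLIGHT_HOUR,
    MAGNETIC,
    CompassMode,
    clip_night_hours,
    night_flight_hours,
)
from .geodesy import great_circle_step, normalize_lon
from .world import MAX_DETECTION_KM, World, detection_probability

__all__ = [
    "Genome",
    "Individual",
    "JourneyOutcome",
    "Precisions",
    "STATUS_LABELS",
    "SUCCESS",
    "OVERWATER_MORTALITY",
    "OVERSHOOT",
    "POLEWARD_EXIT",
    "TIMEOUT",
    "draw_departure_date",
    "draw_flight_capacity",
    "gauge_signpost",
    "stopover_policy",
    "simulate_cohort",
    "simulate_journey",
    "CohortResult",
]

# departure window (day-of-year, 365-day calendar): Aug 6 / Aug 20 / Sep 3
DEPARTURE_MEAN_DOY = 232.0
DEPARTURE_SD_DAYS = 5.0
DEPARTURE_EARLIEST_DOY = 218.0
DEPARTURE_LATEST_DOY = 246.0

CAPACITY_MIN_H = 48.0
CAPACITY_MAX_H = 72.0
MAX_JOURNEY_DAYS = 90
POLEWARD_LIMIT_DEG = 87.5
STOPOVER_DAYS = 5
STOPOVER_DAYS_SIGNPOST = 14
STOPOVER_CAPACITY_FACTOR = 3.0

# terminal status codes
IN_PROGRESS = 0
SUCCESS = 1
OVERWATER_MORTALITY = 2
OVERSHOOT = 3
POLEWARD_EXIT = 4
TIMEOUT = 5
STATUS_LABELS = {
    SUCCESS: "success",
    OVERWATER_MORTALITY: "overwater_mortality",
    OVERSHOOT: "overshoot",
    POLEWARD_EXIT: "poleward_exit",
    TIMEOUT: "timeout",
}

SIGNPOST_TYPES = ("none", "inclination", "intensity", "declination")


@dataclass
class Precisions:
    """Perception precisions: flight-step direction and signpost gauging.

    Sigma values are on the circular-precision scale (degrees); intensity
    gauging is a relative normal standard deviation. A non-positive sigma
    disables the corresponding noise (exact perception).
    """

    flight_sigma_deg: float = 15.0
    inclination_sigma_deg: float = 5.0
    intensity_rel_sd: float = 0.02
    declination_sigma_deg: float = 5.0

    def gauge_sigma(self, signpost_type: str) -> float:
        return {
            "inclination": self.inclination_sigma_deg,
            "declination": self.declination_sigma_deg,
            "intensity": self.intensity_rel_sd,
        }[signpost_type]


@dataclass
class Genome:
    """Inherited orientation traits of one migrant.

    ``theta1``/``theta2`` are headings in degrees clockwise from the
    inherited frame's north; ``signpost_value`` is degrees (inclination or
    declination signposts) or nT (intensity). ``sigma_theta`` and
    ``sigma_signpost`` are the intrinsic variabilities in inheritance;
    ``dispersal_km`` the mean natal dispersal D_N (its own inheritance
    noise ``sigma_dispersal_km`` is used during spin-up only).
    """

    theta1: float
    theta2: float = 0.0
    signpost_type: str = "none"
    signpost_value: float = 0.0
    sigma_theta: float = 2.6
    sigma_signpost: float = 0.5
    dispersal_km: float = 16.0
    sigma_dispersal_km: float = 0.1

    def __post_init__(self):
        if self.signpost_type not in SIGNPOST_TYPES:
            raise ValueError(f"signpost_type: {self.signpost_type}")
        if self.signpost_type == "intensity" and self.signpost_value <= 0.0:
            raise ValueError("intensity signpost must be positive")
        self.theta1 = float(self.theta1) % 360.0
        self.theta2 = float(self.theta2) % 360.0
        for name in ("sigma_theta", "sigma_signpost", "dispersal_km", "sigma_dispersal_km"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Individual:
    """One migrant's state (scalar API mirror of the engine's arrays)."""

    natal_lat: float
    natal_lon: float
    genome: Genome
    departure_doy: Optional[float] = None
    flight_capacity_h: float = 60.0
    lat: float = 0.0
    lon: float = 0.0
    date_doy: float = DEPARTURE_MEAN_DOY
    switched: bool = False
    switched_at_landing: bool = False
    last_flight_began_at_sea: bool = False
    state: str = "pre-departure"


@dataclass
class JourneyOutcome:
    """Terminal fate of one journey."""

    status: str
    arrival_lat: float
    arrival_lon: float
    arrival_doy: float
    switched: bool
    zugknick_lat: float = np.nan
    zugknick_lon: float = np.nan

    @property
    def success(self) -> bool:
        return self.status == "success"


# ---------------------------------------------------------------------------
# Scalar operations (reference semantics; the engine vectorizes the same rules)
# ---------------------------------------------------------------------------


def draw_departure_date(rng, mean_doy=DEPARTURE_MEAN_DOY, sd_days=DEPARTURE_SD_DAYS,
                        earliest=DEPARTURE_EARLIEST_DOY, latest=DEPARTURE_LATEST_DOY):
    """Departure day-of-year: normal(Aug 20, 5 d) truncated to [Aug 6, Sep 3]."""
    if sd_days <= 0.0:
        return float(mean_doy)
    a = (earliest - mean_doy) / sd_days
    b = (latest - mean_doy) / sd_days
    return float(stats.truncnorm.rvs(a, b, loc=mean_doy, scale=sd_days, random_state=rng))


def draw_flight_capacity(rng, floor: float = 0.0) -> float:
    """Replenished flight capacity: max(uniform(48, 72) h, current floor)."""
    if floor < 0.0:
        raise ValueError("floor must be >= 0")
    return float(max(rng.uniform(CAPACITY_MIN_H, CAPACITY_MAX_H), floor))


def gauge_signpost(genome: Genome, field_at_landing, rng,
                   precisions: Precisions | None = None) -> bool:
    """Decide whether the perceived signpost triggers the heading switch.

    The migrant perceives the relevant component with noise (von Mises for
    inclination/declination, relative normal for intensity) and switches
    permanently once the perceived magnitude falls below the inherited
    threshold magnitude. Returns True when the switch triggers; a no-op
    (False) for non-signposted genomes.
    """
    if genome.signpost_type == "none":
        return False
    precisions = precisions or Precisions()
    sigma = precisions.gauge_sigma(genome.signpost_type)
    if genome.signpost_type == "intensity":
        true_value = field_at_landing.intensity
        perceived = true_value * (1.0 + sigma * rng.standard_normal()) if sigma > 0 else true_value
    else:
        true_value = (field_at_landing.inclination if genome.signpost_type == "inclination"
                      else field_at_landing.declination)
        if sigma > 0:
            noise = circular.sample_von_mises(0.0, circular.sigma_to_kappa(sigma), None, rng)
            noise = float(normalize_lon(noise))
        else:
            noise = 0.0
        perceived = true_value + noise
    return bool(abs(perceived) < abs(genome.signpost_value))


def stopover_policy(individual: Individual, world: World):
    """Stopover decision at a dawn landing on land.

    A stopover (5 days; 14 when the signpost switched at this landing)
    triggers when remaining flight capacity is below three nightly flight
    durations, or when the completed flight step began at sea. Returns
    ``("stopover", days)`` or ``("continue", None)``. Refuelling at the end
    of the stopover is barred on barren land.
    """
    night = float(clip_night_hours(night_flight_hours(individual.lat, individual.date_doy)))
    triggered = (
        individual.flight_capacity_h < STOPOVER_CAPACITY_FACTOR * night
        or individual.last_flight_began_at_sea
    )
    if not triggered:
        return ("continue", None)
    days = STOPOVER_DAYS_SIGNPOST if individual.switched_at_landing else STOPOVER_DAYS
    return ("stopover", days)


# ---------------------------------------------------------------------------
# Cohort engine
# ---------------------------------------------------------------------------

_PENDING, _READY, _STOPOVER, _AIRBORNE, _DONE = range(5)


@dataclass
class CohortResult:
    """Per-individual journey outcomes for one simulated year."""

    status: np.ndarray
    arrival_doy: np.ndarray
    final_lat: np.ndarray
    final_lon: np.ndarray
    switched: np.ndarray
    zugknick_lat: np.ndarray
    zugknick_lon: np.ndarray
    departure_doy: np.ndarray
    tracks: Optional[list] = None

    @property
    def success(self) -> np.ndarray:
        return self.status == SUCCESS

    @property
    def arrival_fraction(self) -> float:
        return float(np.mean(self.status == SUCCESS))

    @property
    def overwater_fraction(self) -> float:
        return float(np.mean(self.status == OVERWATER_MORTALITY))


def _day_generator(seed: int, year_index: int, day: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(
        key=np.random.SeedSequence([int(seed), int(year_index), int(day)])
        .generate_state(2, np.uint64)))


def _vm_noise(gen, sigma_deg: float, n: int) -> np.ndarray:
    """Centered von Mises directional noise in degrees (zero when sigma <= 0)."""
    if sigma_deg <= 0.0:
        gen.random(n)  # keep the stream layout fixed across precision settings
        return np.zeros(n)
    kappa = circular.sigma_to_kappa(sigma_deg)
    return np.asarray(normalize_lon(
        circular.sample_von_mises(np.zeros(n), kappa, n, gen)))


def simulate_cohort(natal_lat, natal_lon, theta1, theta2, signpost_value,
                    signpost_type: str, world: World, field_provider,
                    mode: CompassMode, precisions: Precisions,
                    field_year: float, seed: int, year_index: int = 0,
                    departure_doy=None, record_tracks: bool = False) -> CohortResult:
    """Simulate every individual's journey for one year.

    ``field_year`` selects the geomagnetic epoch (the seasonal date-of-year
    still advances within it, so reversed-order experiments swap only the
    field). Returns a :class:`CohortResult` of terminal fates.
    """
    n = len(np.atleast_1d(natal_lat))
    natal_lat = np.asarray(natal_lat, dtype=float).reshape(n)
    natal_lon = np.asarray(natal_lon, dtype=float).reshape(n)
    theta1 = np.asarray(theta1, dtype=float).reshape(n)
    theta2 = np.asarray(theta2, dtype=float).reshape(n)
    signpost_value = np.asarray(signpost_value, dtype=float).reshape(n)
    if signpost_type not in SIGNPOST_TYPES:
        raise ValueError(f"signpost_type: {signpost_type}")

    gen0 = _day_generator(seed, year_index, 0)
    if departure_doy is None:
        a = (DEPARTURE_EARLIEST_DOY - DEPARTURE_MEAN_DOY) / DEPARTURE_SD_DAYS
        b = (DEPARTURE_LATEST_DOY - DEPARTURE_MEAN_DOY) / DEPARTURE_SD_DAYS
        departure = stats.truncnorm.rvs(a, b, loc=DEPARTURE_MEAN_DOY,
                                        scale=DEPARTURE_SD_DAYS, size=n, random_state=gen0)
    else:
        gen0.standard_normal(n)
        departure = np.broadcast_to(np.asarray(departure_doy, dtype=float), (n,)).copy()
    capacity0 = gen0.uniform(CAPACITY_MIN_H, CAPACITY_MAX_H, n)
    dep_day = np.floor(departure).astype(int)

    # natal declination for cross-frame imprinting, evaluated at the mean
    # departure date (negligible within-season field change)
    t_imprint = field_year + DEPARTURE_MEAN_DOY / 365.25
    natal_decl = np.zeros(n)
    cross_frame = (mode.primary == MAGNETIC) != (mode.inherited_frame == MAGNETIC)
    if cross_frame:
        d, _, _ = field_provider.sample(natal_lat, natal_lon, t_imprint)
        natal_decl = np.asarray(d, dtype=float).reshape(n)
    # operative heading in the primary compass's frame (imprinted at the
    # natal site when the inherited frame differs from the primary frame)
    if mode.primary == MAGNETIC:
        offset = -natal_decl if cross_frame else 0.0
    else:
        offset = natal_decl if cross_frame else 0.0
    op1 = (theta1 + offset) % 360.0
    op2 = (theta2 + offset) % 360.0
    inflight_magnetic = mode.in_flight == MAGNETIC
    needs_field = (mode.primary == MAGNETIC) or inflight_magnetic

    # mutable global state
    state = np.full(n, _PENDING, dtype=np.int8)
    status = np.full(n, IN_PROGRESS, dtype=np.int8)
    lat = natal_lat.copy()
    lon = natal_lon.copy()
    capacity = np.zeros(n)
    switched = np.zeros(n, dtype=bool)
    stopover_left = np.zeros(n, dtype=np.int16)
    days_since_dep = np.full(n, -1, dtype=np.int16)
    carry_heading = np.zeros(n)     # in-flight-frame heading carried over water
    sea_begin = np.zeros(n, dtype=bool)
    arrival_doy = np.full(n, np.nan)
    zk_lat = np.full(n, np.nan)
    zk_lon = np.full(n, np.nan)
    tracks: list = [] if record_tracks else None

    goal = world.goal_region
    half_lat = 0.5 * (goal.lat_max - goal.lat_min)
    half_lon = 0.5 * (goal.lon_max - goal.lon_min)

    def log(idx, day, event):
        if tracks is not None:
            for k in np.atleast_1d(idx):
                tracks.append((int(k), int(day), float(lat[k]), float(lon[k]), event))

    def finish(idx, code, day):
        idx = np.atleast_1d(idx)
        if len(idx):
            status[idx] = code
            state[idx] = _DONE
            log(idx, day, STATUS_LABELS[code])

    def overshoot_mask(idx):
        return (lat[idx] < goal.lat_min - half_lat) | (
            (lat[idx] <= goal.lat_max)
            & ((lon[idx] < goal.lon_min - half_lon) | (lon[idx] > goal.lon_max + half_lon)))

    def detect(idx, plat, plon, u):
        """Bernoulli coastline detection at positions (plat, plon) for
        global slots idx; returns (detected subset of idx, coastal index)."""
        if len(idx) == 0:
            return idx, idx
        near = world.coast_distance_approx(plat, plon) < MAX_DETECTION_KM + 150.0
        if not near.any():
            return idx[:0], idx[:0]
        ni = np.nonzero(near)[0]
        dist, cidx = world.nearest_coast(plat[ni], plon[ni])
        seen = u[idx[ni]] < detection_probability(dist)
        return idx[ni[seen]], cidx[seen]

    first_day = int(dep_day.min())
    last_day = int(dep_day.max()) + MAX_JOURNEY_DAYS + 1

    for day in range(first_day, last_day + 1):
        if np.all(state == _DONE):
            break
        gen = _day_generator(seed, year_index, day)
        step_noise = _vm_noise(gen, precisions.flight_sigma_deg, n)
        det_u = gen.random((40, n))
        refuel_u = gen.uniform(CAPACITY_MIN_H, CAPACITY_MAX_H, n)
        if signpost_type in ("inclination", "declination"):
            gauge_noise = _vm_noise(gen, precisions.gauge_sigma(signpost_type), n)
        elif signpost_type == "intensity":
            gauge_noise = gen.standard_normal(n)
        else:
            gauge_noise = np.zeros(n)

        # departures
        newly = (state == _PENDING) & (dep_day == day)
        if np.any(newly):
            state[newly] = _READY
            capacity[newly] = capacity0[newly]
            days_since_dep[newly] = 0
            log(np.nonzero(newly)[0], day, "departure")

        # stopover countdown and refuelling
        in_stop = state == _STOPOVER
        if np.any(in_stop):
            stopover_left[in_stop] -= 1
            ending = in_stop & (stopover_left <= 0)
            if np.any(ending):
                refuel_ok = ending & ~world.barren_at(lat, lon)
                capacity[refuel_ok] = np.maximum(capacity[refuel_ok], refuel_u[refuel_ok])
                state[ending] = _READY

        f_idx = np.nonzero((state == _READY) | (state == _AIRBORNE))[0]
        if len(f_idx):
            t_base = field_year + day / 365.25
            t_night = np.zeros(n)
            t_night[f_idx] = clip_night_hours(night_flight_hours(lat[f_idx], day))
            ceil_t = np.zeros(n, dtype=int)
            ceil_t[f_idx] = np.ceil(t_night[f_idx]).astype(int)
            airborne = state == _AIRBORNE
            sea_begin[f_idx] = airborne[f_idx] | ~world.is_land(lat[f_idx], lon[f_idx])

            # resolve the departure bearing
            if needs_field:
                d_dusk, _, _ = field_provider.sample(lat[f_idx], lon[f_idx], t_base)
                d_dusk = np.asarray(d_dusk, dtype=float).reshape(len(f_idx))
            else:
                d_dusk = np.zeros(len(f_idx))
            op = np.where(switched[f_idx], op2[f_idx], op1[f_idx])
            g_dep = op + d_dusk if mode.primary == MAGNETIC else op.copy()
            if inflight_magnetic:
                g_dep = np.where(airborne[f_idx], carry_heading[f_idx] + d_dusk, g_dep)
            else:
                g_dep = np.where(airborne[f_idx], carry_heading[f_idx], g_dep)
            g_noisy = g_dep + step_noise[f_idx]
            # heading held through the night, in the in-flight compass frame
            night_heading = np.zeros(n)
            night_heading[f_idx] = (g_noisy - d_dusk) if inflight_magnetic else g_noisy % 360.0

            flying = np.zeros(n, dtype=bool)
            flying[f_idx] = True
            landed = np.zeros(n, dtype=bool)
            marks = np.zeros((3, n), dtype=int)
            for k, frac in enumerate((0.7, 0.8, 0.9)):
                marks[k, f_idx] = np.ceil(frac * t_night[f_idx]).astype(int)
            dec_pos = np.full((3, n, 2), np.nan)

            def fly_hours(max_h, hours_limit, det_row0, mid_checks, day=day, t_base=t_base):
                """Advance flying individuals hour by hour.

                ``hours_limit`` per-slot integer hours; ``mid_checks`` turns
                on hourly coast detection/landing for sea-begin flights;
                detection uniforms use rows det_row0+h-1.
                """
                for h in range(1, max_h + 1):
                    act = np.nonzero(flying & (status == IN_PROGRESS) & (h <= hours_limit))[0]
                    if len(act) == 0:
                        break
                    dt_h = np.minimum(1.0, np.maximum(t_night[act] - (h - 1), 0.0)) \
                        if det_row0 == 0 else np.ones(len(act))
                    t_now = t_base + h / 24.0 / 365.25
                    if inflight_magnetic:
                        d_now, _, _ = field_provider.sample(lat[act], lon[act], t_now)
                        bearing = night_heading[act] + np.asarray(d_now, float).reshape(len(act))
                    else:
                        bearing = night_heading[act]
                    lat[act], lon[act] = great_circle_step(lat[act], lon[act], bearing,
                                                           KM_PER_FLIGHT_HOUR * dt_h)
                    capacity[act] = np.maximum(capacity[act] - dt_h, 0.0)

                    pole = act[lat[act] > POLEWARD_LIMIT_DEG]
                    if len(pole):
                        finish(pole, POLEWARD_EXIT, day)
                        flying[pole] = False
                        act = act[status[act] == IN_PROGRESS]
                        if len(act) == 0:
                            continue
                    if mid_checks:
                        sb = act[sea_begin[act]]
                        if len(sb):
                            on_land = world.is_land(lat[sb], lon[sb])
                            reach = sb[on_land]
                            landed[reach] = True
                            flying[reach] = False
                            look = sb[~on_land]
                            hit, cidx = detect(look, lat[look], lon[look],
                                               det_u[min(det_row0 + h - 1, 39)])
                            if len(hit):
                                lat[hit] = world.coast_lat[cidx]
                                lon[hit] = world.coast_lon[cidx]
                                landed[hit] = True
                                flying[hit] = False
                    empty = act[(capacity[act] <= 0.0) & flying[act] & ~landed[act]]
                    if len(empty):
                        on_land = world.is_land(lat[empty], lon[empty])
                        ground = empty[on_land]
                        landed[ground] = True
                        flying[ground] = False
                        finish(empty[~on_land], OVERWATER_MORTALITY, day)
                        flying[empty[~on_land]] = False
                    if det_row0 == 0:
                        for k in range(3):
                            hit = act[(marks[k, act] == h) & flying[act]]
                            dec_pos[k, hit, 0] = lat[hit]
                            dec_pos[k, hit, 1] = lon[hit]

            # the night flight: sea-begin flights check for land hourly
            fly_hours(int(ceil_t[f_idx].max()), ceil_t, det_row0=0, mid_checks=True)

            # dawn: land under the bird, else try the last three deciles + dawn
            live = np.nonzero(flying & (status == IN_PROGRESS))[0]
            if len(live):
                on_land = world.is_land(lat[live], lon[live])
                ground = live[on_land]
                landed[ground] = True
                flying[ground] = False
                ow = live[~on_land]
                for k in range(4):
                    if len(ow) == 0:
                        break
                    if k < 3:
                        plat, plon = dec_pos[k, ow, 0], dec_pos[k, ow, 1]
                        valid = np.isfinite(plat)
                        cand = ow[valid]
                        plat, plon = plat[valid], plon[valid]
                    else:
                        cand, plat, plon = ow, lat[ow], lon[ow]
                    hit, cidx = detect(cand, plat, plon, det_u[12 + k])
                    if len(hit):
                        lat[hit] = world.coast_lat[cidx]
                        lon[hit] = world.coast_lon[cidx]
                        landed[hit] = True
                        flying[hit] = False
                        ow = ow[~np.isin(ow, hit)]

                # continuation toward the next dusk, checking every hour
                if len(ow):
                    cont_hours = np.zeros(n, dtype=int)
                    cont_hours[ow] = np.maximum(1, np.ceil(24.0 - t_night[ow])).astype(int)
                    sea_begin[ow] = True
                    fly_hours(int(cont_hours[ow].max()), cont_hours,
                              det_row0=16, mid_checks=True)
                    still_air = np.nonzero(flying & (status == IN_PROGRESS))[0]
                    state[still_air] = _AIRBORNE
                    carry_heading[still_air] = night_heading[still_air]

            # landing processing
            li = np.nonzero(landed & (status == IN_PROGRESS))[0]
            if len(li):
                log(li, day, "landing")
                state[li] = _READY

                in_goal = goal.contains(lat[li], lon[li])
                win = li[in_goal]
                if len(win):
                    arrival_doy[win] = day
                    finish(win, SUCCESS, day)
                li = li[~in_goal]

                if len(li):
                    ov = overshoot_mask(li)
                    finish(li[ov], OVERSHOOT, day)
                    li = li[~ov]

                switched_here = np.zeros(n, dtype=bool)
                if len(li) and signpost_type != "none":
                    unsw = li[~switched[li]]
                    if len(unsw):
                        t_dawn = t_base + 0.5 / 365.25
                        d_l, i_l, f_l = field_provider.sample(lat[unsw], lon[unsw], t_dawn)
                        if signpost_type == "intensity":
                            perceived = np.asarray(f_l, float).reshape(len(unsw)) * (
                                1.0 + precisions.intensity_rel_sd * gauge_noise[unsw])
                        else:
                            comp = i_l if signpost_type == "inclination" else d_l
                            perceived = np.asarray(comp, float).reshape(len(unsw)) \
                                + gauge_noise[unsw]
                        trig = unsw[np.abs(perceived) < np.abs(signpost_value[unsw])]
                        if len(trig):
                            switched[trig] = True
                            switched_here[trig] = True
                            zk_lat[trig] = lat[trig]
                            zk_lon[trig] = lon[trig]
                            log(trig, day, "zugknick")

                if len(li):
                    night_here = clip_night_hours(night_flight_hours(lat[li], day))
                    need = (capacity[li] < STOPOVER_CAPACITY_FACTOR * night_here) | sea_begin[li]
                    si = li[need]
                    state[si] = _STOPOVER
                    stopover_left[si] = np.where(switched_here[si],
                                                 STOPOVER_DAYS_SIGNPOST, STOPOVER_DAYS)

        # overshoot of over-water (airborne) dawn positions
        air = np.nonzero((state == _AIRBORNE) & (status == IN_PROGRESS))[0]
        if len(air):
            finish(air[overshoot_mask(air)], OVERSHOOT, day)

        # per-individual 90-day clock
        started = (days_since_dep >= 0) & (status == IN_PROGRESS)
        days_since_dep[started] += 1
        expired = np.nonzero(started & (days_since_dep > MAX_JOURNEY_DAYS))[0]
        finish(expired, TIMEOUT, day)

    # anything left unfinished at the horizon counts as timed out
    finish(np.nonzero(status == IN_PROGRESS)[0], TIMEOUT, last_day)

    return CohortResult(
        status=status.copy(), arrival_doy=arrival_doy, final_lat=lat.copy(),
        final_lon=lon.copy(), switched=switched.copy(), zugknick_lat=zk_lat,
        zugknick_lon=zk_lon, departure_doy=departure, tracks=tracks,
    )


def simulate_journey(individual: Individual, world: World, field_provider,
                     mode: CompassMode, precisions: Precisions, year: float,
                     seed: int, record_track: bool = False) -> JourneyOutcome:
    """Simulate one migrant's journey (a cohort of one)."""
    g = individual.genome
    res = simulate_cohort(
        [individual.natal_lat], [individual.natal_lon], [g.theta1], [g.theta2],
        [g.signpost_value], g.signpost_type, world, field_provider, mode,
        precisions, field_year=year, seed=seed,
        departure_doy=None if individual.departure_doy is None else [individual.departure_doy],
        record_tracks=record_track,
    )
    return JourneyOutcome(
        status=STATUS_LABELS[int(res.status[0])],
        arrival_lat=float(res.final_lat[0]), arrival_lon=float(res.final_lon[0]),
        arrival_doy=float(res.arrival_doy[0]), switched=bool(res.switched[0]),
        zugknick_lat=float(res.zugknick_lat[0]), zugknick_lon=float(res.zugknick_lon[0]),
    )
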