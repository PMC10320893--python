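"""Night-flight timing, spherical flight steps, and compass-mode logic.

Migrants fly at a constant 15 m/s ground speed (a mean-tailwind-adjusted
value; winds are not modelled) in hourly great-circle substeps. The nightly
flight window runs from 90 minutes after sunset to 90 minutes before
sunrise, clipped to 6-12 h. Compass use is a triple: the frame headings are
inherited in (magnetic or geographic), the primary compass that re-determines
the heading on each departure (magnetic or star), and the in-flight compass
that maintains it through the night (magnetic, updated hourly against local
declination, or star, holding a fixed geographic bearing).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .geodesy import great_circle_step
from .geomag import FieldSample

__all__ = [
    "MAGNETIC",
    "GEOGRAPHIC",
    "STAR",
    "CompassMode",
    "FlightStep",
    "GROUND_SPEED_MS",
    "KM_PER_FLIGHT_HOUR",
    "MIN_NIGHT_HOURS",
    "MAX_NIGHT_HOURS",
    "solar_declination",
    "night_flight_hours",
    "clip_night_hours",
    "step_position",
    "resolve_bearing",
]

MAGNETIC = "magnetic"
GEOGRAPHIC = "geographic"
STAR = "star"  # celestial compass: fixed relative to true (geographic) north

GROUND_SPEED_MS = 15.0
KM_PER_FLIGHT_HOUR = GROUND_SPEED_MS * 3.6  # 54 km per flight hour
MIN_NIGHT_HOURS = 6.0
MAX_NIGHT_HOURS = 12.0


@dataclass(frozen=True)
class CompassMode:
    """One of the 8 combinations of inherited frame, primary and in-flight compass."""

    inherited_frame: str = MAGNETIC   # magnetic | geographic
    primary: str = MAGNETIC           # magnetic | star
    in_flight: str = MAGNETIC         # magnetic | star

    def __post_init__(self):
        if self.inherited_frame not in (MAGNETIC, GEOGRAPHIC):
            raise ValueError(f"inherited_frame: {self.inherited_frame}")
        if self.primary not in (MAGNETIC, STAR):
            raise ValueError(f"primary: {self.primary}")
        if self.in_flight not in (MAGNETIC, STAR):
            raise ValueError(f"in_flight: {self.in_flight}")

    @classmethod
    def all_modes(cls):
        return [cls(f, p, i) for f, p, i in
                product((MAGNETIC, GEOGRAPHIC), (MAGNETIC, STAR), (MAGNETIC, STAR))]

    def label(self) -> str:
        return f"{self.inherited_frame[:3]}-{self.primary[:3]}-{self.in_flight[:3]}"


@dataclass(frozen=True)
class FlightStep:
    """One nightly flight step: start position, resolved bearing, duration."""

    lat: float
    lon: float
    bearing_geographic: float
    hours: float
    ground_speed_ms: float = GROUND_SPEED_MS

    def __post_init__(self):
        if not 0.0 < self.hours:
            raise ValueError("flight hours must be positive")


def solar_declination(day_of_year) -> np.ndarray:
    """Solar declination (degrees) from the standard Fourier approximation.

    Spencer's series; accurate to a few hundredths of a degree, well inside
    the model's needs. ``day_of_year`` counts from 1 (365-day calendar).
    """
    g = 2.0 * np.pi * (np.asarray(day_of_year, dtype=float) - 1.0) / 365.0
    delta = (
        0.006918
        - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g)
    )
    return np.rad2deg(delta)


def night_flight_hours(lat, day_of_year):
    """Raw nightly flight duration T_fl = 24(1 - H/pi) - 3 hours.

    H is the sunset solar hour angle, cos H = -tan(lat) tan(solar decl),
    clamped so polar day/night degenerate smoothly (polar night -> H = 0 ->
    21 h; midnight sun -> H = pi -> -3 h). The -3 h term encodes flying from
    90 min after sunset to 90 min before sunrise. Callers clip the result to
    [6, 12] h (:func:`clip_night_hours`).
    """
    psi = np.deg2rad(np.asarray(lat, dtype=float))
    delta = np.deg2rad(solar_declination(day_of_year))
    cos_h = np.clip(-np.tan(psi) * np.tan(delta), -1.0, 1.0)
    h = np.arccos(cos_h)
    return 24.0 * (1.0 - h / np.pi) - 3.0


def clip_night_hours(t_fl):
    return np.clip(t_fl, MIN_NIGHT_HOURS, MAX_NIGHT_HOURS)


def step_position(pos, bearing_geo, hours, speed_ms=GROUND_SPEED_MS):
    """Great-circle forward step from ``pos`` for ``hours`` at ``speed_ms``.

    Hourly integration substeps use hours <= 1; the closed-form spherical
    direct problem keeps per-step error at machine precision.
    """
    lat, lon = pos
    dist_km = speed_ms * 3.6 * np.asarray(hours, dtype=float)
    return great_circle_step(lat, lon, bearing_geo, dist_km)


def resolve_bearing(mode: CompassMode, inherited_heading, field_now: FieldSample,
                    field_at_departure: FieldSample, phase: str,
                    natal_declination: float | None = None):
    """Geographic bearing implied by an inherited heading under a compass mode.

    ``phase`` is "departure" (the primary compass re-determines the heading)
    or "in_flight" (the in-flight compass maintains it). Magnetic-frame
    bearings convert via geographic = magnetic + declination; the declination
    is the local hourly one for a magnetic in-flight compass, and the frozen
    departure declination when the in-flight compass is star (cue transfer).
    Cross-frame inheritance is imprinted at the natal site: a geographic
    inherited heading used with a magnetic primary compass (or vice versa)
    is offset by ``natal_declination``.

    Returns degrees clockwise from true north in [0, 360).
    """
    if phase not in ("departure", "in_flight"):
        raise ValueError(f"phase: {phase}")
    heading = float(inherited_heading)

    if mode.primary == MAGNETIC:
        if field_at_departure is None:
            raise ValueError("magnetic primary compass requires the departure field")
        if mode.inherited_frame == MAGNETIC:
            operative_magnetic = heading
        else:
            if natal_declination is None:
                raise ValueError("geographic-inherited/magnetic-primary needs natal declination")
            operative_magnetic = heading - natal_declination
        bearing_dep = operative_magnetic + field_at_departure.declination
    else:  # star primary: a fixed geographic bearing per departure
        if mode.inherited_frame == GEOGRAPHIC:
            bearing_dep = heading
        else:
            if natal_declination is None:
                raise ValueError("magnetic-inherited/star-primary needs natal declination")
            bearing_dep = heading + natal_declination

    if phase == "departure":
        return bearing_dep % 360.0

    if mode.in_flight == MAGNETIC:
        if field_now is None or field_at_departure is None:
            raise ValueError("magnetic in-flight compass requires current and departure fields")
        magnetic_in_flight = bearing_dep - field_at_departure.declination
        return (magnetic_in_flight + field_now.declination) % 360.0
    return bearing_dep % 360.0
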