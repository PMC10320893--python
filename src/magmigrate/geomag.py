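"""Geomagnetic core-field providers: analytic tilted dipole and IGRF.

Both providers answer the same question: what are declination (D, degrees
clockwise from true to magnetic north), inclination (I, degrees, positive
downward) and total intensity (F, nT) at a point and time? The dipole is a
closed-form surrogate with a configurable pole-drift track, used for fully
synthetic experiments; the IGRF provider evaluates a standard spherical-
harmonic coefficient file (the published ``igrf13coeffs``-style text format)
with linear interpolation between epochs.

Evaluation is at the surface of a 6371-km sphere; the simulated migrants are
near-surface and the core field dominates at that scale. Crustal anomalies
and magnetic storms are not modelled.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .geodesy import great_circle_distance, normalize_lon

__all__ = [
    "FieldSample",
    "DipoleConfig",
    "DipoleField",
    "IGRFCoefficients",
    "IGRFField",
    "load_igrf",
    "dipole_field",
    "evaluate_field",
    "decimal_year",
    "mean_declination_change",
]


@dataclass(frozen=True)
class FieldSample:
    """Local geomagnetic field: declination/inclination (deg), intensity (nT)."""

    declination: float
    inclination: float
    intensity: float

    def __post_init__(self):
        object.__setattr__(self, "declination", float(normalize_lon(self.declination)))
        if not -90.0 <= self.inclination <= 90.0:
            raise ValueError(f"inclination out of [-90, 90]: {self.inclination}")
        if not self.intensity > 0.0:
            raise ValueError(f"intensity must be positive: {self.intensity}")


class FieldProvider(Protocol):
    """Vectorized field interface used by the migration engine."""

    def sample(self, lat, lon, t): ...  # -> (declination, inclination, intensity)


def decimal_year(when) -> float:
    """Convert a datetime/date to a decimal year (year + day_of_year/365.25).

    Hourly resolution; floats pass through unchanged.
    """
    if isinstance(when, (int, float)):
        return float(when)
    doy = when.timetuple().tm_yday - 1
    hours = 0.0
    if isinstance(when, _dt.datetime):
        hours = when.hour + when.minute / 60.0 + when.second / 3600.0
    return when.year + (doy + hours / 24.0) / 365.25


# ---------------------------------------------------------------------------
# Analytic tilted dipole
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DipoleConfig:
    """A centred tilted dipole with an optional secular pole-drift track.

    ``pole_track`` is a piecewise-linear track of the geomagnetic north
    (boreal) pole as ``(decimal_year, lat, lon)`` rows; a single row gives a
    static field. Alternatively supply callables ``pole_lat_fn(t)`` /
    ``pole_lon_fn(t)``. ``equatorial_intensity_nt`` scales the moment so the
    surface intensity on the geomagnetic equator is that value (the field's
    observed ~30,000 nT); the pole/equator intensity ratio is exactly 2.
    """

    pole_track: tuple = ((1900.0, 90.0, 0.0),)
    pole_lat_fn: Callable[[float], float] | None = None
    pole_lon_fn: Callable[[float], float] | None = None
    equatorial_intensity_nt: float = 30_000.0

    def __post_init__(self):
        if not self.equatorial_intensity_nt > 0.0:
            raise ValueError("equatorial_intensity_nt must be positive")
        track = tuple(tuple(map(float, row)) for row in self.pole_track)
        years = [row[0] for row in track]
        if len(track) > 1 and any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("pole_track years must be strictly increasing")
        object.__setattr__(self, "pole_track", track)

    def pole_position(self, t: float) -> tuple[float, float]:
        """Boreal-pole (lat, lon) at decimal year ``t``."""
        if self.pole_lat_fn is not None and self.pole_lon_fn is not None:
            return float(self.pole_lat_fn(t)), float(self.pole_lon_fn(t))
        track = self.pole_track
        if len(track) == 1:
            return track[0][1], track[0][2]
        years = np.array([r[0] for r in track])
        if t < years[0] - 1e-9 or t > years[-1] + 1e-9:
            raise ValueError(f"time {t} outside pole-track domain [{years[0]}, {years[-1]}]")
        lat = float(np.interp(t, years, [r[1] for r in track]))
        # interpolate longitude via unwrapped values to cross the date line
        lons = np.rad2deg(np.unwrap(np.deg2rad([r[2] for r in track])))
        lon = float(normalize_lon(np.interp(t, years, lons)))
        return lat, lon


class DipoleField:
    """Vectorized provider evaluating :func:`dipole_field`'s closed form."""

    def __init__(self, config: DipoleConfig):
        self.config = config

    def sample(self, lat, lon, t):
        la = np.deg2rad(np.asarray(lat, dtype=float))
        pole_lat, pole_lon = self.config.pole_position(float(t))
        pla = np.deg2rad(pole_lat)
        dlon = np.deg2rad(pole_lon - np.asarray(lon, dtype=float))
        sl, cl = np.sin(la), np.cos(la)
        sp, cp = np.sin(pla), np.cos(pla)
        cd = np.cos(dlon)
        # sin(magnetic latitude) = cos(angular distance to the boreal pole)
        sin_maglat = np.clip(sp * sl + cp * cl * cd, -1.0, 1.0)
        cos_maglat = np.sqrt(1.0 - sin_maglat**2)
        inclination = np.rad2deg(np.arctan2(2.0 * sin_maglat, cos_maglat))
        intensity = self.config.equatorial_intensity_nt * np.sqrt(1.0 + 3.0 * sin_maglat**2)
        # horizontal field points along the great circle toward the boreal pole
        y = np.sin(dlon) * cp
        x = cl * sp - sl * cp * cd
        declination = np.rad2deg(np.arctan2(y, x))
        return declination, inclination, intensity


def dipole_field(cfg: DipoleConfig, lat: float, lon: float, t: float) -> FieldSample:
    """Closed-form dipole evaluation at one point (scalar convenience).

    tan(I) = 2 tan(magnetic latitude); F = F_eq * sqrt(1 + 3 sin^2);
    D is the initial great-circle bearing toward the boreal pole, which is
    exact for a pure dipole's horizontal direction on a sphere. Evaluation
    at the geomagnetic pole (or its antipode) raises: declination is
    undefined there.
    """
    pole_lat, pole_lon = cfg.pole_position(float(t))
    dist = float(great_circle_distance(lat, lon, pole_lat, pole_lon))
    if dist < 1e-6 or dist > np.pi * 6371.0 - 1e-6:
        raise ValueError("declination undefined at the geomagnetic pole/antipode")
    d, i, f = DipoleField(cfg).sample(lat, lon, t)
    return FieldSample(float(d), float(i), float(f))


# ---------------------------------------------------------------------------
# IGRF spherical-harmonic evaluation
# ---------------------------------------------------------------------------


@dataclass
class IGRFCoefficients:
    """Gauss coefficients per epoch plus secular variation for the final epoch."""

    epochs: np.ndarray          # (E,), strictly increasing decimal years
    g: np.ndarray               # (E, nmax+1, nmax+1)
    h: np.ndarray
    sv_g: np.ndarray            # (nmax+1, nmax+1), nT/yr beyond the last epoch
    sv_h: np.ndarray
    nmax: int = field(default=13)

    def at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (g, h) tables at decimal year ``t``."""
        e = self.epochs
        if t < e[0] - 1e-9:
            raise ValueError(f"year {t} before first epoch {e[0]}")
        if t > e[-1] + 5.0 + 1e-9:
            raise ValueError(f"year {t} beyond secular-variation validity ({e[-1] + 5.0})")
        if t >= e[-1]:
            dt = t - e[-1]
            return self.g[-1] + dt * self.sv_g, self.h[-1] + dt * self.sv_h
        i = int(np.searchsorted(e, t, side="right")) - 1
        i = max(i, 0)
        w = (t - e[i]) / (e[i + 1] - e[i])
        return (1 - w) * self.g[i] + w * self.g[i + 1], (1 - w) * self.h[i] + w * self.h[i + 1]


def load_igrf(path) -> IGRFCoefficients:
    """Parse a standard IGRF coefficient text file (``igrf13coeffs`` format).

    Expects ``#`` comment lines, a header row starting ``g/h`` listing the
    epoch columns, then one row per (g|h, degree, order) with coefficients
    per epoch and a trailing secular-variation column.
    """
    epochs = None
    rows = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens or line.lstrip().startswith("#"):
                continue
            if tokens[0] == "c/s":
                continue
            if tokens[0] == "g/h":
                epochs = [float(tok) for tok in tokens[3:-1]]
                continue
            if tokens[0] in ("g", "h"):
                if epochs is None:
                    raise ValueError("coefficient row before g/h header")
                n, m = int(tokens[1]), int(tokens[2])
                vals = [float(tok) for tok in tokens[3:]]
                if len(vals) != len(epochs) + 1:
                    raise ValueError(f"row g/h {n} {m}: expected {len(epochs) + 1} values")
                rows.append((tokens[0], n, m, vals))
    if epochs is None or not rows:
        raise ValueError(f"not a parseable IGRF coefficient file: {path}")
    epochs = np.asarray(epochs, dtype=float)
    if np.any(np.diff(epochs) <= 0):
        raise ValueError("epochs must be strictly increasing")
    nmax = max(r[1] for r in rows)
    ne = len(epochs)
    g = np.zeros((ne, nmax + 1, nmax + 1))
    h = np.zeros((ne, nmax + 1, nmax + 1))
    sv_g = np.zeros((nmax + 1, nmax + 1))
    sv_h = np.zeros((nmax + 1, nmax + 1))
    for kind, n, m, vals in rows:
        target, sv = (g, sv_g) if kind == "g" else (h, sv_h)
        target[:, n, m] = vals[:-1]
        sv[n, m] = vals[-1]
    return IGRFCoefficients(epochs=epochs, g=g, h=h, sv_g=sv_g, sv_h=sv_h, nmax=nmax)


def _schmidt_legendre(nmax: int, theta: np.ndarray):
    """Schmidt quasi-normalized associated Legendre P and dP/dtheta.

    Returns arrays ``P[n][m]`` and ``dP[n][m]`` of shape ``theta.shape``.
    Standard stable recurrences; no Condon-Shortley phase.
    """
    ct, st = np.cos(theta), np.sin(theta)
    P = [[None] * (nmax + 1) for _ in range(nmax + 1)]
    dP = [[None] * (nmax + 1) for _ in range(nmax + 1)]
    P[0][0] = np.ones_like(ct)
    dP[0][0] = np.zeros_like(ct)
    for n in range(1, nmax + 1):
        # sectoral term m = n
        if n == 1:
            P[1][1] = st.copy()
            dP[1][1] = ct.copy()
        else:
            fac = np.sqrt(1.0 - 1.0 / (2.0 * n))
            P[n][n] = fac * st * P[n - 1][n - 1]
            dP[n][n] = fac * (st * dP[n - 1][n - 1] + ct * P[n - 1][n - 1])
        for m in range(n):
            denom = np.sqrt(float(n * n - m * m))
            pm2 = P[n - 2][m] if n >= 2 and m <= n - 2 else 0.0
            dpm2 = dP[n - 2][m] if n >= 2 and m <= n - 2 else 0.0
            k = np.sqrt(max(float((n - 1) ** 2 - m * m), 0.0))
            P[n][m] = ((2 * n - 1) * ct * P[n - 1][m] - k * pm2) / denom
            dP[n][m] = ((2 * n - 1) * (ct * dP[n - 1][m] - st * P[n - 1][m]) - k * dpm2) / denom
    return P, dP


class IGRFField:
    """Field provider evaluating IGRF Gauss coefficients on the sphere surface.

    Full truncation degree of the file (13 for IGRF-13) with linear epoch
    interpolation; both are conventional choices, and results at truncated
    degree are cross-checked against the dipole closed form in the tests.
    """

    def __init__(self, coeffs: IGRFCoefficients, nmax: int | None = None):
        self.coeffs = coeffs
        self.nmax = min(nmax, coeffs.nmax) if nmax is not None else coeffs.nmax

    def sample(self, lat, lon, t):
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        g, h = self.coeffs.at(float(t))
        theta = np.deg2rad(90.0 - lat)
        phi = np.deg2rad(lon)
        P, dP = _schmidt_legendre(self.nmax, theta)
        st = np.sin(theta)
        inv_st = np.where(np.abs(st) < 1e-12, 0.0, 1.0 / np.where(st == 0, 1.0, st))
        X = np.zeros_like(theta)
        Y = np.zeros_like(theta)
        Z = np.zeros_like(theta)
        for n in range(1, self.nmax + 1):
            for m in range(0, n + 1):
                if g[n, m] == 0.0 and h[n, m] == 0.0:
                    continue
                cm, sm = np.cos(m * phi), np.sin(m * phi)
                c = g[n, m] * cm + h[n, m] * sm
                X += c * dP[n][m]
                Z -= (n + 1) * c * P[n][m]
                if m > 0:
                    Y += m * (g[n, m] * sm - h[n, m] * cm) * P[n][m] * inv_st
        horiz = np.hypot(X, Y)
        decl = np.rad2deg(np.arctan2(Y, X))
        incl = np.rad2deg(np.arctan2(Z, horiz))
        intens = np.hypot(horiz, Z)
        return decl, incl, intens


def evaluate_field(provider, lat: float, lon: float, when) -> FieldSample:
    """Evaluate any provider at one point/time; ``when`` may be a datetime."""
    t = decimal_year(when)
    d, i, f = provider.sample(lat, lon, t)
    return FieldSample(float(np.asarray(d).reshape(-1)[0]),
                       float(np.asarray(i).reshape(-1)[0]),
                       float(np.asarray(f).reshape(-1)[0]))


def mean_declination_change(provider, lat_min, lat_max, lon_min, lon_max,
                            year0: float, year1: float, cell_deg: float = 1.0,
                            land_mask=None) -> float:
    """Grid-mean declination change (degrees, clockwise positive) over a box.

    Evaluates the provider at cell centres at ``year0`` and ``year1`` and
    averages the wrapped difference, optionally restricted by a boolean mask
    aligned with the grid.
    """
    lats = np.arange(lat_min + cell_deg / 2.0, lat_max, cell_deg)
    lons = np.arange(lon_min + cell_deg / 2.0, lon_max, cell_deg)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    d0, _, _ = provider.sample(glat.ravel(), glon.ravel(), year0)
    d1, _, _ = provider.sample(glat.ravel(), glon.ravel(), year1)
    delta = normalize_lon(np.asarray(d1) - np.asarray(d0))
    if land_mask is not None:
        delta = delta[np.asarray(land_mask).ravel()]
    return float(np.mean(delta))
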