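"""Packaged synthetic scenarios: worlds plus field configurations.

Every pipeline stage is testable offline through these seeded, fully
serializable scenarios. The flagship ``barrier`` scenario emulates the
study system's geometry: a high-latitude natal landmass separated from the
goal landmass by an ocean wider than the maximum direct flight range
(capacity 72 h at 54 km/h, under 3900 km), with a land corridor reachable
only via an east-then-south detour (a Zugknick route), and a short northern
crossing that keeps single-heading migration marginally viable. The
``secular_drift`` scenario adds a rotating-pole dipole whose declination at
the natal centroid drifts linearly at a configured rate; ``uniform`` is a
zero-declination null world for compass-mode equivalence checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from .geodesy import great_circle_step
from .geomag import DipoleConfig, DipoleField
from .world import Box, LandBlock, SyntheticWorldSpec, World, make_synthetic_world

__all__ = [
    "Scenario",
    "LinearDeclinationField",
    "scenario_barrier_world",
    "scenario_secular_drift",
    "scenario_uniform_field",
    "SCENARIOS",
    "get_scenario",
]

# scaled desk-run defaults; the full-scale study conditions live in RunConfig
TEST_SCALE = {"population": 1000, "n_years": 40,
              "spinup_random_gens": 10, "spinup_fixed_gens": 5}


def _box(box: Box) -> list:
    return [box.lat_min, box.lat_max, box.lon_min, box.lon_max]


@dataclass
class Scenario:
    """A named, seed-complete world + field recipe with run overrides."""

    name: str
    world_spec: SyntheticWorldSpec
    pole_track: tuple = ((1900.0, 90.0, 0.0),)
    equatorial_intensity_nt: float = 30_000.0
    run_overrides: dict = dc_field(default_factory=dict)
    notes: str = ""

    def field_provider(self) -> DipoleField:
        return DipoleField(DipoleConfig(pole_track=self.pole_track,
                                        equatorial_intensity_nt=self.equatorial_intensity_nt))

    def build_world(self, seed: int = 0) -> World:
        return make_synthetic_world(self.world_spec, np.random.default_rng(
            np.random.SeedSequence([seed, 101])))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        ws = self.world_spec
        return {
            "name": self.name,
            "notes": self.notes,
            "pole_track": [list(row) for row in self.pole_track],
            "equatorial_intensity_nt": self.equatorial_intensity_nt,
            "run_overrides": dict(self.run_overrides),
            "world_spec": {
                "domain": _box(ws.domain),
                "cell_deg": ws.cell_deg,
                "barren_patch_fraction": ws.barren_patch_fraction,
                "habitat_noise": ws.habitat_noise,
                "name": ws.name,
                "natal_region": _box(ws.natal_region),
                "goal_region": _box(ws.goal_region),
                "land_blocks": [
                    {"box": _box(b.box), "vegetation": b.vegetation,
                     "low_vegetation": b.low_vegetation, "barren": b.barren,
                     "ndvi": b.ndvi, "name": b.name}
                    for b in ws.land_blocks
                ],
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        ws = data["world_spec"]
        spec = SyntheticWorldSpec(
            domain=Box(*ws["domain"]),
            land_blocks=tuple(
                LandBlock(box=Box(*b["box"]), vegetation=b["vegetation"],
                          low_vegetation=b["low_vegetation"], barren=b["barren"],
                          ndvi=b["ndvi"], name=b["name"])
                for b in ws["land_blocks"]
            ),
            natal_region=Box(*ws["natal_region"]),
            goal_region=Box(*ws["goal_region"]),
            cell_deg=ws["cell_deg"],
            barren_patch_fraction=ws["barren_patch_fraction"],
            habitat_noise=ws["habitat_noise"],
            name=ws["name"],
        )
        return cls(name=data["name"], world_spec=spec,
                   pole_track=tuple(tuple(r) for r in data["pole_track"]),
                   equatorial_intensity_nt=data["equatorial_intensity_nt"],
                   run_overrides=data.get("run_overrides", {}),
                   notes=data.get("notes", ""))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_dict(yaml.safe_load(text))


class LinearDeclinationField:
    """Synthetic field with a linear east-west declination gradient.

    Declination is ``gradient_deg_per_lon * (lon - lon0)`` plus a constant;
    inclination and intensity follow the axial-dipole latitude profiles.
    Used to exercise the self-correction property of magnetic headings on
    eastward-increasing declination gradients.
    """

    def __init__(self, gradient_deg_per_lon: float, lon0: float = 0.0,
                 base_declination: float = 0.0, equatorial_intensity_nt: float = 30_000.0):
        self.gradient = float(gradient_deg_per_lon)
        self.lon0 = float(lon0)
        self.base = float(base_declination)
        self.f_eq = float(equatorial_intensity_nt)

    def sample(self, lat, lon, t):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        decl = self.base + self.gradient * (lon - self.lon0)
        sl = np.sin(np.deg2rad(lat))
        cl = np.cos(np.deg2rad(lat))
        incl = np.rad2deg(np.arctan2(2.0 * sl, cl))
        intensity = self.f_eq * np.sqrt(1.0 + 3.0 * sl**2)
        return decl, incl, intensity


# natal centroid used to anchor the drifting pole's orbit
_NATAL_CENTROID = (68.0, -36.0)


def _barrier_world_spec() -> SyntheticWorldSpec:
    return SyntheticWorldSpec(
        domain=Box(-10.0, 88.0, -85.0, 45.0),
        land_blocks=(
            LandBlock(Box(58.0, 78.0, -50.0, -25.0), name="natal_mainland"),
            LandBlock(Box(70.0, 78.0, -25.0, -10.0), name="natal_east_arm"),
            LandBlock(Box(35.0, 62.0, 0.0, 35.0), name="corridor_north"),
            LandBlock(Box(0.0, 35.0, 5.0, 35.0), name="corridor_south"),
        ),
        natal_region=Box(58.0, 78.0, -45.0, -12.0),
        goal_region=Box(5.0, 15.0, 5.0, 25.0),
        name="barrier",
    )


def scenario_barrier_world() -> Scenario:
    """Ocean-barrier world with a detour corridor; static axial dipole."""
    return Scenario(
        name="barrier",
        world_spec=_barrier_world_spec(),
        pole_track=((1900.0, 90.0, 0.0),),
        run_overrides=dict(TEST_SCALE),
        notes=("Direct natal-to-goal courses cross >4000 km of open ocean, beyond "
               "the 72 h x 54 km/h flight range; a northern crossing (~1100-1800 km) "
               "reaches the corridor landmass, which leads south to the goal."),
    )


def _orbit_pole_track(drift_deg_per_year: float, start_year: float, n_years: int,
                      radius_deg: float = 20.0) -> tuple:
    """Pole track on a small circle around the natal centroid.

    The pole sits at a fixed 20-degree angular radius from the natal
    centroid, at bearing ``drift * (t - start)``; the declination at the
    centroid therefore equals that bearing exactly, giving a linear drift
    of the requested sign and magnitude.
    """
    clat, clon = _NATAL_CENTROID
    rows = []
    for k in range(n_years + 2):
        bearing = drift_deg_per_year * k
        plat, plon = great_circle_step(clat, clon, bearing, radius_deg * 111.19492664455873)
        rows.append((start_year + k, float(plat), float(plon)))
    return tuple(rows)


def scenario_secular_drift(drift_deg_per_year: float, start_year: int = 1900,
                           n_years: int = 60) -> Scenario:
    """Barrier world under a rotating-pole dipole with linear declination drift."""
    if abs(drift_deg_per_year) > 2.0:
        raise ValueError("drift must be within +/-2 deg/yr")
    return Scenario(
        name=f"secular_drift_{drift_deg_per_year:+g}",
        world_spec=_barrier_world_spec(),
        pole_track=_orbit_pole_track(drift_deg_per_year, float(start_year), n_years),
        run_overrides={**TEST_SCALE, "start_year": start_year, "n_years": n_years},
        notes=(f"Declination at the natal centroid drifts {drift_deg_per_year:+g} deg/yr "
               "(clockwise positive) by construction of the pole orbit."),
    )


def scenario_uniform_field() -> Scenario:
    """Zero-declination null world: one landmass, axial dipole, no barrier."""
    return Scenario(
        name="uniform",
        world_spec=SyntheticWorldSpec(
            domain=Box(-10.0, 88.0, -40.0, 40.0),
            land_blocks=(LandBlock(Box(-5.0, 80.0, -30.0, 30.0), name="mainland"),),
            natal_region=Box(60.0, 70.0, -10.0, 10.0),
            goal_region=Box(5.0, 15.0, -10.0, 10.0),
            name="uniform",
        ),
        pole_track=((1900.0, 90.0, 0.0),),
        run_overrides=dict(TEST_SCALE),
        notes="Declination is zero everywhere; all compass modes must coincide.",
    )


SCENARIOS = {
    "barrier": scenario_barrier_world,
    "uniform": scenario_uniform_field,
}


def get_scenario(name: str, **kwargs) -> Scenario:
    if name.startswith("secular_drift"):
        return scenario_secular_drift(**kwargs)
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; have {sorted(SCENARIOS)}") from None
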