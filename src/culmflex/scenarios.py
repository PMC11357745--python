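"""Study scenarios: the published culm archetypes and perturbed variants.

``make_paper_scenarios`` emits the two archetypes everything else is
compared on: the graded culm wall (exponential radial profiles) and its
cross-section-averaged homogeneous twin, on the calibrated 10 m tapered
geometry, under the published wind profile (v0 = 16 m/s at x0 = 10 m,
1/14 power law) with a 100 N tip-load case retained for solver
validation.  ``make_perturbed_suite`` draws seeded log-normal
perturbations of the graded profiles (and optionally the geometry) and
pairs every variant with its own homogenized twin, so robustness
properties can be asserted as suite statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError
from .loading import LoadCase, WindProfile
from .materials import (
    BeamGeometry,
    MaterialModel,
    calibrate_geometry,
    homogenize,
    table1_graded,
    with_noise,
)

__all__ = ["ScenarioSpec", "Scenario", "make_paper_scenarios", "make_perturbed_suite"]

TIP_LOAD_VALIDATION_N = 100.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of the perturbed robustness suite."""

    seed: int = 0
    profile_noise_cv: float = 0.1
    geometry_jitter: float = 0.0
    n_scenarios: int = 20

    def __post_init__(self):
        if self.profile_noise_cv < 0 or self.geometry_jitter < 0:
            raise DomainError("noise parameters must be >= 0")
        if self.n_scenarios < 1:
            raise DomainError("n_scenarios must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """One runnable configuration: material + geometry + loads."""

    material: MaterialModel
    geometry: BeamGeometry
    loads: LoadCase
    label: str = ""
    reference_station: float = 0.0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        prof = lambda p: {  # noqa: E731
            "amplitude_gpa": p.amplitude_gpa,
            "rate_per_mm": p.rate_per_mm,
            "r_origin": p.r_origin,
        }
        return {
            "label": self.label,
            "material": {
                **{k: prof(p) for k, p in self.material.profiles.items()},
                "nu_axial": self.material.nu_axial,
                "nu_transverse": self.material.nu_transverse,
                "label": self.material.label,
            },
            "geometry": {
                "length_m": self.geometry.length,
                "outer_radius_tip_m": self.geometry.outer_radius_tip,
                "wall_thickness_tip_m": self.geometry.wall_thickness_tip,
                "taper_constant": self.geometry.taper_constant,
                "I0_m4": self.geometry.I0,
            },
            "loads": {
                "tip_load_N": self.loads.tip_load,
                "wind": None
                if self.loads.wind is None
                else {
                    "v0_m_s": self.loads.wind.v0,
                    "x0_m": self.loads.wind.x0,
                    "exponent": self.loads.wind.exponent,
                },
                "air_density_kg_m3": self.loads.air_density,
                "drag_coefficient": self.loads.drag_coefficient,
                "resolution": self.loads.resolution,
            },
            "reference_station": self.reference_station,
            "meta": dict(self.meta),
        }


def _wind_case(v0: float = 16.0) -> LoadCase:
    return LoadCase(tip_load=0.0, wind=WindProfile(v0=v0, x0=10.0, exponent=1.0 / 14.0))


def make_paper_scenarios(
    *,
    length: float = 10.0,
    taper_constant: float = 2.0,
    thickness_ratio: float = 0.18,
    reference_station: float = 0.0,
    v0: float = 16.0,
    graded_material: MaterialModel | None = None,
) -> tuple[Scenario, Scenario]:
    """The published graded/homogeneous pair on calibrated geometry.

    The wall annulus is calibrated at the reference station (default the
    clamped root, where culm material characterization specimens are
    conventionally cut) so the graded axial modulus averages to the
    published homogeneous value; the homogeneous twin then *is* the
    cross-section average of the graded wall.
    """
    graded = graded_material if graded_material is not None else table1_graded()
    cal = calibrate_geometry(
        graded,
        length=length,
        taper_constant=taper_constant,
        thickness_ratio=thickness_ratio,
        reference_station=reference_station,
    )
    twin = homogenize(graded, cal.geometry, reference_station)
    loads = _wind_case(v0)
    meta = {
        "calibration_achieved_gpa": cal.achieved_gpa,
        "calibration_target_gpa": cal.target_gpa,
        "calibration_residuals": cal.residuals,
        "tip_load_validation_N": TIP_LOAD_VALIDATION_N,
    }
    return (
        Scenario(graded, cal.geometry, loads, "graded", reference_station, meta),
        Scenario(twin, cal.geometry, loads, "homogeneous", reference_station, meta),
    )


def make_perturbed_suite(spec: ScenarioSpec) -> list[tuple[Scenario, Scenario]]:
    """Seeded log-normal perturbations of the graded wall, paired with twins.

    Each graded variant is re-calibrated and re-homogenized, so every
    pair satisfies ``homogenize(graded) == homogeneous`` by construction.
    Identical seeds reproduce identical suites bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    base = table1_graded()
    pairs = []
    for _ in range(spec.n_scenarios):
        profiles = {
            name: with_noise(p, rng, spec.profile_noise_cv)
            for name, p in base.profiles.items()
        }
        graded = replace(base, **profiles)
        jitter = spec.geometry_jitter
        taper = 2.0 * float(np.exp(rng.normal(0.0, jitter))) if jitter > 0 else 2.0
        thickness = 0.18 * float(np.exp(rng.normal(0.0, jitter))) if jitter > 0 else 0.18
        pairs.append(
            make_paper_scenarios(
                taper_constant=max(1.0, taper),
                thickness_ratio=min(0.6, thickness),
                graded_material=graded,
            )
        )
    return pairs
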