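"""Graded material models and tapered hollow cross-section geometry.

Bamboo culm walls are radially graded: stiff fibre bundles concentrate
toward the outer periphery, so every elastic modulus grows roughly
exponentially with the radial coordinate,

    E(r) = A * exp(k * r),

with ``A`` in GPa and ``r`` in millimetres.  A culm is idealized here as a
hollow tapered cantilever whose second moment of area follows the cubic
taper law

    I(x) = I0 * [1 + (n - 1) * x / (L - Delta)]**3,

with ``x`` measured from the free end (where ``I = I0``), ``n`` the taper
constant and ``Delta`` the horizontal tip shortening of the deformed beam.

The module also provides the homogenization used to build the
"homogeneous" twin of a graded culm (each profile replaced by its
area-weighted mean over the wall annulus at a reference station) and the
calibration of the under-determined wall geometry: the wall annulus is
sized so that the graded axial Young's modulus averages to the published
homogeneous value.

Units
-----
Profiles are stored in field units (GPa, 1/mm) because that is how the
material data are published; geometry is SI (m).  Conversion helpers are
provided where the two meet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import CalibrationError, DomainError, GeometryError

__all__ = [
    "GradedProfile",
    "MaterialModel",
    "BeamGeometry",
    "SectionProperties",
    "eval_profile",
    "second_moment",
    "homogenize",
    "calibrate_geometry",
    "CalibrationResult",
    "section_properties",
    "table1_graded",
    "table1_homogeneous",
]

GPA = 1.0e9
MM = 1.0e-3

# Gauss-Legendre rule reused for all radial wall quadratures.  64 nodes
# integrate exp(k*r) over any physical wall to machine precision.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _wall_quad(f, a: float, b: float) -> float:
    """Integrate ``f`` over ``[a, b]`` with the shared Gauss rule."""
    if b <= a:
        raise GeometryError(f"empty integration interval [{a}, {b}]")
    x = 0.5 * (b - a) * _GL_NODES + 0.5 * (a + b)
    return float(0.5 * (b - a) * np.sum(_GL_WEIGHTS * f(x)))


@dataclass(frozen=True)
class GradedProfile:
    """One elastic property varying as ``A * exp(k * r)`` over the wall.

    Parameters
    ----------
    amplitude_gpa:
        ``A`` in GPa; must be positive.
    rate_per_mm:
        ``k`` in 1/mm.  ``k = 0`` reproduces a homogeneous property
        exactly.
    r_origin:
        Radial datum of ``r``: ``"axis"`` (distance from the section
        axis, the default) or ``"inner"`` (distance from the inner wall
        surface).  The published tables do not state the datum, so it is
        a modelling choice.
    """

    amplitude_gpa: float
    rate_per_mm: float = 0.0
    r_origin: str = "axis"

    def __post_init__(self):
        object.__setattr__(self, "amplitude_gpa", float(self.amplitude_gpa))
        object.__setattr__(self, "rate_per_mm", float(self.rate_per_mm))
        if not self.amplitude_gpa > 0:
            raise DomainError(f"amplitude must be positive, got {self.amplitude_gpa}")
        if self.r_origin not in ("axis", "inner"):
            raise DomainError(f"r_origin must be 'axis' or 'inner', got {self.r_origin!r}")

    @property
    def is_constant(self) -> bool:
        return self.rate_per_mm == 0.0

    def __call__(self, r_mm):
        """Evaluate the profile at radial position ``r`` (mm) -> GPa."""
        if self.is_constant:
            return self.amplitude_gpa * np.ones_like(np.asarray(r_mm, dtype=float))
        return self.amplitude_gpa * np.exp(self.rate_per_mm * np.asarray(r_mm, dtype=float))

    def pa_at_radius(self, r_m, inner_radius_m: float = 0.0):
        """Evaluate in Pa at an absolute radius (m), honouring the datum."""
        r = np.asarray(r_m, dtype=float)
        if self.r_origin == "inner":
            r = r - inner_radius_m
        return np.asarray(self(r / MM)) * GPA


def eval_profile(profile: GradedProfile, r_mm: float, wall_mm: tuple | None = None) -> float:
    """Evaluate ``profile`` at radial position ``r_mm`` (mm) -> GPa.

    If ``wall_mm = (r_inner, r_outer)`` is given, ``r_mm`` must lie inside
    that interval; otherwise a :class:`DomainError` naming the admissible
    range is raised.
    """
    if wall_mm is not None:
        lo, hi = wall_mm
        if not (lo <= r_mm <= hi):
            raise DomainError(
                f"radial position {r_mm} mm outside the wall interval [{lo}, {hi}] mm"
            )
    return float(profile(r_mm))


@dataclass(frozen=True)
class MaterialModel:
    """Transversely isotropic culm wall material.

    Four moduli vary radially (axial/transverse Young's and shear
    moduli); the two Poisson ratios are treated as constants.  ``label``
    distinguishes the graded culm from its cross-section-averaged twin.
    """

    E_axial: GradedProfile
    E_transverse: GradedProfile
    G_axial: GradedProfile
    G_transverse: GradedProfile
    nu_axial: float
    nu_transverse: float
    label: str = "graded"

    def __post_init__(self):
        for name in ("nu_axial", "nu_transverse"):
            nu = getattr(self, name)
            if not 0.0 < nu < 0.5:
                raise DomainError(f"{name} must lie in (0, 0.5), got {nu}")
        if self.label not in ("graded", "homogeneous"):
            raise DomainError(f"label must be 'graded' or 'homogeneous', got {self.label!r}")
        if self.label == "homogeneous" and not self.is_homogeneous:
            raise DomainError("a 'homogeneous' material must have k = 0 in every profile")

    @property
    def profiles(self) -> dict:
        return {
            "E_axial": self.E_axial,
            "E_transverse": self.E_transverse,
            "G_axial": self.G_axial,
            "G_transverse": self.G_transverse,
        }

    @property
    def is_homogeneous(self) -> bool:
        return all(p.is_constant for p in self.profiles.values())


def table1_graded() -> MaterialModel:
    """The published graded culm wall properties (GPa, 1/mm)."""
    return MaterialModel(
        E_axial=GradedProfile(1.23, 0.08),
        E_transverse=GradedProfile(0.56, 0.016),
        G_axial=GradedProfile(0.5, 0.05),
        G_transverse=GradedProfile(0.46, 0.03),
        nu_axial=0.36,
        nu_transverse=0.19,
    )


def table1_homogeneous() -> MaterialModel:
    """The published cross-section-averaged twin properties."""
    return MaterialModel(
        E_axial=GradedProfile(10.9),
        E_transverse=GradedProfile(0.85),
        G_axial=GradedProfile(1.9),
        G_transverse=GradedProfile(1.02),
        nu_axial=0.36,
        nu_transverse=0.19,
        label="homogeneous",
    )


@dataclass(frozen=True)
class BeamGeometry:
    """Hollow tapered cantilever.

    The tip (free-end) annulus is the reference section: ``I0`` is its
    second moment of area.  Away from the tip the inertia follows the
    cubic taper law; the wall keeps a constant thickness-to-radius ratio
    so that outer radius and wall thickness scale as ``I**(1/4)``.
    """

    length: float
    outer_radius_tip: float
    wall_thickness_tip: float
    taper_constant: float = 2.0

    def __post_init__(self):
        if not self.length > 0:
            raise GeometryError(f"length must be positive, got {self.length}")
        if not 0 < self.wall_thickness_tip < self.outer_radius_tip:
            raise GeometryError(
                "wall thickness must satisfy 0 < t < outer radius, got "
                f"t={self.wall_thickness_tip}, R={self.outer_radius_tip}"
            )
        if self.taper_constant < 1.0:
            raise GeometryError(f"taper constant must be >= 1, got {self.taper_constant}")

    @property
    def thickness_ratio(self) -> float:
        return self.wall_thickness_tip / self.outer_radius_tip

    @property
    def I0(self) -> float:
        """Second moment of the tip annulus (m^4)."""
        ro = self.outer_radius_tip
        ri = ro - self.wall_thickness_tip
        return math.pi / 4.0 * (ro**4 - ri**4)

    def taper_factor(self, x, delta: float = 0.0):
        """``1 + (n - 1) x / (L - Delta)`` with ``x`` from the free end."""
        if delta >= self.length:
            raise GeometryError(
                f"tip shortening Delta={delta} >= length {self.length}: beam fully folded"
            )
        x = np.asarray(x, dtype=float)
        span = self.length - delta
        if np.any(x < -1e-12) or np.any(x > span * (1 + 1e-12)):
            raise DomainError(f"station x must lie in [0, {span}], got {x}")
        return 1.0 + (self.taper_constant - 1.0) * x / span

    def radii_at(self, x, delta: float = 0.0):
        """Outer and inner wall radius (m) at station ``x`` from the free end."""
        fac = self.taper_factor(x, delta) ** 0.75
        ro = self.outer_radius_tip * fac
        return ro, ro * (1.0 - self.thickness_ratio)


def second_moment(geometry: BeamGeometry, x, delta: float = 0.0):
    """Cubic taper law ``I(x) = I0 [1 + (n-1) x/(L-Delta)]**3`` (m^4).

    ``x`` is measured from the free end, where ``I = I0``.
    """
    return geometry.I0 * geometry.taper_factor(x, delta) ** 3


@dataclass(frozen=True)
class SectionProperties:
    """Section-level stiffness integrals of a graded annulus."""

    area: float
    I_geometric: float
    EI_effective: float
    EA_effective: float
    neutral_axis_offset: float

    def __post_init__(self):
        for name in ("area", "I_geometric", "EI_effective", "EA_effective"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be positive")

    @property
    def E_effective(self) -> float:
        """Bending-effective modulus ``EI_eff / I`` (Pa)."""
        return self.EI_effective / self.I_geometric


def section_properties(
    material: MaterialModel, geometry: BeamGeometry, x: float, delta: float = 0.0
) -> SectionProperties:
    """Modulus-weighted section integrals at station ``x`` from the free end.

    For a modulus depending only on the radial distance from the section
    axis, the azimuthal integrals are done analytically:

        EA = 2*pi * int E(r) r dr,      EI = pi * int E(r) r^3 dr,

    and the modulus-weighted neutral axis coincides with the section axis
    by symmetry (``int sin(phi) dphi = 0`` exactly), so the offset is zero.
    """
    ro, ri = geometry.radii_at(x, delta)
    E = material.E_axial
    area = math.pi * (ro**2 - ri**2)
    I_geo = math.pi / 4.0 * (ro**4 - ri**4)
    if E.is_constant:
        e0 = E.amplitude_gpa * GPA
        ea, ei = e0 * area, e0 * I_geo
    else:
        ea = 2.0 * math.pi * _wall_quad(lambda r: E.pa_at_radius(r, ri) * r, ri, ro)
        ei = math.pi * _wall_quad(lambda r: E.pa_at_radius(r, ri) * r**3, ri, ro)
    return SectionProperties(
        area=area,
        I_geometric=I_geo,
        EI_effective=ei,
        EA_effective=ea,
        neutral_axis_offset=0.0,  # radial symmetry of E(r)
    )


def _annulus_average(profile: GradedProfile, ri_m: float, ro_m: float, weighting: str = "area"):
    """Average of a profile over the wall ``[ri, ro]`` (m) -> GPa.

    ``weighting="area"`` uses the section-area weight ``r dr`` (the
    default, matching an average "over the cross-section");
    ``weighting="radial"`` is the plain line average used for thin-wall
    or solid-interval checks.
    """
    if profile.is_constant:
        return profile.amplitude_gpa
    if weighting == "area":
        num = _wall_quad(lambda r: profile.pa_at_radius(r, ri_m) * r, ri_m, ro_m)
        den = 0.5 * (ro_m**2 - ri_m**2)
    elif weighting == "radial":
        num = _wall_quad(lambda r: profile.pa_at_radius(r, ri_m), ri_m, ro_m)
        den = ro_m - ri_m
    else:
        raise DomainError(f"unknown weighting {weighting!r}")
    return num / den / GPA


def homogenize(
    material: MaterialModel,
    geometry: BeamGeometry,
    reference_station: float = 0.0,
    weighting: str = "area",
) -> MaterialModel:
    """Replace every profile by its wall average at the reference station.

    ``reference_station`` is the height fraction measured from the
    clamped root (0 = root, 1 = tip).  The result carries ``k = 0`` in
    every profile and the label ``"homogeneous"``; Poisson ratios pass
    through unchanged.  Homogenizing an already homogeneous material is
    an exact identity.
    """
    x_from_tip = geometry.length * (1.0 - reference_station)
    ro, ri = geometry.radii_at(x_from_tip)
    if not ro > ri > 0:
        raise GeometryError(f"degenerate annulus at reference station: ri={ri}, ro={ro}")
    averaged = {
        name: GradedProfile(_annulus_average(p, ri, ro, weighting))
        for name, p in material.profiles.items()
    }
    return MaterialModel(
        **averaged,
        nu_axial=material.nu_axial,
        nu_transverse=material.nu_transverse,
        label="homogeneous",
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the wall-geometry calibration."""

    geometry: BeamGeometry
    reference_station: float
    achieved_gpa: float
    target_gpa: float
    residuals: dict = field(default_factory=dict)


def calibrate_geometry(
    material: MaterialModel,
    targets: MaterialModel | None = None,
    *,
    length: float = 10.0,
    taper_constant: float = 2.0,
    thickness_ratio: float = 0.18,
    reference_station: float = 0.0,
    search_radius_m: tuple = (1.0e-3, 0.3),
    rtol: float = 5.0e-3,
) -> CalibrationResult:
    """Size the wall annulus so the graded axial modulus averages to target.

    The published data pair each graded profile with a homogeneous value
    but print no radii, so the outer radius at the reference station is
    found by root-finding on

        area-average of E_axial over [R(1-c), R]  =  E_axial(homogeneous),

    with ``c`` the wall thickness-to-radius ratio.  Only the axial
    Young's modulus is used as the constraint; the residual mismatch of
    the other three moduli (a single annulus cannot match all four) is
    reported in :attr:`CalibrationResult.residuals` as relative errors.
    """
    from scipy.optimize import brentq

    if material.is_homogeneous:
        raise DomainError("calibration requires a graded material")
    if targets is None:
        targets = table1_homogeneous()
    target = targets.E_axial.amplitude_gpa
    if not target > 0:
        raise DomainError(f"target modulus must be positive, got {target}")

    profile = material.E_axial
    c = thickness_ratio

    if profile.is_constant:
        # k = 0: the average equals A for any annulus; any geometry passes.
        if not math.isclose(profile.amplitude_gpa, target, rel_tol=rtol):
            raise CalibrationError(
                f"constant profile {profile.amplitude_gpa} GPa cannot average "
                f"to {target} GPa"
            )
        r_ref = 0.03  # default culm scale
    else:
        def mismatch(R):
            return _annulus_average(profile, R * (1 - c), R) - target

        lo, hi = search_radius_m
        f_lo, f_hi = mismatch(lo), mismatch(hi)
        if f_lo * f_hi > 0:
            raise CalibrationError(
                "no calibration root in the searched radius interval "
                f"[{lo}, {hi}] m: mismatch({lo})={f_lo:+.3f} GPa, "
                f"mismatch({hi})={f_hi:+.3f} GPa (target {target} GPa)"
            )
        r_ref = brentq(mismatch, lo, hi, xtol=1e-10)

    # Tip radius follows from the cubic taper law: R ~ I^(1/4) at
    # constant thickness ratio, and the reference station sits at
    # height fraction `reference_station` from the root.
    x_ref_from_tip = length * (1.0 - reference_station)
    bracket = 1.0 + (taper_constant - 1.0) * x_ref_from_tip / length
    r_tip = r_ref / bracket**0.75
    geometry = BeamGeometry(
        length=length,
        outer_radius_tip=r_tip,
        wall_thickness_tip=c * r_tip,
        taper_constant=taper_constant,
    )

    ri, ro = r_ref * (1 - c), r_ref
    achieved = _annulus_average(profile, ri, ro)
    if abs(achieved - target) > rtol * target:
        raise CalibrationError(
            f"calibration residual {achieved:.4f} vs {target} GPa exceeds {rtol:.1%}"
        )
    residuals = {}
    for name, p in material.profiles.items():
        if name == "E_axial":
            continue
        tgt = targets.profiles[name].amplitude_gpa
        residuals[name] = float((_annulus_average(p, ri, ro) - tgt) / tgt)
    return CalibrationResult(
        geometry=geometry,
        reference_station=reference_station,
        achieved_gpa=achieved,
        target_gpa=target,
        residuals=residuals,
    )


def with_noise(profile: GradedProfile, rng, cv: float) -> GradedProfile:
    """Multiplicative log-normal perturbation of ``A`` and ``k``."""
    if cv < 0:
        raise DomainError(f"coefficient of variation must be >= 0, got {cv}")
    if cv == 0:
        return profile
    sigma = math.sqrt(math.log(1.0 + cv**2))
    factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=2))
    return replace(
        profile,
        amplitude_gpa=profile.amplitude_gpa * factors[0],
        rate_per_mm=profile.rate_per_mm * factors[1],
    )
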