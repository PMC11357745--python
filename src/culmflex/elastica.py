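"""Large-deflection bending of the tapered, variable-stiffness cantilever.

The culm is a vertical cantilever, clamped at the root, loaded by
horizontal wind drag and/or a horizontal tip force.  Its shape obeys the
elastica equation

    d(theta)/ds = M(s) / (E(s) I(s)),

with ``s`` the arc length from the root, ``theta`` the rotation from the
vertical, and ``M`` the bending moment computed **in the deformed
configuration**: every load element is split into a component normal to
the deformed axis (which bends) and a tangential component (which does
not), so a culm that aligns with the wind sheds effective load.

Two independent solvers are provided and cross-checked:

``solve_pseudolinear``
    The equivalent-linear-system method: the nonlinear Cartesian
    equation ``y'' [1+y'^2]^(-3/2) = M/(EI)`` is rewritten as a *linear*
    beam ``y'' = Me' / (E0 I0)`` whose modified moment diagram

        Me  = M / (f g),          Me' = Me [1 + y'^2]^(3/2)

    absorbs the stiffness variation ``f(x) g(x) = E(x)I(x)/(E0 I0)`` and
    the curvature correction.  ``Me'`` is rebuilt from the current shape
    and the linear system re-solved by double integration with
    clamped-end constants until the tip deflection and the tip
    shortening ``Delta`` stop changing.

``solve_shooting``
    Direct arc-length integration of the rotation equation from the
    clamped root, with the moment field updated self-consistently on the
    deformed shape (outer fixed-point iteration).

Both evaluate section properties at the *material* arc-length station
(the taper bracket of the inertia law takes the running arc length as
argument); the linearized ``(L - Delta)`` stretched-coordinate variant
is available as ``taper_mapping="stretched"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_simpson, cumulative_trapezoid

from .exceptions import (
    ComparisonError,
    ConvergenceError,
    DomainError,
    RegimeError,
)
from .loading import LoadCase
from .materials import BeamGeometry, MaterialModel, section_properties

__all__ = [
    "StiffnessField",
    "PseudoLinearSystem",
    "ElasticaSolution",
    "bending_moment",
    "solve_pseudolinear",
    "solve_shooting",
    "compare_deflection",
]

_THETA_CAP = 0.9995 * np.pi / 2.0


@dataclass(frozen=True)
class StiffnessField:
    """Reference rigidity and the dimensionless modifiers ``f``, ``g``.

    ``E0`` and ``I0`` are taken at the free end; ``f`` and ``g`` map the
    station measured from the free end (m) to the modulus and inertia
    modifiers, with ``f = g = 1`` everywhere reproducing the uniform
    beam.
    """

    E0: float
    I0: float
    f: Callable = None
    g: Callable = None

    def __post_init__(self):
        if not (self.E0 > 0 and self.I0 > 0):
            raise DomainError("reference rigidity must be positive")
        if self.f is None:
            object.__setattr__(self, "f", lambda x: np.ones_like(np.asarray(x, float)))
        if self.g is None:
            object.__setattr__(self, "g", lambda x: np.ones_like(np.asarray(x, float)))

    def EI(self, x_from_tip):
        """Flexural rigidity E(x) I(x) (N m^2) at stations from the free end."""
        fx = np.asarray(self.f(x_from_tip), float)
        gx = np.asarray(self.g(x_from_tip), float)
        if np.any(fx <= 0) or np.any(gx <= 0):
            raise DomainError("stiffness modifiers must stay positive")
        return self.E0 * self.I0 * fx * gx

    @classmethod
    def from_material(
        cls, material: MaterialModel, geometry: BeamGeometry, n_samples: int = 256
    ) -> "StiffnessField":
        """Build ``f`` and ``g`` from a wall material and taper geometry.

        ``g`` is the cubic taper law; ``f`` is the section-effective
        modulus ``EI_eff / I`` normalized by its free-end value, sampled
        and linearly interpolated (the radial wall law applies at every
        station, so ``f`` varies along the length for a graded wall).
        """
        xs = np.linspace(0.0, geometry.length, n_samples)
        e_eff = np.array(
            [section_properties(material, geometry, x).E_effective for x in xs]
        )
        e0 = e_eff[0]
        i0 = geometry.I0
        if material.E_axial.is_constant:
            f = lambda x: np.ones_like(np.asarray(x, float))  # noqa: E731
        else:
            f = lambda x: np.interp(np.asarray(x, float), xs, e_eff / e0)  # noqa: E731
        g = lambda x: geometry.taper_factor(np.clip(x, 0.0, geometry.length)) ** 3  # noqa: E731
        return cls(E0=e0, I0=i0, f=f, g=g)


@dataclass(frozen=True)
class PseudoLinearSystem:
    """Equivalent moment diagrams and integration constants.

    ``Me`` is the stiffness-scaled diagram ``M/(f g)``; ``Me_prime``
    additionally carries the ``[1+y'^2]^(3/2)`` curvature correction and
    is the diagram the linear equivalent beam is actually integrated
    with.  Both are exported for inspection.
    """

    x: np.ndarray
    Me: np.ndarray
    Me_prime: np.ndarray
    C1: float = 0.0
    C2: float = 0.0


@dataclass
class ElasticaSolution:
    """Converged deformed state of the cantilever.

    All arrays are sampled on the material arc-length grid ``stations``
    measured from the clamped root; ``x`` is the vertical (undeformed
    axis) coordinate and ``y`` the horizontal deflection of each
    material point.
    """

    stations: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    curvature: np.ndarray
    M: np.ndarray
    V: np.ndarray
    delta: float
    tip_deflection: float
    iterations: int
    residual: float
    solver: str = ""
    pseudo_linear: PseudoLinearSystem | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def arc_length(self) -> float:
        """Recovered arc length of the deformed centerline (m)."""
        ds = np.sqrt(np.gradient(self.x, self.stations) ** 2 + np.gradient(self.y, self.stations) ** 2)
        return float(np.trapezoid(ds, self.stations))

    def to_frame(self):
        """Solution table (s, x, y, theta, curvature, M) for export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "s_m": self.stations,
                "x_m": self.x,
                "y_m": self.y,
                "theta_rad": self.theta,
                "curvature_per_m": self.curvature,
                "moment_Nm": self.M,
                "shear_N": self.V,
            }
        )


def _cumint(f, t):
    return cumulative_trapezoid(f, t, initial=0.0)


def _revint(f, t):
    """``int_t^end f dt`` on the grid (reverse cumulative integral)."""
    F = _cumint(f, t)
    return F[-1] - F


def _moment_and_shear(s, theta, X, Y, q_arc, P, resolution="normal"):
    """Deformed-configuration moment and transverse shear at every station.

    Loads are horizontal.  With ``resolution="normal"`` only the
    component normal to the deformed axis is retained (``q cos(theta)``,
    and ``P cos(theta_tip)`` at the tip): the moment of a normal force
    ``qn ds'`` applied at ``(X', Y')`` about the station at ``(X, Y)``
    has lever ``(X'-X) cos(theta') + (Y'-Y) sin(theta')``, and the
    transverse shear is the outboard normal resultant projected onto the
    local normal, ``int qn cos(theta' - theta) ds'``.  With
    ``resolution="full"`` the exact dead-load moment is used: a
    horizontal force about a station has the vertical offset ``X' - X``
    as lever.
    """
    ct, st = np.cos(theta), np.sin(theta)
    if resolution == "full":
        fy = _revint(q_arc, s) + P
        # identity: int_s^L q (X'-X) ds' + P (X_L - X) == int_s^L cos(theta) Fy ds
        M = _revint(ct * fy, s)
        V = ct * fy
        return M, V
    qn = q_arc * ct
    i1 = _revint(qn * ct, s)
    i2 = _revint(qn * ct * X, s)
    i3 = _revint(qn * st, s)
    i4 = _revint(qn * st * Y, s)
    M = (i2 - X * i1) + (i4 - Y * i3)
    V = ct * i1 + st * i3
    if P != 0.0:
        thl = theta[-1]
        pn = P * np.cos(thl)
        M = M + pn * ((X[-1] - X) * np.cos(thl) + (Y[-1] - Y) * np.sin(thl))
        V = V + pn * (ct * np.cos(thl) + st * np.sin(thl))
    return M, V


def bending_moment(solution: ElasticaSolution, loads: LoadCase, geometry: BeamGeometry, s):
    """Moment (N m) of all loads outboard of station(s) ``s``, deformed arms.

    Recomputes the moment field on the solution's deformed shape and
    interpolates; at the tip the moment vanishes (nothing outboard).
    """
    grid = solution.stations
    ro, _ = geometry.radii_at(geometry.length - grid)
    q = loads.distributed(grid, 2.0 * ro)
    M, _ = _moment_and_shear(grid, solution.theta, solution.x, solution.y, q, loads.tip_load, loads.resolution)
    return np.interp(np.asarray(s, float), grid, M)


def _material_stations(geometry: BeamGeometry, s):
    """Distance from the free end of material points at arc length ``s``."""
    return np.clip(geometry.length - s, 0.0, geometry.length)


def _check_regime(theta, solver):
    if np.max(theta) >= 0.999 * np.pi / 2:
        raise RegimeError(
            f"{solver}: rotation reached pi/2 (fold-over); the elastica "
            "model does not continue past alignment with the load"
        )


def solve_shooting(
    stiffness: StiffnessField,
    loads: LoadCase,
    geometry: BeamGeometry,
    n_stations: int = 401,
    rtol: float = 1.0e-6,
    max_iter: int = 200,
    relaxation: float = 0.5,
) -> ElasticaSolution:
    """Arc-length fixed-point solver (independent oracle).

    Integrates ``dtheta/ds = M/(EI)``, ``dx/ds = cos(theta)``,
    ``dy/ds = sin(theta)`` from the clamped root, rebuilding ``M`` on the
    deformed shape each outer iteration with under-relaxation on
    ``theta``.  Converges when the tip deflection changes by less than
    ``rtol`` between iterations.
    """
    L = geometry.length
    s = np.linspace(0.0, L, n_stations)
    EI = stiffness.EI(_material_stations(geometry, s))
    ro, _ = geometry.radii_at(_material_stations(geometry, s))
    q = loads.distributed(s, 2.0 * ro)

    theta = np.zeros_like(s)
    tip_prev = np.inf
    omega = relaxation
    trace = []
    residual = np.inf
    cap_hits = 0
    for it in range(1, max_iter + 1):
        X = _cumint(np.cos(theta), s)
        Y = _cumint(np.sin(theta), s)
        M, V = _moment_and_shear(s, theta, X, Y, q, loads.tip_load, loads.resolution)
        theta_raw = _cumint(M / EI, s)
        cap_hits = cap_hits + 1 if theta_raw.max() >= _THETA_CAP else 0
        if cap_hits >= 10:  # rotation persistently pinned at pi/2
            raise RegimeError(
                "shooting solver: rotation reached pi/2 (fold-over); the "
                "elastica model does not continue past alignment with the load"
            )
        theta_new = np.minimum(theta_raw, _THETA_CAP)
        theta = theta + omega * (theta_new - theta)
        tip = _cumint(np.sin(theta), s)[-1]
        trace.append(tip)
        residual = abs(tip - tip_prev) / max(abs(tip), 1e-12)
        if it > 2 and residual < rtol:
            break
        if it > 6 and abs(trace[-1] - trace[-2]) > abs(trace[-2] - trace[-3]):
            omega = max(0.1, 0.7 * omega)  # damp oscillatory fixed points
        tip_prev = tip
    else:
        raise ConvergenceError(
            f"shooting solver: no convergence in {max_iter} iterations "
            f"(last relative change {residual:.2e})",
            trace=trace,
        )
    _check_regime(theta, "shooting solver")

    X = _cumint(np.cos(theta), s)
    Y = _cumint(np.sin(theta), s)
    M, V = _moment_and_shear(s, theta, X, Y, q, loads.tip_load, loads.resolution)
    return ElasticaSolution(
        stations=s,
        x=X,
        y=Y,
        theta=theta,
        curvature=M / EI,
        M=M,
        V=V,
        delta=L - X[-1],
        tip_deflection=float(Y[-1]),
        iterations=it,
        residual=float(residual),
        solver="shooting",
        diagnostics={"relaxation_final": omega},
    )


def solve_pseudolinear(
    stiffness: StiffnessField,
    loads: LoadCase,
    geometry: BeamGeometry,
    n_stations: int = 401,
    rtol: float = 1.0e-6,
    max_iter: int = 200,
    relaxation: float = 0.5,
    taper_mapping: str = "arclength",
) -> ElasticaSolution:
    """Equivalent-linear-system solver in Cartesian coordinates.

    Fixed-point scheme: (i) assume ``Delta`` and a shape ``y(x)`` on the
    horizontal extent ``[0, L - Delta]``; (ii) build the equivalent
    moment diagrams ``Me = M/(f g)`` and ``Me' = Me [1+y'^2]^(3/2)`` in
    the deformed configuration; (iii) solve the linear system
    ``y'' = Me'/(E0 I0)`` by double (composite Simpson) integration with
    clamped-end constants; (iv) update ``Delta`` from arc-length
    conservation.  Shape and ``Delta`` updates are under-relaxed.

    ``taper_mapping`` selects the argument handed to ``f`` and ``g``:
    ``"arclength"`` (default) uses the running material arc length,
    ``"stretched"`` the linearized ``x L/(L - Delta)`` stretch of the
    deformed coordinate.
    """
    if taper_mapping not in ("arclength", "stretched"):
        raise DomainError(f"unknown taper_mapping {taper_mapping!r}")
    from scipy.optimize import brentq

    L = geometry.length
    xi = np.linspace(0.0, 1.0, n_stations)  # root -> tip, normalized
    Xt = L  # horizontal extent L - Delta
    y = np.zeros_like(xi)
    E0I0 = stiffness.E0 * stiffness.I0
    omega = relaxation
    tip_prev = np.inf
    trace = []
    residual = np.inf
    Me = Me_prime = None
    for it in range(1, max_iter + 1):
        x = xi * Xt
        yp = np.gradient(y, x)
        theta = np.minimum(np.arctan(yp), _THETA_CAP)
        sec = np.sqrt(1.0 + yp**2)
        s_of_x = _cumint(sec, x)  # material arc length of each node
        s_of_x = np.minimum(s_of_x, L)
        if taper_mapping == "arclength":
            station_tip = _material_stations(geometry, s_of_x)
        else:
            station_tip = np.clip(L - x * L / Xt, 0.0, L)
        fg = stiffness.EI(station_tip) / E0I0
        ro, _ = geometry.radii_at(station_tip)
        q = loads.distributed(s_of_x, 2.0 * ro)  # per unit arc length
        # Moment in the deformed configuration, integrated along the arc.
        M, V = _moment_and_shear(s_of_x, theta, x, y, q, loads.tip_load, loads.resolution)
        Me = M / fg
        Me_prime = Me * sec**3
        slope = cumulative_simpson(Me_prime / E0I0, x=x, initial=0.0)
        y_new = cumulative_simpson(slope, x=x, initial=0.0)  # y(0)=y'(0)=0
        y = y + omega * (y_new - y)
        # Delta update: stretch the horizontal extent until the arc
        # length of the relaxed shape equals the beam length.
        y_xi = np.gradient(y, xi)

        def arc_minus_L(xt):
            return np.trapezoid(np.sqrt(xt**2 + y_xi**2), xi) - L

        if arc_minus_L(L) < 0.0:  # numerically straight
            Xt_new = L
        elif arc_minus_L(1e-6 * L) > 0.0:
            raise RegimeError(
                "pseudo-linear solver: deflection exceeds the beam length "
                "(fold-over); use the shooting solver or reduce the load"
            )
        else:
            Xt_new = brentq(arc_minus_L, 1e-6 * L, L)
        Xt = Xt + omega * (Xt_new - Xt)
        tip = y[-1]
        trace.append(tip)
        residual = abs(tip - tip_prev) / max(abs(tip), 1e-12)
        if it > 2 and residual < rtol:
            break
        if it > 6 and abs(trace[-1] - trace[-2]) > abs(trace[-2] - trace[-3]):
            omega = max(0.1, 0.7 * omega)
        tip_prev = tip
    else:
        raise ConvergenceError(
            f"pseudo-linear solver: no convergence in {max_iter} iterations "
            f"(last relative change {residual:.2e})",
            trace=trace,
        )
    x = xi * Xt
    yp = np.gradient(y, x)
    theta = np.arctan(yp)
    if np.max(theta) >= 0.999 * np.pi / 2:
        raise RegimeError(
            "pseudo-linear solver: rotation reached pi/2; use the shooting "
            "solver or reduce the load"
        )
    sec = np.sqrt(1.0 + yp**2)
    s_of_x = np.minimum(_cumint(sec, x), L)
    station_tip = (
        _material_stations(geometry, s_of_x)
        if taper_mapping == "arclength"
        else np.clip(L - x * L / Xt, 0.0, L)
    )
    EI = stiffness.EI(station_tip)
    ro, _ = geometry.radii_at(station_tip)
    q = loads.distributed(s_of_x, 2.0 * ro)
    M, V = _moment_and_shear(s_of_x, theta, x, y, q, loads.tip_load, loads.resolution)
    # Resample onto a uniform arc-length grid for a comparable solution.
    s_grid = np.linspace(0.0, L, n_stations)
    interp = lambda arr: np.interp(s_grid, s_of_x, arr)  # noqa: E731
    return ElasticaSolution(
        stations=s_grid,
        x=interp(x),
        y=interp(y),
        theta=interp(theta),
        curvature=interp(M / EI),
        M=interp(M),
        V=interp(V),
        delta=L - Xt,
        tip_deflection=float(y[-1]),
        iterations=it,
        residual=float(residual),
        solver="pseudolinear",
        pseudo_linear=PseudoLinearSystem(x=x, Me=Me, Me_prime=Me_prime, C1=0.0, C2=0.0),
        diagnostics={"relaxation_final": omega, "taper_mapping": taper_mapping},
    )


def compare_deflection(graded: ElasticaSolution, homogeneous: ElasticaSolution) -> float:
    """Percent tip-deflection increase of the graded culm over its twin."""
    if homogeneous.tip_deflection == 0.0:
        raise ComparisonError("homogeneous tip deflection is zero; comparison undefined")
    return 100.0 * (graded.tip_deflection - homogeneous.tip_deflection) / homogeneous.tip_deflection
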