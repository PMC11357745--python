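"""Crack-transformation stability analysis of the culm wall.

Bamboo pairs its stiffness gradation with an *opposite* toughness
gradation: the inner wall is several times tougher than the outer one
(a factor of about 5 is the printed anchor), and through-thickness
toughness exceeds the interlaminar one.  A bending-induced surface crack
therefore tends to convert into an interlaminar (axial) crack instead of
severing the stem — a small loss of section instead of catastrophic
failure.

The analysis is deliberately parameterized: measured toughness data are
not reprinted here, so toughness enters as through-wall profiles with a
configurable inner/outer ratio.  The driving quantity is the far-field
(remote) bending stress at the crack mouth from the stress module; the
critical remote stress uses the standard edge-crack relation

    sigma_crit = K / (Y * sqrt(pi * a)),

and the wind speed at which propagation begins is found by bisection on
the wind reference speed ``v0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import DomainError
from .materials import MaterialModel, BeamGeometry

__all__ = [
    "ToughnessProfile",
    "CrackScenario",
    "ThresholdResult",
    "critical_remote_stress",
    "crack_path",
    "threshold_wind_speed",
    "default_toughness",
]

MPA_SQRT_M = 1.0e6


def _as_profile(value) -> Callable:
    if callable(value):
        return value
    return lambda w: float(value) * np.ones_like(np.asarray(w, dtype=float))


@dataclass(frozen=True)
class ToughnessProfile:
    """Through-wall fracture toughness (MPa sqrt(m)) profiles.

    ``K_through`` resists through-thickness propagation, ``K_interlaminar``
    resists splitting along the fibre direction.  Each maps the
    normalized wall position (0 = inner surface, 1 = outer surface) to a
    toughness; scalars are accepted for constant profiles.
    """

    K_through: Callable | float
    K_interlaminar: Callable | float

    def __post_init__(self):
        object.__setattr__(self, "K_through", _as_profile(self.K_through))
        object.__setattr__(self, "K_interlaminar", _as_profile(self.K_interlaminar))
        w = np.linspace(0.0, 1.0, 33)
        if np.any(np.asarray(self.K_through(w)) < 0) or np.any(
            np.asarray(self.K_interlaminar(w)) < 0
        ):
            raise DomainError("toughness profiles must be non-negative")

    @property
    def inner_outer_ratio(self) -> float:
        """Diagnostic ``K_through(inner) / K_through(outer)``."""
        k_in = float(np.asarray(self.K_through(0.0)))
        k_out = float(np.asarray(self.K_through(1.0)))
        return k_in / k_out if k_out > 0 else math.inf


def default_toughness(inner_outer_ratio: float = 5.0) -> ToughnessProfile:
    """Exponential toughness pair anchored at the outer surface.

    The inner surface is ``inner_outer_ratio`` times tougher (default 5);
    through-thickness toughness is five times the interlaminar one at
    every wall position, reflecting that splitting between laminae is the
    easy path.  Outer-surface anchors (1.75 and 0.35 MPa sqrt(m)) are
    chosen at the scale of woody-grass fracture measurements.
    """
    if inner_outer_ratio <= 0:
        raise DomainError("inner/outer toughness ratio must be positive")
    lam = math.log(inner_outer_ratio)
    k_through = lambda w: 1.75 * np.exp(lam * (1.0 - np.asarray(w, dtype=float)))  # noqa: E731
    k_inter = lambda w: 0.35 * np.exp(lam * (1.0 - np.asarray(w, dtype=float)))  # noqa: E731
    return ToughnessProfile(K_through=k_through, K_interlaminar=k_inter)


@dataclass(frozen=True)
class CrackScenario:
    """A surface crack of depth ``a`` starting from one wall surface."""

    surface: str = "inner"
    depth: float = 1.0e-3
    geometry_factor: float = 1.12

    def __post_init__(self):
        if self.surface not in ("inner", "outer"):
            raise DomainError(f"surface must be 'inner' or 'outer', got {self.surface!r}")
        if self.depth < 0:
            raise DomainError(f"crack depth must be non-negative, got {self.depth}")
        if not self.geometry_factor > 0:
            raise DomainError("geometry factor Y must be positive")

    def validate_against(self, geometry: BeamGeometry):
        if self.depth >= geometry.wall_thickness_tip:
            raise DomainError(
                f"crack depth {self.depth} m exceeds the wall thickness "
                f"{geometry.wall_thickness_tip} m"
            )

    @property
    def wall_position(self) -> float:
        return 0.0 if self.surface == "inner" else 1.0


def critical_remote_stress(
    crack: CrackScenario, toughness: ToughnessProfile, mode: str = "interlaminar"
) -> float:
    """Far-field stress (Pa) required to propagate the surface crack.

    Uses ``sigma = K / (Y sqrt(pi a))`` with the toughness of the
    requested propagation mode evaluated at the crack's wall surface.
    A vanishing crack cannot concentrate stress: returns ``inf`` with a
    warning.
    """
    if crack.depth == 0.0:
        warnings.warn("vanishing crack depth: critical stress is unbounded", stacklevel=2)
        return math.inf
    prof = toughness.K_interlaminar if mode == "interlaminar" else toughness.K_through
    K = float(np.asarray(prof(crack.wall_position))) * MPA_SQRT_M
    return K / (crack.geometry_factor * math.sqrt(math.pi * crack.depth))


def crack_path(
    crack: CrackScenario,
    toughness: ToughnessProfile,
    path_ratio_threshold: float = 1.0,
) -> str:
    """Which way the crack continues: ``"through"`` or ``"interlaminar"``.

    The crack turns into the interlaminar plane when the interlaminar
    toughness at its tip is strictly lower than ``path_ratio_threshold``
    times the through-thickness toughness; at equality the through path
    is kept (tie-break).
    """
    w = crack.wall_position
    k_int = float(np.asarray(toughness.K_interlaminar(w)))
    k_thr = float(np.asarray(toughness.K_through(w)))
    if k_thr == 0.0:
        return "through"
    return "interlaminar" if k_int / k_thr < path_ratio_threshold else "through"


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the wind-speed threshold search."""

    wind_speed: float
    censored: bool
    critical_stress: float
    crack: CrackScenario
    evaluations: int = 0

    def __float__(self):
        return self.wind_speed


def threshold_wind_speed(
    solve_stress_max: Callable[[float], float],
    crack: CrackScenario,
    toughness: ToughnessProfile,
    v_max: float = 50.0,
    tol: float = 0.1,
    mode: str = "interlaminar",
) -> ThresholdResult:
    """Wind reference speed ``v0`` at which the crack begins to propagate.

    ``solve_stress_max(v0)`` must return the maximum over stations of the
    magnitude of the axial surface stress at the crack's wall surface for
    the given wind reference speed; it is assumed monotone over the
    bracket.  Bisection refines ``v0`` to ``tol`` (m/s).  If even
    ``v_max`` cannot reach the critical stress the result is censored at
    ``v_max`` ("no failure below v_max").
    """
    sigma_c = critical_remote_stress(crack, toughness, mode=mode)
    if sigma_c == 0.0:
        return ThresholdResult(0.0, False, sigma_c, crack)
    if not math.isfinite(sigma_c):
        return ThresholdResult(v_max, True, sigma_c, crack)
    evals = 0

    def excess(v0):
        nonlocal evals
        evals += 1
        return solve_stress_max(v0) - sigma_c

    hi = excess(v_max)
    if hi < 0.0:
        return ThresholdResult(v_max, True, sigma_c, crack, evals)
    lo_v, hi_v = 0.0, v_max
    while hi_v - lo_v > tol:
        mid = 0.5 * (lo_v + hi_v)
        if excess(mid) >= 0.0:
            hi_v = mid
        else:
            lo_v = mid
    return ThresholdResult(0.5 * (lo_v + hi_v), False, sigma_c, crack, evals)
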