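"""End-to-end orchestration: calibrate -> solve -> stress -> compare -> threshold.

``run_comparison`` executes the full stage chain on a graded/homogeneous
scenario pair and returns a :class:`RunReport`; with an output directory
it also writes the resolved configuration echo, per-case solution and
stress tables (CSV), the report (JSON) and the comparison plots, so that
every reported number is recomputable from the archived configuration.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .delamination import (
    CrackScenario,
    ThresholdResult,
    ToughnessProfile,
    default_toughness,
    threshold_wind_speed,
)
from .exceptions import ConvergenceError, RegimeError
from .elastica import (
    ElasticaSolution,
    StiffnessField,
    compare_deflection,
    solve_pseudolinear,
    solve_shooting,
)
from .scenarios import Scenario, make_paper_scenarios
from .stress import StressField, compare_stress, peak_stress_profile, stress_field

log = logging.getLogger(__name__)

__all__ = ["RunReport", "run_comparison", "solve_scenario", "wind_threshold"]

REPORT_SCHEMA_VERSION = 1


def _solver(name: str):
    return {"pseudolinear": solve_pseudolinear, "shooting": solve_shooting}[name]


def solve_scenario(
    scenario: Scenario, solver: str = "pseudolinear", n_stations: int = 401, **kwargs
) -> ElasticaSolution:
    """Solve one scenario with the named solver."""
    stiffness = StiffnessField.from_material(scenario.material, scenario.geometry)
    return _solver(solver)(
        stiffness, scenario.loads, scenario.geometry, n_stations=n_stations, **kwargs
    )


def scenario_stress(
    scenario: Scenario, solution: ElasticaSolution, n_wall: int = 81
) -> StressField:
    return stress_field(solution, scenario.material, scenario.geometry, n_wall=n_wall)


def wind_threshold(
    scenario: Scenario,
    crack: CrackScenario | None = None,
    toughness: ToughnessProfile | None = None,
    solver: str = "pseudolinear",
    n_stations: int = 301,
    v_max: float = 50.0,
    tol: float = 0.1,
) -> ThresholdResult:
    """Wind speed v0 at which the scenario's surface crack starts moving.

    Re-solves the full bending + stress chain at every bisection step
    with the scenario's wind profile rescaled to the trial ``v0``.
    """
    from dataclasses import replace

    crack = crack if crack is not None else CrackScenario()
    toughness = toughness if toughness is not None else default_toughness()
    crack.validate_against(scenario.geometry)
    stiffness = StiffnessField.from_material(scenario.material, scenario.geometry)
    solve = _solver(solver)

    def stress_max(v0: float) -> float:
        if v0 <= 0.0:
            return 0.0
        wind = replace(scenario.loads.wind, v0=v0)
        loads = replace(scenario.loads, wind=wind)
        try:
            sol = solve(stiffness, loads, scenario.geometry, n_stations=n_stations)
        except (RegimeError, ConvergenceError):
            # Past fold-over the curvature (and hence the surface stress)
            # diverges, so any finite critical stress is exceeded.
            return math.inf
        fld = stress_field(sol, scenario.material, scenario.geometry, n_wall=41)
        return float(np.max(np.abs(fld.surface(crack.surface))))

    return threshold_wind_speed(stress_max, crack, toughness, v_max=v_max, tol=tol)


@dataclass
class RunReport:
    """Full provenance record of one graded-vs-homogeneous comparison."""

    schema_version: int
    package_version: str
    config: dict
    tip_deflection_m: dict
    tip_shortening_m: dict
    deflection_increase_percent: float
    stress_comparison: dict
    max_shear_position: dict
    wind_thresholds: dict
    solver_diagnostics: dict
    artifacts: list = field(default_factory=list)
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=_jsonable, indent=2, **kwargs)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_comparison(
    pair: tuple[Scenario, Scenario] | None = None,
    *,
    solver: str = "pseudolinear",
    n_stations: int = 401,
    crack: CrackScenario | None = None,
    toughness: ToughnessProfile | None = None,
    thresholds: bool = True,
    out_dir: str | Path | None = None,
    plots: bool = False,
) -> RunReport:
    """Execute the full stage chain on a scenario pair.

    Deterministic for a fixed configuration.  Stage failures propagate
    with the stage name attached.
    """
    if pair is None:
        pair = make_paper_scenarios()
    graded_sc, hom_sc = pair
    stage = "solve"
    timings = {}
    try:
        t0 = time.perf_counter()
        sol_g = solve_scenario(graded_sc, solver, n_stations)
        sol_h = solve_scenario(hom_sc, solver, n_stations)
        timings["solve_s"] = time.perf_counter() - t0

        stage = "stress"
        t0 = time.perf_counter()
        fld_g = scenario_stress(graded_sc, sol_g)
        fld_h = scenario_stress(hom_sc, sol_h)
        timings["stress_s"] = time.perf_counter() - t0

        stage = "compare"
        incr = compare_deflection(sol_g, sol_h)
        cmp_stress = compare_stress(fld_g, fld_h)

        thresholds_report = {}
        if thresholds:
            stage = "delamination"
            t0 = time.perf_counter()
            crack = crack if crack is not None else CrackScenario()
            toughness = toughness if toughness is not None else default_toughness()
            for label, sc in (("graded", graded_sc), ("homogeneous", hom_sc)):
                res = wind_threshold(sc, crack, toughness, solver=solver)
                thresholds_report[label] = {
                    "wind_speed_m_s": res.wind_speed,
                    "censored": res.censored,
                    "critical_stress_Pa": res.critical_stress,
                    "crack_surface": crack.surface,
                    "crack_depth_m": crack.depth,
                }
            timings["delamination_s"] = time.perf_counter() - t0
    except Exception as exc:
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc

    loc_out_g, _, _ = peak_stress_profile(fld_g, "outer")
    loc_out_h, _, _ = peak_stress_profile(fld_h, "outer")
    report = RunReport(
        schema_version=REPORT_SCHEMA_VERSION,
        package_version=__version__,
        config={
            "graded": graded_sc.to_dict(),
            "homogeneous": hom_sc.to_dict(),
            "solver": solver,
            "n_stations": n_stations,
        },
        tip_deflection_m={"graded": sol_g.tip_deflection, "homogeneous": sol_h.tip_deflection},
        tip_shortening_m={"graded": sol_g.delta, "homogeneous": sol_h.delta},
        deflection_increase_percent=incr,
        stress_comparison={
            "outer_peak_ratio": cmp_stress["outer"]["peak_ratio"],
            "inner_peak_reduction_percent": cmp_stress["inner"]["reduction_percent"],
            "outer_peak_location_graded": loc_out_g,
            "outer_peak_location_homogeneous": loc_out_h,
            "detail": {k: cmp_stress[k] for k in ("inner", "outer")},
        },
        max_shear_position={
            "graded_root": float(fld_g.neutral_surface_position[0]),
            "homogeneous_root": float(fld_h.neutral_surface_position[0]),
        },
        wind_thresholds=thresholds_report,
        solver_diagnostics={
            "graded": {"iterations": sol_g.iterations, "residual": sol_g.residual},
            "homogeneous": {"iterations": sol_h.iterations, "residual": sol_h.residual},
            "timings": timings,
        },
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    if out_dir is not None:
        report.artifacts = _write_artifacts(
            Path(out_dir), report, (graded_sc, sol_g, fld_g), (hom_sc, sol_h, fld_h), plots
        )
        (Path(out_dir) / "report.json").write_text(report.to_json())
    return report


def _write_artifacts(out, report, graded_bundle, hom_bundle, plots):
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    echo = out / "config_resolved.json"
    echo.write_text(json.dumps(report.config, default=_jsonable, indent=2))
    artifacts.append(echo.name)
    for sc, sol, fld in (graded_bundle, hom_bundle):
        p = out / f"solution_{sc.label}.csv"
        sol.to_frame().to_csv(p, index=False)
        artifacts.append(p.name)
        p = out / f"stress_{sc.label}.csv"
        fld.to_frame().to_csv(p, index=False)
        artifacts.append(p.name)
    if plots:
        artifacts.extend(_render_plots(out, graded_bundle, hom_bundle))
    artifacts.append("report.json")
    return artifacts


def _render_plots(out, graded_bundle, hom_bundle):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    (sc_g, sol_g, fld_g), (sc_h, sol_h, fld_h) = graded_bundle, hom_bundle
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    ax = axes[0, 0]
    for sol, lab in ((sol_h, "homogeneous"), (sol_g, "graded")):
        ax.plot(sol.stations / sol.stations[-1], sol.y, label=lab)
    ax.set_xlabel("s/L from root")
    ax.set_ylabel("deflection y (m)")
    ax.legend()
    for ax, surf, title in (
        (axes[0, 1], "outer", "outer-surface axial stress"),
        (axes[1, 0], "inner", "inner-surface axial stress"),
    ):
        for fld, lab in ((fld_h, "homogeneous"), (fld_g, "graded")):
            ax.plot(fld.stations, fld.surface(surf) / 1e6, label=lab)
        ax.set_xlabel("x/L from root")
        ax.set_ylabel("sigma_xx (MPa)")
        ax.set_title(title)
        ax.legend()
    ax = axes[1, 1]
    for fld, lab in ((fld_h, "homogeneous"), (fld_g, "graded")):
        ax.plot(fld.wall_positions, fld.tau[0] / 1e6, label=lab)
    ax.set_xlabel("wall position (0=inner A, 1=outer B)")
    ax.set_ylabel("tau at root (MPa)")
    ax.legend()
    fig.tight_layout()
    p = out / "comparison.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return [p.name]
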