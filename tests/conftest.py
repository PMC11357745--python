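"""Shared fixtures: the published scenario pair and a regression suite.

Solving the elastica is cheap but not free, so converged solutions of
the published wind scenario are cached at session scope.
"""

from __future__ import annotations

import numpy as np
import pytest

from culmflex import (
    BeamGeometry,
    LoadCase,
    StiffnessField,
    make_paper_scenarios,
    solve_pseudolinear,
    solve_shooting,
    stress_field,
    table1_graded,
    table1_homogeneous,
)


@pytest.fixture(scope="session")
def paper_pair():
    return make_paper_scenarios()


@pytest.fixture(scope="session")
def paper_solutions(paper_pair):
    """Converged pseudo-linear solutions of both published cases."""
    from culmflex.pipeline import solve_scenario

    graded, hom = paper_pair
    return {
        "graded": solve_scenario(graded, "pseudolinear"),
        "homogeneous": solve_scenario(hom, "pseudolinear"),
    }


@pytest.fixture(scope="session")
def paper_stress(paper_pair, paper_solutions):
    graded, hom = paper_pair
    return {
        "graded": stress_field(paper_solutions["graded"], graded.material, graded.geometry),
        "homogeneous": stress_field(
            paper_solutions["homogeneous"], hom.material, hom.geometry
        ),
    }


@pytest.fixture(scope="session")
def uniform_geometry():
    """Untapered hollow beam for closed-form checks."""
    return BeamGeometry(
        length=10.0, outer_radius_tip=0.03, wall_thickness_tip=0.005, taper_constant=1.0
    )


def regression_configs():
    """Uniform/tapered x homogeneous/graded x 3 tip-load levels.

    Load levels are scaled per geometry so the largest stays below the
    fold-over regime (rotations around 50 degrees).
    """
    graded, hom = make_paper_scenarios()
    configs = []
    for geo_label in ("uniform", "tapered"):
        for mat_label, material in (("homogeneous", hom.material), ("graded", graded.material)):
            geometry = (
                graded.geometry
                if geo_label == "tapered"
                else BeamGeometry(
                    length=graded.geometry.length,
                    outer_radius_tip=graded.geometry.outer_radius_tip,
                    wall_thickness_tip=graded.geometry.wall_thickness_tip,
                    taper_constant=1.0,
                )
            )
            stiffness = StiffnessField.from_material(material, geometry)
            # reference rigidity at mid-span sets the load scale
            ei_mid = stiffness.EI(geometry.length / 2.0)
            for level, beta in (("low", 0.05), ("mid", 0.4), ("high", 1.0)):
                P = beta * ei_mid / geometry.length**2
                configs.append(
                    pytest.param(
                        geometry,
                        material,
                        LoadCase(tip_load=float(P), resolution="full"),
                        id=f"{geo_label}-{mat_label}-{level}",
                    )
                )
    return configs


def solve_both(geometry, material, loads, n_stations=401):
    stiffness = StiffnessField.from_material(material, geometry)
    sol_p = solve_pseudolinear(stiffness, loads, geometry, n_stations=n_stations)
    sol_s = solve_shooting(stiffness, loads, geometry, n_stations=n_stations)
    return sol_p, sol_s
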