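"""Elastica solvers: closed-form limits, cross-solver agreement, invariants."""

import numpy as np
import pytest

from culmflex import (
    BeamGeometry,
    ComparisonError,
    LoadCase,
    RegimeError,
    StiffnessField,
    WindProfile,
    bending_moment,
    compare_deflection,
    solve_pseudolinear,
    solve_shooting,
)
from conftest import regression_configs, solve_both

SOLVERS = [solve_pseudolinear, solve_shooting]


@pytest.fixture(scope="module")
def uniform(uniform_geometry):
    return uniform_geometry, StiffnessField(E0=10e9, I0=uniform_geometry.I0)


class TestLimits:
    @pytest.mark.parametrize("solver", SOLVERS, ids=lambda f: f.__name__)
    def test_zero_load_stays_straight(self, uniform, solver):
        geo, stiff = uniform
        sol = solver(stiff, LoadCase(tip_load=0.0), geo)
        assert np.allclose(sol.y, 0.0)
        assert sol.delta == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("solver", SOLVERS, ids=lambda f: f.__name__)
    def test_small_load_matches_linear_cantilever(self, uniform, solver):
        geo, stiff = uniform
        EI = stiff.E0 * stiff.I0
        P = 3e-3 * EI / geo.length**3 * 3.0  # delta/L = 3e-3
        sol = solver(stiff, LoadCase(tip_load=P), geo)
        assert sol.tip_deflection == pytest.approx(
            P * geo.length**3 / (3.0 * EI), rel=1e-2
        )

    def test_small_load_tapered_matches_quadrature_solution(self, paper_pair):
        """Linear tapered beam against unit-load-theorem quadrature."""
        _, hom = paper_pair
        stiff = StiffnessField.from_material(hom.material, hom.geometry)
        L = hom.geometry.length
        ei_root = float(stiff.EI(L))
        P = 1e-3 * 3.0 * ei_root / L**3
        sol = solve_shooting(stiff, LoadCase(tip_load=P), hom.geometry)
        # oracle: delta = int M(x) m(x) / EI dx with M = P*(L-x), m = (L-x)
        x = np.linspace(0.0, L, 20001)
        ei = stiff.EI(L - x)
        oracle = np.trapezoid(P * (L - x) ** 2 / ei, x)
        assert sol.tip_deflection == pytest.approx(oracle, rel=1e-2)

    def test_classical_elastica_benchmark(self, uniform):
        """Uniform beam at PL^2/EI = 1 against an independent BVP oracle."""
        from scipy.integrate import solve_ivp
        from scipy.optimize import brentq

        geo, stiff = uniform
        EI = stiff.E0 * stiff.I0
        L = geo.length
        P = EI / L**2
        loads = LoadCase(tip_load=P, resolution="full")

        def shoot(kappa0):
            rhs = lambda s, y: [y[1], -(P / EI) * np.cos(y[0])]  # noqa: E731
            res = solve_ivp(rhs, [0, L], [0.0, kappa0], rtol=1e-10, atol=1e-12,
                            dense_output=True)
            return res

        kappa0 = brentq(lambda k: shoot(k).y[1, -1], 1e-8, 2.0 * P * L / EI)
        ss = np.linspace(0.0, L, 4001)
        theta = shoot(kappa0).sol(ss)[0]
        oracle = np.trapezoid(np.sin(theta), ss) / L
        assert oracle == pytest.approx(0.302, abs=2e-3)  # classical value
        for solver in SOLVERS:
            sol = solver(stiff, loads, geo, n_stations=801)
            assert sol.tip_deflection / L == pytest.approx(oracle, rel=5e-3)


class TestBendingMoment:
    def test_straight_beam_tip_load_levers(self, uniform):
        geo, stiff = uniform
        tiny = 1e-8 * stiff.E0 * stiff.I0 / geo.length**2
        sol = solve_shooting(stiff, LoadCase(tip_load=tiny), geo)
        loads = LoadCase(tip_load=100.0)
        assert bending_moment(sol, loads, geo, 0.0) == pytest.approx(1000.0, rel=1e-6)
        assert bending_moment(sol, loads, geo, 5.0) == pytest.approx(500.0, rel=1e-6)
        assert bending_moment(sol, loads, geo, 10.0) == pytest.approx(0.0, abs=1e-6)


class TestCrossSolver:
    @pytest.mark.parametrize("geometry,material,loads", regression_configs())
    def test_solvers_agree_on_regression_suite(self, geometry, material, loads):
        """Pseudo-linear and shooting solutions agree within 0.5 %."""
        sol_p, sol_s = solve_both(geometry, material, loads)
        assert sol_p.tip_deflection == pytest.approx(sol_s.tip_deflection, rel=5e-3)
        scale = max(abs(sol_s.tip_deflection), 1e-9)
        y_s = np.interp(sol_p.stations, sol_s.stations, sol_s.y)
        assert np.max(np.abs(sol_p.y - y_s)) / scale < 5e-3


class TestInvariants:
    @pytest.mark.parametrize("solver", SOLVERS, ids=lambda f: f.__name__)
    def test_arc_length_conserved(self, paper_pair, solver):
        graded, _ = paper_pair
        stiff = StiffnessField.from_material(graded.material, graded.geometry)
        sol = solver(stiff, graded.loads, graded.geometry)
        L = graded.geometry.length
        assert abs(sol.arc_length - L) < 1e-4 * L

    def test_curvature_equals_moment_over_rigidity(self, paper_pair, paper_solutions):
        graded, _ = paper_pair
        stiff = StiffnessField.from_material(graded.material, graded.geometry)
        sol = solve_shooting(stiff, graded.loads, graded.geometry)
        ei = stiff.EI(graded.geometry.length - sol.stations)
        assert np.allclose(sol.curvature * ei, sol.M, rtol=1e-9, atol=1e-12)
        # the resampled pseudo-linear solution satisfies it to grid accuracy
        sol_p = paper_solutions["graded"]
        assert np.allclose(sol_p.curvature * ei, sol_p.M, rtol=1e-3, atol=1e-3)

    def test_deflection_monotone_in_load(self, uniform):
        geo, stiff = uniform
        EI = stiff.E0 * stiff.I0
        tips = [
            solve_shooting(stiff, LoadCase(tip_load=b * EI / geo.length**2), geo).tip_deflection
            for b in (0.2, 0.5, 1.0, 1.5)
        ]
        assert np.all(np.diff(tips) > 0)

    def test_deflection_monotone_decreasing_in_taper(self, paper_pair):
        _, hom = paper_pair
        tips = []
        for n in (1.0, 1.5, 2.0, 3.0):
            geo = BeamGeometry(
                length=hom.geometry.length,
                outer_radius_tip=hom.geometry.outer_radius_tip,
                wall_thickness_tip=hom.geometry.wall_thickness_tip,
                taper_constant=n,
            )
            stiff = StiffnessField.from_material(hom.material, geo)
            loads = LoadCase(tip_load=5.0, resolution="full")
            tips.append(solve_shooting(stiff, loads, geo).tip_deflection)
        assert np.all(np.diff(tips) < 0)

    def test_grid_convergence_on_paper_scenario(self, paper_pair):
        graded, _ = paper_pair
        stiff = StiffnessField.from_material(graded.material, graded.geometry)
        tips = [
            solve_shooting(stiff, graded.loads, graded.geometry, n_stations=n).tip_deflection
            for n in (401, 801)
        ]
        assert abs(tips[1] - tips[0]) / abs(tips[1]) < 1e-3

    def test_fold_over_raises_regime_error(self, uniform):
        geo, stiff = uniform
        EI = stiff.E0 * stiff.I0
        with pytest.raises(RegimeError):
            solve_shooting(
                stiff,
                LoadCase(tip_load=60.0 * EI / geo.length**2, resolution="full"),
                geo,
                max_iter=400,
            )


class TestCompareDeflection:
    def test_identical_solutions_give_zero(self, paper_solutions):
        sol = paper_solutions["graded"]
        assert compare_deflection(sol, sol) == 0.0

    def test_stiffer_beam_deflects_less(self, uniform):
        geo, stiff = uniform
        stiffer = StiffnessField(E0=2.0 * stiff.E0, I0=stiff.I0)
        loads = LoadCase(tip_load=stiff.E0 * stiff.I0 / geo.length**2 * 0.5)
        soft = solve_shooting(stiff, loads, geo)
        hard = solve_shooting(stiffer, loads, geo)
        assert compare_deflection(hard, soft) < 0.0

    def test_zero_reference_deflection_rejected(self, uniform):
        geo, stiff = uniform
        zero = solve_shooting(stiff, LoadCase(tip_load=0.0), geo)
        with pytest.raises(ComparisonError):
            compare_deflection(zero, zero)
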