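"""Through-wall stress recovery: classical limits, equilibrium, peaks."""

import numpy as np
import pytest

from culmflex import (
    ComparisonError,
    DegenerateInputError,
    compare_stress,
    peak_stress_profile,
    stress_field,
)
def annulus_sigma_moment(field_obj, geometry, material, station_idx, L):
    """Quadrature oracle: int sigma z dA over the full annulus.

    With sigma = E(r) kappa z and z = r sin(phi), the azimuthal integral
    of sin^2 is pi, so the moment is pi * kappa * int E r^3 dr.
    """
    s = field_obj.stations[station_idx] * L
    ro, ri = geometry.radii_at(L - s)
    r = np.linspace(ri, ro, 4001)
    E = material.E_axial.pa_at_radius(r, ri)
    return np.pi * np.trapezoid(E * r**3, r)


class TestAxialStress:
    def test_zero_moment_station_is_stress_free(self, paper_stress):
        # the free end carries no moment
        assert np.allclose(paper_stress["graded"].sigma_xx[-1], 0.0, atol=1e-6)

    def test_homogeneous_wall_reduces_to_Mz_over_I(self, paper_pair):
        from culmflex import StiffnessField, solve_shooting

        _, hom = paper_pair
        stiff = StiffnessField.from_material(hom.material, hom.geometry)
        sol = solve_shooting(stiff, hom.loads, hom.geometry)
        fld = stress_field(sol, hom.material, hom.geometry)
        L = hom.geometry.length
        for i in (0, 100, 250):
            s = fld.stations[i] * L
            ro, ri = hom.geometry.radii_at(L - s)
            I = np.pi / 4 * (ro**4 - ri**4)
            r = ri + fld.wall_positions * (ro - ri)
            expected = sol.M[i] * r / I
            assert np.allclose(fld.sigma_xx[i], expected, rtol=1e-8)

    def test_graded_wall_matches_pointwise_oracle(self, paper_pair, paper_solutions):
        """sigma(r) = E(r) kappa r on a dense independent radial grid."""
        graded, _ = paper_pair
        sol = paper_solutions["graded"]
        fld = stress_field(sol, graded.material, graded.geometry, n_wall=1001)
        L = graded.geometry.length
        i = 40
        s = fld.stations[i] * L
        ro, ri = graded.geometry.radii_at(L - s)
        r = np.linspace(ri, ro, 1001)
        oracle = graded.material.E_axial.pa_at_radius(r, ri) * sol.curvature[i] * r
        assert np.allclose(fld.sigma_xx[i], oracle, rtol=1e-10)

    def test_section_moment_equilibrium(self, paper_pair, paper_solutions, paper_stress):
        """int sigma z dA recovers the bending moment at every station."""
        for label in ("graded", "homogeneous"):
            sc = paper_pair[0] if label == "graded" else paper_pair[1]
            sol, fld = paper_solutions[label], paper_stress[label]
            L = sc.geometry.length
            for i in range(0, len(fld.stations) - 1, 40):
                ei_quad = annulus_sigma_moment(fld, sc.geometry, sc.material, i, L)
                moment = ei_quad * sol.curvature[i]
                if abs(sol.M[i]) > 1e-9:
                    assert moment == pytest.approx(sol.M[i], rel=1e-4)

    def test_net_axial_force_vanishes_by_symmetry(self, paper_pair, paper_solutions):
        """int sigma dA = 0: odd integrand over the symmetric annulus."""
        graded, _ = paper_pair
        sol = paper_solutions["graded"]
        L = graded.geometry.length
        i = 0
        ro, ri = graded.geometry.radii_at(L)
        r = np.linspace(ri, ro, 801)
        phi = np.linspace(0.0, 2 * np.pi, 1601)
        E = graded.material.E_axial.pa_at_radius(r, ri)
        z = np.outer(np.sin(phi), r)
        sigma = E[None, :] * sol.curvature[i] * z
        net = np.trapezoid(np.trapezoid(sigma * r[None, :], r, axis=1), phi)
        scale = np.trapezoid(np.trapezoid(np.abs(sigma) * r[None, :], r, axis=1), phi)
        assert abs(net) / scale < 1e-6

    def test_doubling_moduli_leaves_stress_unchanged(self, paper_pair, paper_solutions):
        """Section stress is statically determined given M: scale invariance."""
        import dataclasses

        graded, _ = paper_pair
        sol = paper_solutions["graded"]
        doubled_profiles = {
            k: dataclasses.replace(p, amplitude_gpa=2.0 * p.amplitude_gpa)
            for k, p in graded.material.profiles.items()
        }
        doubled = dataclasses.replace(graded.material, **doubled_profiles)
        base = stress_field(sol, graded.material, graded.geometry)
        # same moment requires half the curvature when E doubles
        half = dataclasses.replace(sol)
        half.curvature = 0.5 * sol.curvature
        scaled = stress_field(half, doubled, graded.geometry)
        assert np.allclose(scaled.sigma_xx, base.sigma_xx, rtol=1e-12)


class TestShearStress:
    def test_free_surfaces_carry_no_shear(self, paper_stress):
        for fld in paper_stress.values():
            assert np.all(fld.tau[:, 0] == 0.0)
            assert np.all(fld.tau[:, -1] == 0.0)

    def test_homogeneous_max_at_mid_wall(self, paper_stress):
        fld = paper_stress["homogeneous"]
        assert np.allclose(fld.neutral_surface_position, 0.5, atol=1e-9)
        # and the tau profile peaks there
        i = 0
        assert abs(fld.wall_positions[np.argmax(fld.tau[i])] - 0.5) < 0.02

    def test_graded_max_shifted_outward(self, paper_stress):
        g = paper_stress["graded"].neutral_surface_position
        h = paper_stress["homogeneous"].neutral_surface_position
        assert np.all(g > h)

    def test_shear_integrates_to_section_shear_force(self, paper_pair, paper_solutions, paper_stress):
        graded, _ = paper_pair
        sol = paper_solutions["graded"]
        fld = stress_field(sol, graded.material, graded.geometry, n_wall=401)
        L = graded.geometry.length
        for i in range(0, len(fld.stations) - 1, 50):
            s = fld.stations[i] * L
            ro, ri = graded.geometry.radii_at(L - s)
            area = np.pi * (ro**2 - ri**2)
            b_eff = area / (ro - ri)
            r = ri + fld.wall_positions * (ro - ri)
            total = np.trapezoid(fld.tau[i] * b_eff, r)
            if abs(sol.V[i]) > 1e-9:
                assert total == pytest.approx(sol.V[i], rel=1e-4)

    def test_zero_shear_force_gives_zero_shear_stress(self, paper_pair, paper_solutions):
        import dataclasses

        graded, _ = paper_pair
        sol = dataclasses.replace(paper_solutions["graded"])
        sol.V = np.zeros_like(sol.V)
        fld = stress_field(sol, graded.material, graded.geometry)
        assert np.all(fld.tau == 0.0)

    def test_homogeneous_strip_peak_is_classical_parabola(self, paper_pair, paper_solutions):
        """tau_max = 1.5 V / A for the homogeneous rectangular strip."""
        _, hom = paper_pair
        sol = paper_solutions["homogeneous"]
        fld = stress_field(sol, hom.material, hom.geometry, n_wall=401)
        L = hom.geometry.length
        i = 0
        ro, ri = hom.geometry.radii_at(L)
        area = np.pi * (ro**2 - ri**2)
        assert np.max(fld.tau[i]) == pytest.approx(1.5 * sol.V[i] / area, rel=1e-4)


class TestPeaksAndComparison:
    def test_single_nonzero_station_is_the_peak(self, paper_stress):
        import dataclasses

        fld = dataclasses.replace(paper_stress["graded"])
        sigma = np.zeros_like(fld.sigma_xx)
        sigma[17, :] = 1.0e6
        fld.sigma_xx = sigma
        loc, val, curve = peak_stress_profile(fld, "outer")
        assert loc == pytest.approx(fld.stations[17])
        assert val == pytest.approx(1.0e6)
        assert curve.shape == fld.stations.shape

    def test_all_zero_field_rejected(self, paper_stress):
        import dataclasses

        fld = dataclasses.replace(paper_stress["graded"])
        fld.sigma_xx = np.zeros_like(fld.sigma_xx)
        with pytest.raises(DegenerateInputError):
            peak_stress_profile(fld, "outer")

    def test_identical_fields_compare_trivially(self, paper_stress):
        fld = paper_stress["graded"]
        rep = compare_stress(fld, fld)
        assert rep["outer"]["peak_ratio"] == pytest.approx(1.0)
        assert rep["inner"]["reduction_percent"] == pytest.approx(0.0)

    def test_halved_field_reports_fifty_percent(self, paper_stress):
        import dataclasses

        fld = paper_stress["graded"]
        half = dataclasses.replace(fld)
        half.sigma_xx = 0.5 * fld.sigma_xx
        rep = compare_stress(half, fld)
        assert rep["outer"]["peak_ratio"] == pytest.approx(0.5)
        assert rep["inner"]["reduction_percent"] == pytest.approx(50.0)

    def test_mismatched_grids_rejected(self, paper_pair, paper_solutions, paper_stress):
        graded, _ = paper_pair
        coarse = stress_field(
            paper_solutions["graded"], graded.material, graded.geometry, n_wall=11
        )
        with pytest.raises(ComparisonError):
            compare_stress(coarse, paper_stress["graded"])
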