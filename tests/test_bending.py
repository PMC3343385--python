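"""Rod-inclusion bending energetics: identities, closed forms, equilibria."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barmech.bending import (
    MembraneMaterial,
    MembranePatch,
    ParametricShape,
    RodProtein,
    curvature_seen,
    equilibrium_tube_radius,
    kT,
    membrane_energy,
    optimal_orientation,
    packing_scenarios,
    protein_energy,
    protein_energy_orient,
    rigid_tube_c1,
)

NM = 1e-9
KT = kT(298.0)

curvatures = st.floats(min_value=-0.3, max_value=0.3)
angles = st.floats(min_value=0.0, max_value=math.pi)


class TestCurvatureSeen:
    def test_cylinder_extremes(self):
        patch = MembranePatch(0.1 / NM, 0.0)
        assert curvature_seen(patch, 0.0) == pytest.approx(0.1 / NM)
        assert curvature_seen(patch, math.pi / 2) == pytest.approx(0.0, abs=1e-12 / NM)

    def test_sphere_is_isotropic(self):
        patch = MembranePatch(0.05 / NM, 0.05 / NM)
        for w in np.linspace(0, math.pi, 7):
            assert curvature_seen(patch, w) == pytest.approx(0.05 / NM)

    @given(curvatures, curvatures, angles)
    @settings(derandomize=True, max_examples=100)
    def test_range_bound(self, c1, c2, omega):
        patch = MembranePatch(c1 / NM, c2 / NM)
        c = curvature_seen(patch, omega)
        H, D = patch.mean_curvature, patch.curvature_deviator
        assert H - D - 1e-9 <= c <= H + D + 1e-9


class TestProteinEnergy:
    def test_zero_at_intrinsic_curvature(self):
        p = RodProtein(0.05 / NM, 10 * KT * NM, 20 * NM)
        assert protein_energy(p, 0.05 / NM) == 0.0

    def test_quadratic_scaling(self):
        p = RodProtein(0.0, 10 * KT * NM, 20 * NM)
        assert protein_energy(p, 0.1 / NM) == pytest.approx(
            4 * protein_energy(p, 0.05 / NM), rel=1e-12
        )

    def test_arithmetic_example(self):
        # K_p = 10 kT nm, L0 = 20 nm, C - C_p = 0.05/nm -> 0.25 kT
        p = RodProtein(0.0, 10 * KT * NM, 20 * NM)
        assert protein_energy(p, 0.05 / NM) / KT == pytest.approx(0.25, rel=1e-12)

    @given(curvatures, curvatures, curvatures, angles)
    @settings(derandomize=True, max_examples=200)
    def test_composition_identity(self, c1, c2, cp, omega):
        """The oriented energy equals the explicit H, D, omega formula."""
        patch = MembranePatch(c1 / NM, c2 / NM)
        p = RodProtein(cp / NM, 10 * KT * NM, 20 * NM, omega)
        H, D = patch.mean_curvature, patch.curvature_deviator
        explicit = (
            0.5 * p.flexural_rigidity * p.length
            * (H - p.intrinsic_curvature + D * math.cos(2 * p.orientation)) ** 2
        )
        assert protein_energy_orient(p, patch) == pytest.approx(explicit, rel=1e-12, abs=1e-30)

    def test_isotropic_patch_orientation_independent(self):
        patch = MembranePatch(0.05 / NM, 0.05 / NM)
        energies = {
            protein_energy_orient(RodProtein(0.02 / NM, 10 * KT * NM, 20 * NM, w), patch)
            for w in np.linspace(0, math.pi, 5)
        }
        assert max(energies) == pytest.approx(min(energies), rel=1e-12)


def grid_search_orientation(protein, patch, n=2000):
    """Independent minimizer over omega in [0, pi/2]: coarse grid scan
    followed by local refinement around the bracketing interval."""
    omegas = np.linspace(0.0, math.pi / 2, n)
    energies = [protein_energy(protein, curvature_seen(patch, w)) for w in omegas]
    i = int(np.argmin(energies))
    lo, hi = omegas[max(i - 1, 0)], omegas[min(i + 1, n - 1)]
    fine = np.linspace(lo, hi, 2000)
    fine_e = [protein_energy(protein, curvature_seen(patch, w)) for w in fine]
    j = int(np.argmin(fine_e))
    return fine[j], fine_e[j]


class TestOptimalOrientation:
    def test_interior_minimum(self):
        p = RodProtein(0.05 / NM, 10 * KT * NM, 20 * NM)
        patch = MembranePatch(0.1 / NM, 0.0)
        w, e = optimal_orientation(p, patch)
        assert w == pytest.approx(math.pi / 4)
        assert e == 0.0

    def test_boundary_cases(self):
        patch = MembranePatch(0.1 / NM, 0.0)
        w_hi, e_hi = optimal_orientation(RodProtein(0.2 / NM, 10 * KT * NM, 20 * NM), patch)
        assert w_hi == 0.0 and e_hi > 0
        w_lo, e_lo = optimal_orientation(RodProtein(-0.05 / NM, 10 * KT * NM, 20 * NM), patch)
        assert w_lo == pytest.approx(math.pi / 2) and e_lo > 0

    def test_sphere_convention(self):
        patch = MembranePatch(0.05 / NM, 0.05 / NM)
        p = RodProtein(0.02 / NM, 10 * KT * NM, 20 * NM)
        w, e = optimal_orientation(p, patch)
        assert w == 0.0
        assert e == pytest.approx(protein_energy(p, 0.05 / NM), rel=1e-12)

    @given(curvatures, curvatures, curvatures)
    @settings(derandomize=True, max_examples=100)
    def test_agrees_with_grid_search(self, c1, c2, cp):
        p = RodProtein(cp / NM, 10 * KT * NM, 20 * NM)
        patch = MembranePatch(c1 / NM, c2 / NM)
        _, e_opt = optimal_orientation(p, patch)
        _, e_grid = grid_search_orientation(p, patch)
        D = patch.curvature_deviator
        tol = 1e-10 * p.flexural_rigidity * p.length * D**2 + 1e-12 * KT
        assert e_opt <= e_grid + 1e-30
        assert e_grid - e_opt <= tol


class TestRigidTube:
    def test_aligned_rod(self):
        assert rigid_tube_c1(0.05 / NM, 0.0) == 0.05 / NM

    def test_diagonal_orientation_doubles_curvature(self):
        cp = 0.05 / NM
        assert rigid_tube_c1(cp, math.pi / 4) == 2 * cp

    def test_sixty_degrees_quadruples(self):
        cp = 0.05 / NM
        assert rigid_tube_c1(cp, math.pi / 3) == pytest.approx(4 * cp, rel=1e-12)

    def test_axis_aligned_rod_unconstrained(self):
        with pytest.raises(ValueError, match="axis"):
            rigid_tube_c1(0.05 / NM, math.pi / 2)

    @given(st.floats(min_value=0.0, max_value=1.2), st.floats(min_value=0.001, max_value=0.3))
    @settings(derandomize=True, max_examples=100)
    def test_inverts_projection_relation(self, omega, cp):
        """C1 = Cp/cos^2(omega) is the exact inverse of Cp = C1 cos^2(omega)."""
        c1 = rigid_tube_c1(cp / NM, omega)
        assert c1 * 0.5 * (1 + math.cos(2 * omega)) == pytest.approx(cp / NM, rel=1e-12)
        assert c1 >= cp / NM


class TestMembraneEnergy:
    material = MembraneMaterial(
        local_bending_constant=20 * KT,
        gaussian_constant=-10 * KT,
        effective_deviator=1e9,
    )

    def test_sphere_bending_is_radius_independent(self):
        for R in (5 * NM, 50 * NM, 500 * NM):
            e = membrane_energy(ParametricShape("sphere", R), self.material)
            assert e["bending"] == pytest.approx(8 * math.pi * 20 * KT, rel=1e-12)
            assert e["gaussian"] == pytest.approx(4 * math.pi * -10 * KT, rel=1e-12)

    def test_cylinder_closed_forms(self):
        R, L = 10 * NM, 100 * NM
        shape = ParametricShape("cylinder", R, L)
        e = membrane_energy(shape, self.material)
        assert e["bending"] == pytest.approx(math.pi * 20 * KT * L / R, rel=1e-12)
        assert e["gaussian"] == 0.0
        m = self.material
        arg = m.deviator_coupling_area * m.effective_deviator / (2 * R)
        expected_dev = -2 * m.lipid_area_density * m.kT * math.log(2 * math.cosh(arg)) * shape.area
        assert e["deviatoric"] == pytest.approx(expected_dev, rel=1e-12)

    def test_no_deviator_gives_area_entropy(self):
        m = MembraneMaterial(local_bending_constant=20 * KT, effective_deviator=0.0)
        for shape in (ParametricShape("cylinder", 10 * NM, 50 * NM), ParametricShape("sphere", 10 * NM)):
            e = membrane_energy(shape, m)
            assert e["deviatoric"] == pytest.approx(
                -2 * m.lipid_area_density * m.kT * math.log(2) * shape.area, rel=1e-12
            )


class TestEquilibriumTubeRadius:
    def test_membrane_only_minimum_matches_grid_scan(self):
        """With a strong lipid deviator the bare membrane has a finite R*."""
        mat = MembraneMaterial(local_bending_constant=20 * KT, effective_deviator=6e9)
        rod = RodProtein(0.05 / NM, 10 * KT * NM, 20 * NM)
        r_star = equilibrium_tube_radius(mat, rod, 0.0)
        radii = np.geomspace(0.5 * NM, 1e-6, 20_000)
        from barmech.bending import _tube_energy_per_area

        f = [_tube_energy_per_area(r, mat, rod, 0.0) for r in radii]
        r_grid = radii[int(np.argmin(f))]
        assert r_star == pytest.approx(r_grid, rel=1e-3)

    def test_no_minimum_signalled(self):
        """No proteins and no deviator: bending alone prefers the flat limit."""
        mat = MembraneMaterial(local_bending_constant=20 * KT, effective_deviator=0.0)
        rod = RodProtein(0.05 / NM, 10 * KT * NM, 20 * NM)
        with pytest.raises(ValueError, match="minimum") as exc:
            equilibrium_tube_radius(mat, rod, 0.0)
        assert hasattr(exc.value, "energy_curve")

    def test_strong_coupling_caps_radius_at_intrinsic_curvature(self):
        """Stiff, dense rods keep the tube (almost) as curved as C_p: the
        residual flattening scales inversely with coverage and rigidity."""
        mat = MembraneMaterial(local_bending_constant=20 * KT, effective_deviator=0.0)
        rod = RodProtein(0.05 / NM, 1e4 * KT * NM, 20 * NM)
        r_star = equilibrium_tube_radius(mat, rod, 1e17)
        assert 1.0 / r_star >= 0.05 / NM * 0.99

    def test_monotone_in_intrinsic_curvature(self):
        """Larger intrinsic curvature -> smaller (never larger) tube."""
        mat = MembraneMaterial(local_bending_constant=20 * KT, effective_deviator=0.0)
        radii = []
        for cp in (0.02, 0.03, 0.05, 0.08, 0.12):
            rod = RodProtein(cp / NM, 1000 * KT * NM, 20 * NM)
            radii.append(equilibrium_tube_radius(mat, rod, 1e16))
        assert all(r2 <= r1 * (1 + 1e-9) for r1, r2 in zip(radii, radii[1:]))


class TestPackingScenarios:
    material = MembraneMaterial(local_bending_constant=20 * KT, effective_deviator=0.0)
    rod = RodProtein(0.05 / NM, 100 * KT * NM, 20 * NM)

    def test_no_interaction_low_density_prefers_dispersed(self):
        df = packing_scenarios(self.rod, self.material, 0.0, [1e13])
        assert df["minimal"].iloc[0] == "dispersed"

    def test_strong_attraction_high_density_prefers_spiral(self):
        df = packing_scenarios(self.rod, self.material, -20 * KT, [1e16])
        assert df["minimal"].iloc[0] == "spiral"
        # independent comparison of the three closed-form totals
        row = df.iloc[0]
        assert row["E_spiral_J"] == min(row["E_dispersed_J"], row["E_ring_J"], row["E_spiral_J"])

    def test_spiral_tube_curvature_is_doubled(self):
        assert rigid_tube_c1(self.rod.intrinsic_curvature, math.pi / 4) == pytest.approx(
            2 * self.rod.intrinsic_curvature
        )

    def test_density_sweep_shape(self):
        df = packing_scenarios(self.rod, self.material, -5 * KT, [0.0, 1e13, 1e16])
        assert list(df.columns[:1]) == ["density_per_m2"]
        assert len(df) == 3
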