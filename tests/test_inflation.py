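"""Kinematics, equilibrium, and material comparison of the inflation solver."""

import numpy as np
import pytest

import plaquemech as pm
from plaquemech.inflation import equilibrium_residual

from .oracles import cylinder_quadrature_dense, fd_penalty_solver

# single-layer instance used by the oracle cross-checks: plaque annulus
# [Ri, Rp] = [1.0, 1.5] mm inflated from lumen radius 1.0 to 1.3 mm
SINGLE_LAYER_GEOM = pm.VesselGeometry(
    sfa_diameter=3.2,
    healthy_lumen_diameter=3.0,
    initial_stenosis_pct=100.0 / 3.0,
    final_stenosis_pct=40.0 / 3.0,
)


class TestGeometry:
    def test_reference_radii_healthy_lumen_convention(self, default_geometry):
        ri, rp, ro = pm.reference_configuration(default_geometry)
        assert ri == pytest.approx(0.2975)
        assert rp == pytest.approx(2.975)
        assert ro == pytest.approx(3.435)

    def test_reference_radii_sfa_convention(self):
        geom = pm.VesselGeometry(stenosis_reference="sfa")
        ri, _, _ = pm.reference_configuration(geom)
        assert ri == pytest.approx(0.3435)

    def test_printed_wall_thickness_option(self):
        geom = pm.VesselGeometry(honour_wall_thickness=True)
        _, rp, ro = pm.reference_configuration(geom)
        assert ro == pytest.approx(rp + 0.48)

    def test_invalid_orderings_rejected(self):
        with pytest.raises(ValueError):
            pm.VesselGeometry(healthy_lumen_diameter=7.0)  # lumen > sfa
        with pytest.raises(ValueError):
            pm.VesselGeometry(initial_stenosis_pct=10, final_stenosis_pct=90)
        with pytest.raises(ValueError):
            pm.VesselGeometry(stenosis_reference="bogus")


class TestDeformedRadiusMap:
    def test_identity_when_undisplaced(self):
        R = np.linspace(0.3, 3.4, 11)
        np.testing.assert_allclose(pm.deformed_radius_map(R, 0.3, 0.3), R)

    def test_reference_example(self):
        r = pm.deformed_radius_map(2.975, 0.2975, 2.6775)
        assert r == pytest.approx(3.9914, abs=2e-4)

    def test_area_conservation_identity(self):
        R = np.linspace(0.2975, 3.435, 1000)
        r = np.asarray(pm.deformed_radius_map(R, 0.2975, 2.6775))
        ref_area = R**2 - 0.2975**2
        def_area = r**2 - 2.6775**2
        np.testing.assert_allclose(def_area, ref_area, rtol=1e-12)

    def test_rejects_radius_inside_lumen(self):
        with pytest.raises(ValueError):
            pm.deformed_radius_map(0.1, 0.3, 1.0)


class TestHoopStressDifference:
    def test_zero_at_unit_stretch(self, femoral_heavy):
        assert pm.hoop_stress_difference(1.0, femoral_heavy) == 0.0

    def test_coincides_with_planar_shear_stress(self, femoral_heavy):
        """The plane-strain hoop state has the same invariant structure as
        planar shear, so the stress difference equals the planar-shear stress."""
        for lam in (1.1, 1.5, 2.0):
            assert pm.hoop_stress_difference(lam, femoral_heavy) == pytest.approx(
                pm.cauchy_stress_planar_shear(lam, femoral_heavy), rel=1e-12
            )
        assert pm.hoop_stress_difference(1.5, femoral_heavy) == pytest.approx(
            0.1190, abs=5e-5
        )

    def test_aortic_exceeds_femoral_by_orders_of_magnitude(
        self, femoral_heavy, aortic_calcified
    ):
        femoral = pm.hoop_stress_difference(1.5, femoral_heavy)
        aortic = pm.hoop_stress_difference(1.5, aortic_calcified)
        assert aortic / femoral > 100.0


class TestSolveRevascularisation:
    def test_noop_revascularisation_is_stress_free(self, femoral_heavy):
        geom = pm.VesselGeometry(initial_stenosis_pct=90, final_stenosis_pct=90)
        profile = pm.solve_revascularisation(
            geom, pm.MaterialAssignment(femoral_heavy, pm.DEFAULT_WALL)
        )
        for field in ("sigma_rr", "sigma_tt", "sigma_zz"):
            assert np.max(np.abs(getattr(profile, field))) <= 1e-10

    @pytest.mark.parametrize("group", ["heavily", "calcified_aortic"])
    def test_field_equation_checks(self, default_geometry, group):
        profile = pm.solve_revascularisation(
            default_geometry,
            pm.MaterialAssignment(pm.PLAQUE_MATERIALS[group], pm.DEFAULT_WALL),
            check_stability=False,
        )
        assert abs(profile.sigma_rr[-1]) <= 1e-8
        assert equilibrium_residual(profile) <= 1e-6 * np.max(np.abs(profile.sigma_tt))
        # sub-annulus area conservation
        ref_area = profile.reference_radius**2 - profile.reference_radius[0] ** 2
        def_area = profile.radius**2 - profile.radius[0] ** 2
        np.testing.assert_allclose(def_area[1:], ref_area[1:], rtol=1e-10, atol=1e-12)
        # principal ordering and incompressibility by construction
        np.testing.assert_array_equal(
            profile.sigma_max_principal,
            np.maximum(np.maximum(profile.sigma_rr, profile.sigma_tt), profile.sigma_zz),
        )

    def test_interface_continuity_of_radial_stress(self, default_geometry, femoral_heavy):
        profile = pm.solve_revascularisation(
            default_geometry, pm.MaterialAssignment(femoral_heavy, pm.DEFAULT_WALL)
        )
        k = np.searchsorted(profile.reference_radius, profile.interface_radius_reference)
        srr = profile.sigma_rr
        jump = abs(srr[k] - srr[k - 1]) + abs(srr[k + 1] - srr[k])
        scale = np.max(np.abs(srr))
        assert jump < 0.01 * scale  # continuous across the material interface

    def test_single_layer_matches_dense_quadrature(self, femoral_heavy):
        profile = pm.solve_revascularisation(
            SINGLE_LAYER_GEOM, pm.MaterialAssignment(femoral_heavy, wall=None)
        )
        r_o, srr_o, stt_o = cylinder_quadrature_dense(femoral_heavy, 1.0, 1.5, 1.3)
        stt = np.interp(r_o, profile.radius, profile.sigma_tt)
        srr = np.interp(r_o, profile.radius, profile.sigma_rr)
        scale = np.max(np.abs(stt_o))
        assert np.max(np.abs(stt - stt_o)) < 1e-3 * scale
        assert np.max(np.abs(srr - srr_o)) < 1e-3 * scale

    def test_grid_doubling_convergence(self, default_geometry, femoral_heavy):
        mats = pm.MaterialAssignment(femoral_heavy, pm.DEFAULT_WALL)
        coarse = pm.solve_revascularisation(default_geometry, mats, grid_size=4000)
        fine = pm.solve_revascularisation(default_geometry, mats, grid_size=8000)
        a = pm.stress_at_depth(coarse, 0.8)
        b = pm.stress_at_depth(fine, 0.8)
        assert a == pytest.approx(b, rel=1e-6)

    def test_unstable_material_warns_but_solves(self, default_geometry):
        softening = pm.YeohCoefficients(0.01, -10.0, 0.0, "softening")
        with pytest.warns(RuntimeWarning, match="softening"):
            profile = pm.solve_revascularisation(
                default_geometry, pm.MaterialAssignment(softening, pm.DEFAULT_WALL)
            )
        assert np.all(np.isfinite(profile.sigma_tt))

    def test_small_grid_rejected(self, default_geometry, femoral_heavy):
        with pytest.raises(ValueError):
            pm.solve_revascularisation(
                default_geometry,
                pm.MaterialAssignment(femoral_heavy, pm.DEFAULT_WALL),
                grid_size=50,
            )

    def test_monotone_loading_at_fixed_material_point(self, neo_hookean):
        """Opening the lumen further only raises the stress at a material point."""
        stresses = []
        for final_pct in (70, 50, 30, 10):
            geom = pm.VesselGeometry(final_stenosis_pct=final_pct)
            profile = pm.solve_revascularisation(
                geom, pm.MaterialAssignment(neo_hookean, neo_hookean)
            )
            # material point R = 2.0 mm tracked through each deformation
            r_q = float(
                pm.deformed_radius_map(2.0, profile.lumen_radius_initial,
                                       profile.lumen_radius_final)
            )
            stresses.append(np.interp(r_q, profile.radius, profile.sigma_max_principal))
        assert all(b >= a - 1e-12 for a, b in zip(stresses, stresses[1:]))


class TestFdPenaltyOracle:
    def test_hoop_stress_matches_independent_fd_solver(self, femoral_heavy):
        """Semi-analytic profile vs 500-node penalty-incompressibility solver."""
        profile = pm.solve_revascularisation(
            SINGLE_LAYER_GEOM, pm.MaterialAssignment(femoral_heavy, wall=None)
        )
        rm, stt_fd = fd_penalty_solver(femoral_heavy, 1.0, 1.5, 1.3, n_nodes=500)
        stt = np.interp(rm, profile.radius, profile.sigma_tt)
        scale = np.max(np.abs(stt))
        interior = rm > rm[0] + 0.1 * (rm[-1] - rm[0])  # skip the clamped-node layer
        assert np.max(np.abs(stt_fd[interior] - stt[interior])) < 0.01 * scale


@pytest.fixture(scope="module")
def profile(default_geometry, femoral_heavy):
    return pm.solve_revascularisation(
        default_geometry, pm.MaterialAssignment(femoral_heavy, pm.DEFAULT_WALL)
    )


class TestStressAtDepth:
    def test_zero_depth_is_lumen_node(self, profile):
        assert pm.stress_at_depth(profile, 0.0) == pytest.approx(
            profile.sigma_max_principal[0]
        )

    def test_grid_node_returns_stored_value(self, profile):
        k = len(profile.radius) // 2
        depth = profile.depth_from_lumen[k]
        assert pm.stress_at_depth(profile, depth) == pytest.approx(
            profile.sigma_max_principal[k]
        )

    def test_hoop_stretch_at_reporting_depth(self, profile):
        lam = pm.stress_at_depth(profile, 0.8, field="lam_theta")
        assert lam == pytest.approx(1.553, abs=1e-3)

    def test_reference_convention_maps_forward(self, profile):
        # reference depth 0.8: R = Ri + 0.8, mapped through the deformation
        r_expected = float(
            pm.deformed_radius_map(
                profile.reference_radius[0] + 0.8,
                profile.lumen_radius_initial,
                profile.lumen_radius_final,
            )
        )
        value = pm.stress_at_depth(profile, 0.8, convention="reference")
        direct = np.interp(r_expected, profile.radius, profile.sigma_max_principal)
        assert value == pytest.approx(direct)

    def test_depth_outside_vessel_rejected(self, profile):
        with pytest.raises(ValueError):
            pm.stress_at_depth(profile, 50.0)


class TestCompareMaterials:
    def test_identical_materials_ratio_one(self, default_geometry, femoral_heavy):
        comp = pm.compare_materials(
            default_geometry,
            {"a": femoral_heavy, "b": femoral_heavy},
            pm.DEFAULT_WALL,
        )
        assert comp.ratios.loc["a", "b"] == pytest.approx(1.0)

    def test_ratio_invariant_to_global_stiffness_scaling(self, default_geometry):
        base = {
            "soft": pm.YeohCoefficients(0.05, 0.0, 0.0),
            "stiff": pm.YeohCoefficients(0.5, 0.1, 0.0),
        }
        wall = pm.YeohCoefficients(0.05, 0.0, 0.0)
        factor = 7.0
        scaled = {
            k: pm.YeohCoefficients(v.c10 * factor, v.c20 * factor, v.c30 * factor)
            for k, v in base.items()
        }
        wall_scaled = pm.YeohCoefficients(wall.c10 * factor, 0.0, 0.0)
        r1 = pm.compare_materials(default_geometry, base, wall).ratios
        r2 = pm.compare_materials(default_geometry, scaled, wall_scaled).ratios
        assert r1.loc["stiff", "soft"] == pytest.approx(r2.loc["stiff", "soft"], rel=1e-9)

    def test_single_material_rejected(self, default_geometry, femoral_heavy):
        with pytest.raises(ValueError):
            pm.compare_materials(default_geometry, {"a": femoral_heavy}, pm.DEFAULT_WALL)
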