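"""Released volume, scenario execution, calibration, reporting, clinical math."""

import numpy as np
import pandas as pd
import pytest

from conftest import block_labels
from orbitmech.analysis import (
    CalibrationGrid,
    PatientRecord,
    ScenarioResult,
    ScenarioSpec,
    WallPressures,
    build_report,
    calibrate,
    hertel_reduction,
    keypoint_gain,
    linearity_stats,
    load_clinical_cohort,
    released_volume,
    run_scenario,
    tissue_release,
)
from orbitmech.elasticity import DisplacementField, MaterialModel
from orbitmech.errors import (
    MissingValueError,
    ReportError,
    TetInversionError,
    ValidationError,
)
from orbitmech.meshing import voxels_to_tetmesh


@pytest.fixture(scope="module")
def mesh():
    return voxels_to_tetmesh(block_labels(4, 4, 4))


class TestReleasedVolume:
    def test_zero_displacement_releases_nothing(self, mesh):
        u = DisplacementField(np.zeros_like(mesh.nodes))
        assert released_volume(mesh, u) == 0.0

    def test_uniform_dilation_exact(self, mesh):
        alpha = 0.05
        u = DisplacementField(alpha * mesh.nodes)
        v = 64.0 / 1000.0  # 4x4x4 block at 1 mm, in cm^3
        assert released_volume(mesh, u) == pytest.approx(
            ((1 + alpha) ** 3 - 1) * v, rel=1e-12
        )

    def test_inverted_elements_raise(self, mesh):
        u = DisplacementField(-1.5 * mesh.nodes)  # reflects the mesh
        with pytest.raises(TetInversionError, match="small-strain"):
            released_volume(mesh, u)


class TestScenarios:
    def test_empty_scenario_releases_nothing(self, world_2mm, material, pressures):
        r = run_scenario(
            world_2mm.mesh, material, pressures,
            ScenarioSpec(name="none", tags=frozenset()),
        )
        assert r.dv_cm3 == 0.0
        assert r.v_sim_cm3 == r.v_pre_cm3

    def test_scenario_names_resolve_to_ring_unions(self):
        assert ScenarioSpec.from_name("l4").tags == {"l1", "l2", "l3", "kp1"}
        assert ScenarioSpec.from_name("l4+f4+kp2").tags == {
            "l1", "l2", "l3", "kp1", "f1", "f2", "f3", "f4", "kp2",
        }

    def test_two_wall_release_couples_the_walls(self, scenario_report):
        """Combined two-wall release is computed on the coupled system,
        not additively over walls: it exceeds either one-wall release
        and differs from their sum (here slightly above it, since
        unfixing both walls lengthens the shared free boundary)."""
        dv = dict(zip(scenario_report.scenario, scenario_report.dV_cm3))
        assert dv["l4+f4"] > max(dv["l4"], dv["f4"])
        combined, summed = dv["l4+f4"], dv["l4"] + dv["f4"]
        assert abs(combined - summed) / summed > 1e-3


class TestCalibration:
    def test_default_grid_has_320_points(self):
        assert CalibrationGrid().budget == 320

    def test_non_equidistant_axis_rejected(self):
        with pytest.raises(ValidationError, match="equidistant"):
            CalibrationGrid(m_axis=(1.0, 2.0, 10.0, 11.0))

    def test_single_point_grid_returns_that_point(self):
        mesh = voxels_to_tetmesh(block_labels(3, 3, 3))
        tags = mesh.boundary_tags.copy()
        tags[:] = "intact_bone"
        tags[mesh.boundary_normals[:, 2] > 0.5] = "l1"
        tags[mesh.boundary_normals[:, 1] < -0.5] = "f1"
        mesh.boundary_tags = tags
        grid = CalibrationGrid(
            m_axis=(5.0,), nu_axis=(0.1,), p_lat_axis=(0.02,),
            p_floor_axis=(0.05,), dv_target_cm3=0.0,
        )
        res = calibrate(grid, mesh, ScenarioSpec.from_name("l1+f1"))
        assert (res.m, res.nu, res.p_lat, res.p_floor) == (5.0, 0.1, 0.02, 0.05)
        assert len(res.table) == 1


class TestReporting:
    def test_relative_release_from_rounded_inputs(self):
        """dV_rel ratios of the rounded lateral releases 0.46..1.81."""
        results = [
            ScenarioResult(n, a, 59.6, 59.6 + d, d)
            for n, a, d in zip(
                ("l1", "l2", "l3", "l4"),
                (2.91, 5.55, 7.87, 9.28),
                (0.46, 0.92, 1.34, 1.81),
            )
        ]
        rep = build_report(results, {"lateral": ("l1", "l2", "l3", "l4")})
        assert rep.dV_rel_pct.round(1).tolist() == [25.4, 50.8, 74.0, 100.0]

    def test_family_maximum_is_always_100(self, scenario_report):
        for _, fam in scenario_report.groupby("family"):
            assert fam.dV_rel_pct.max() == pytest.approx(100.0)

    def test_report_conserves_dv_identity(self, scenario_report):
        np.testing.assert_allclose(
            scenario_report.dV_cm3,
            scenario_report.V_sim_cm3 - scenario_report.V_pre_cm3,
            atol=1e-12,
        )

    def test_zero_family_maximum_raises(self):
        results = [ScenarioResult("l1", 2.9, 59.6, 59.6, 0.0)]
        with pytest.raises(ReportError):
            build_report(results, {"lateral": ("l1",)})

    def test_keypoint_gain_matches_reported_percentage(self):
        assert keypoint_gain(10.97, 7.58) == pytest.approx(30.9, abs=0.05)


class TestLinearity:
    def test_collinear_points_have_unit_r_squared(self):
        fit = linearity_stats([1, 2, 3, 4], [2.0, 4.0, 6.0, 8.0])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_matches_bruteforce_least_squares(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(2, 10, size=8)
        d = 0.7 * a + rng.normal(scale=0.3, size=8)
        fit = linearity_stats(a, d)
        # normal-equations oracle
        x = np.vstack([a, np.ones_like(a)]).T
        beta = np.linalg.lstsq(x, d, rcond=None)[0]
        resid = d - x @ beta
        ss_tot = ((d - d.mean()) ** 2).sum()
        r2 = 1 - (resid**2).sum() / ss_tot
        assert fit.slope == pytest.approx(beta[0], abs=1e-12)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-12)
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)

    def test_constant_areas_rejected(self):
        with pytest.raises(ValidationError):
            linearity_stats([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestClinicalArithmetic:
    def test_cohort_rows_parse_with_expected_fields(self):
        cohort = load_clinical_cohort()
        assert len(cohort) == 4
        assert {r.side for r in cohort} == {"left", "right"}

    def test_release_and_hertel_examples(self):
        rec = PatientRecord("3", "right", volume_pre=32.3, volume_post=35.9)
        assert tissue_release(rec) == pytest.approx(3.6)
        rec = PatientRecord("4", "right", hertel_pre=28, hertel_post=22)
        assert hertel_reduction(rec) == 6
        same = PatientRecord("x", "left", volume_pre=40.0, volume_post=40.0)
        assert tissue_release(same) == 0.0

    def test_missing_operand_raises(self):
        with pytest.raises(MissingValueError):
            tissue_release(PatientRecord("1", "left", volume_pre=47.7))
        with pytest.raises(MissingValueError):
            hertel_reduction(PatientRecord("1", "left", hertel_pre=21))
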