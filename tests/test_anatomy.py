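"""Synthetic orbit generator: geometry, HU rendering, patch planning."""

import numpy as np
import pytest

from conftest import RENDER_SEED
from orbitmech import HUModel, OrbitSpec, PatchPlan, build_orbit, render_hu
from orbitmech.anatomy import plan_patches, scaled_geometry
from orbitmech.errors import (
    GeometryError,
    MissingDistributionError,
    PatchAreaError,
)
from orbitmech.segmentation import hu_stats
from orbitmech.volumes import LabelVolume, Tissue


class TestOrbitGeometry:
    def test_default_cavity_volume_matches_target(self, orbit_1mm):
        assert orbit_1mm.soft_tissue_volume_cm3() == pytest.approx(59.6, rel=0.02)

    def test_geometry_is_deterministic_and_seed_free(self):
        a = build_orbit(OrbitSpec(seed=1))
        b = build_orbit(OrbitSpec(seed=99))
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_bulbus_radius_gives_pure_fat_muscle_cavity(self):
        labels = build_orbit(OrbitSpec(bulbus_radius_mm=0.0))
        assert labels.count(Tissue.BULBUS) == 0
        assert labels.count(Tissue.FAT) > 0 and labels.count(Tissue.MUSCLE) > 0

    def test_voxelization_converges_with_spacing(self, orbit_1mm):
        coarse = build_orbit(OrbitSpec(voxel_spacing_mm=2.0))
        v1 = orbit_1mm.soft_tissue_volume_cm3()
        v2 = coarse.soft_tissue_volume_cm3()
        assert abs(v1 - v2) / v1 < 0.01

    def test_every_voxel_has_exactly_one_label(self, orbit_1mm):
        assert set(np.unique(orbit_1mm.data)) <= {0, 1, 2, 3, 4}

    def test_soft_tissue_leaves_shell_only_through_anterior_opening(self, orbit_1mm):
        """Soft voxels may touch non-bone exterior only near the aperture."""
        from orbitmech.anatomy import _wall_faces

        keys, cents = _wall_faces(orbit_1mm, Tissue.BACKGROUND)
        h = float(orbit_1mm.spacing[0])
        assert (cents[:, 2] > -1.01 * h).all()

    def test_bulbus_strictly_inside_cavity(self, orbit_1mm):
        geo = scaled_geometry(OrbitSpec())
        centers = orbit_1mm.voxel_centers().reshape(-1, 3)
        bulbus = (orbit_1mm.data == Tissue.BULBUS).reshape(-1)
        assert geo.contains(centers[bulbus]).all()

    @pytest.mark.parametrize(
        "bad_spec",
        [
            OrbitSpec(bulbus_radius_mm=40.0),  # globe larger than the cavity
            OrbitSpec(shell_thickness_mm=0.4),  # shell thinner than one voxel
        ],
    )
    def test_infeasible_geometry_raises(self, bad_spec):
        with pytest.raises(GeometryError):
            build_orbit(bad_spec)


class TestHURendering:
    def test_same_seed_is_bit_identical(self, orbit_1mm, hu_model):
        a = render_hu(orbit_1mm, hu_model, seed=5)
        b = render_hu(orbit_1mm, hu_model, seed=5)
        np.testing.assert_array_equal(a.data, b.data)
        c = render_hu(orbit_1mm, hu_model, seed=6)
        assert (a.data != c.data).any()

    def test_background_only_volume_renders_air(self, hu_model):
        labels = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), np.eye(4))
        img = render_hu(labels, hu_model, seed=0)
        assert (img.data == hu_model.background_hu).all()

    def test_missing_distribution_raises(self, orbit_1mm):
        partial = HUModel(
            tissues={
                t: s
                for t, s in HUModel().tissues.items()
                if t != Tissue.MUSCLE
            }
        )
        with pytest.raises(MissingDistributionError, match="muscle"):
            render_hu(orbit_1mm, partial, seed=0)

    @pytest.mark.parametrize(
        "tissue", [Tissue.FAT, Tissue.MUSCLE, Tissue.BULBUS, Tissue.BONE]
    )
    def test_sampled_stats_match_reference(self, hu_model, tissue):
        """At n = 2*10^4 samples the empirical mean sits within +/-1 HU
        and the median within +/-2 HU of the reference statistics for
        the soft tissues.  Bone, whose fitted spread is ~180 HU, is held
        to a 4-standard-error bound on the mean; its stated mean < median
        is not representable by a truncated normal, so its median is
        checked against the distribution's own value, not the reference."""
        rng = np.random.default_rng(987)
        n = 20_000
        x = hu_model.sample(tissue, n, rng)
        ref = hu_model.tissues[tissue]
        assert x.min() >= ref.lo and x.max() <= ref.hi
        if tissue is Tissue.BONE:
            se = hu_model.distribution(tissue).std() / np.sqrt(n)
            assert abs(x.mean() - ref.mean) < 4 * se
            assert abs(np.median(x) - hu_model.distribution(tissue).median()) < 4 * se
        else:
            assert abs(x.mean() - ref.mean) <= 1.0
            assert abs(np.median(x) - ref.median) <= 2.0

    def test_rendered_fat_voxel_stats(self, orbit_1mm, pseudo_ct, hu_model):
        """Fat, the one tissue exceeding 10^4 voxels in the default
        orbit, also meets the mean/median bounds voxel-wise."""
        assert orbit_1mm.count(Tissue.FAT) >= 10_000
        stats = hu_stats(pseudo_ct, orbit_1mm, Tissue.FAT)
        ref = hu_model.tissues[Tissue.FAT]
        assert stats.min >= ref.lo and stats.max <= ref.hi
        assert abs(stats.mean - ref.mean) <= 1.0
        assert abs(stats.median - ref.median) <= 2.0

    def test_fitted_distributions_reproduce_stated_means_exactly(self, hu_model):
        for tissue in hu_model.tissues:
            d = hu_model.distribution(tissue)
            assert d.mean() == pytest.approx(hu_model.tissues[tissue].mean, abs=1e-6)


@pytest.fixture(scope="module")
def patches(orbit_1mm):
    return plan_patches(orbit_1mm, PatchPlan())


class TestPatchPlanning:
    def test_strict_nesting_by_set_inclusion(self, patches):
        for fam in (("l1", "l2", "l3", "l4"), ("f1", "f2", "f3", "f4")):
            for inner, outer in zip(fam, fam[1:]):
                si = set(patches.masks[inner].tolist())
                so = set(patches.masks[outer].tolist())
                assert si < so  # strict subset

    def test_kp1_is_exact_set_difference_of_l4_l3(self, patches):
        l3 = set(patches.masks["l3"].tolist())
        l4 = set(patches.masks["l4"].tolist())
        assert set(patches.masks["kp1"].tolist()) == l4 - l3
        assert patches.area("l4") == pytest.approx(
            patches.area("l3") + patches.area("kp1"), abs=1e-12
        )

    def test_realized_areas_within_five_percent(self, patches):
        plan = PatchPlan()
        for tag, want in zip(("l1", "l2", "l3", "l4"), plan.lateral_areas_cm2):
            assert patches.area(tag) == pytest.approx(want, rel=0.05)
        for tag, want in zip(("f1", "f2", "f3", "f4"), plan.floor_areas_cm2):
            assert patches.area(tag) == pytest.approx(want, rel=0.05)
        assert patches.area("kp2") == pytest.approx(plan.kp2_area_cm2, rel=0.05)

    def test_kp2_disjoint_from_wall_families(self, patches):
        kp2 = set(patches.masks["kp2"].tolist())
        assert not kp2 & set(patches.masks["l4"].tolist())
        assert not kp2 & set(patches.masks["f4"].tolist())

    def test_zero_area_request_gives_empty_mask(self, orbit_1mm):
        plan = PatchPlan(lateral_areas_cm2=(0.0, 1.0, 2.0, 3.0))
        ps = plan_patches(orbit_1mm, plan)
        assert ps.masks["l1"].size == 0

    def test_excessive_request_errors_naming_wall(self, orbit_1mm):
        plan = PatchPlan(floor_areas_cm2=(3.31, 6.04, 7.58, 500.0))
        with pytest.raises(PatchAreaError, match="floor"):
            plan_patches(orbit_1mm, plan)
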