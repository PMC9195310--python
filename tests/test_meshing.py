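"""Voxel-to-tetrahedron meshing: counts, conservation, watertightness, tags."""

import numpy as np
import pytest

from conftest import block_labels, mask_labels
from orbitmech.anatomy import PatchSet
from orbitmech.errors import MeshError, PatchOverlapError, UnknownTagError
from orbitmech.meshing import (
    patch_area,
    signed_volumes,
    tag_boundary,
    tissue_volume,
    voxels_to_tetmesh,
)
from orbitmech.volumes import LabelVolume, Tissue


class TestSubdivision:
    def test_single_voxel_six_positive_tets(self):
        mesh = voxels_to_tetmesh(block_labels(1, 1, 1, h=2.0))
        assert mesh.n_tets == 6
        vols = signed_volumes(mesh.nodes, mesh.tets)
        assert (vols > 0).all()
        assert vols.sum() == pytest.approx(8.0)

    def test_2x2x2_block_counts_match_face_oracle(self):
        """Brute-force face count: 6 tets/voxel; each exposed voxel square
        splits into 2 boundary triangles (24 squares -> 48 triangles)."""
        mesh = voxels_to_tetmesh(block_labels(2, 2, 2))
        assert mesh.n_tets == 48
        assert mesh.boundary_tris.shape[0] == 48

    def test_volume_conservation_to_machine_precision(self):
        rng = np.random.default_rng(11)
        mask = rng.random((6, 7, 8)) > 0.5
        mask[0, 0, 0] = True
        labels = mask_labels(mask, h=0.7)
        mesh = voxels_to_tetmesh(labels)
        expected = mask.sum() * 0.7**3
        assert signed_volumes(mesh.nodes, mesh.tets).sum() == pytest.approx(
            expected, rel=1e-13
        )

    @staticmethod
    def _edge_counts(mesh):
        edges = np.sort(
            mesh.boundary_tris[:, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2), axis=1
        )
        return np.unique(edges, axis=0, return_counts=True)[1]

    def test_boundary_of_manifold_solid_is_watertight(self, world_2mm):
        """On the synthetic orbit every boundary edge is shared by
        exactly two boundary triangles (a closed surface)."""
        assert (self._edge_counts(world_2mm.mesh) == 2).all()
        assert (self._edge_counts(voxels_to_tetmesh(block_labels(3, 3, 3))) == 2).all()

    def test_boundary_of_arbitrary_voxel_set_is_closed(self):
        """Random voxel blobs may contain non-manifold edge contacts
        (two voxels sharing only an edge), where four boundary triangles
        meet; the boundary is still closed: every edge count is even."""
        rng = np.random.default_rng(4)
        mask = rng.random((5, 5, 5)) > 0.4
        mask[2, 2, 2] = True
        mesh = voxels_to_tetmesh(mask_labels(mask))
        assert (self._edge_counts(mesh) % 2 == 0).all()

    def test_empty_soft_tissue_raises(self):
        labels = LabelVolume(np.zeros((3, 3, 3), dtype=np.uint8), np.eye(4))
        with pytest.raises(MeshError):
            voxels_to_tetmesh(labels)

    def test_element_labels_inherited_from_voxels(self):
        data = np.zeros((2, 1, 1), dtype=np.uint8)
        data[0] = Tissue.FAT
        data[1] = Tissue.MUSCLE
        mesh = voxels_to_tetmesh(LabelVolume(data, np.eye(4)))
        assert (np.sort(np.unique(mesh.tet_labels)) == [2, 3]).all()
        assert (mesh.tet_labels[:6] == Tissue.FAT).all()


class TestMeasurement:
    def test_patch_area_counts_exposed_faces(self):
        """A kxk set of exposed voxel faces has area k^2 h^2."""
        mesh = voxels_to_tetmesh(block_labels(3, 3, 1, h=2.0))
        top = mesh.boundary_normals[:, 2] > 0.5
        tags = mesh.boundary_tags.copy()
        tags[top] = "kp2"
        mesh.boundary_tags = tags
        assert patch_area(mesh, "kp2") == pytest.approx(9 * 4.0 / 100.0)

    def test_block_volume_in_cm3(self):
        mesh = voxels_to_tetmesh(block_labels(10, 10, 10))
        assert tissue_volume(mesh) == pytest.approx(1.0)

    def test_unknown_tag_raises(self, world_2mm):
        with pytest.raises(UnknownTagError):
            patch_area(world_2mm.mesh, "l9")


class TestTagging:
    def test_empty_patch_set_keeps_interface_intact(self):
        mesh = voxels_to_tetmesh(block_labels(2, 2, 2))
        empty = PatchSet(
            masks={
                t: np.empty(0, dtype=np.int64)
                for t in ("l1", "l2", "l3", "l4", "kp1", "f1", "f2", "f3", "f4", "kp2")
            },
            face_area_cm2=0.01,
            shape=(2, 2, 2),
        )
        tagged = tag_boundary(mesh, empty)
        assert set(np.unique(tagged.boundary_tags)) <= {"intact_bone", "opening"}

    def test_overlapping_non_nested_tags_raise(self):
        mesh = voxels_to_tetmesh(block_labels(2, 2, 2))
        shared = np.array([0], dtype=np.int64)
        masks = {
            t: np.empty(0, dtype=np.int64)
            for t in ("l1", "l2", "l3", "l4", "kp1", "f1", "f2", "f3", "f4")
        }
        masks["f1"] = shared
        masks["kp2"] = shared  # same face claimed by two unrelated tags
        bad = PatchSet(masks=masks, face_area_cm2=0.01, shape=(2, 2, 2))
        with pytest.raises(PatchOverlapError):
            tag_boundary(mesh, bad)

    def test_synthetic_world_tag_areas_match_plan(self, world_2mm):
        """Summed triangle areas per scenario tag track the requested
        patch areas (voxel-face discretization, 5% tolerance)."""
        from orbitmech.anatomy import PatchPlan

        plan = PatchPlan()
        mesh = world_2mm.mesh
        for tag, want in zip(("l1", "l2", "l3", "l4"), plan.lateral_areas_cm2):
            assert patch_area(mesh, tag) == pytest.approx(want, rel=0.05)
        for tag, want in zip(("f1", "f2", "f3", "f4"), plan.floor_areas_cm2):
            assert patch_area(mesh, tag) == pytest.approx(want, rel=0.05)
        assert patch_area(mesh, "l4") == pytest.approx(
            patch_area(mesh, "l3") + patch_area(mesh, "kp1"), abs=1e-9
        )

    def test_mesh_volume_matches_labelled_volume(self, world_2mm):
        assert tissue_volume(world_2mm.mesh) == pytest.approx(
            world_2mm.labels.soft_tissue_volume_cm3(), rel=1e-12
        )
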