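"""Voxel-to-tetrahedron meshing, boundary tagging and measurement.

Each soft-tissue voxel is split into six positively oriented tetrahedra
sharing the main cube diagonal (Kuhn/Freudenthal subdivision).  Because
every voxel uses the same diagonal pattern the mesh is conforming across
voxel faces, the meshed volume equals the labelled voxel volume exactly,
and the boundary surface is watertight.

Boundary triangles carry a patch tag from
``{intact_bone, opening, l1..l3, kp1, f1..f4, kp2}``; the nested graded
scenarios are unions of ring tags (``l4`` resolves to ``l1+l2+l3+kp1``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .anatomy import PatchSet
from .errors import MeshError, PatchOverlapError, UnknownTagError
from .volumes import LabelVolume, SOFT_TISSUES, Tissue

__all__ = [
    "TetMesh",
    "voxels_to_tetmesh",
    "tag_boundary",
    "patch_area",
    "tissue_volume",
    "signed_volumes",
    "expand_tag",
]

_CORNERS = np.array(
    [(dx, dy, dz) for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
)  # slot = dx + 2*dy + 4*dz


def _kuhn_tets() -> np.ndarray:
    """Corner-slot quadruples of the 6-tet cube subdivision, oriented +."""
    tets = []
    for perm in itertools.permutations(range(3)):
        path = [np.zeros(3, dtype=int)]
        for axis in perm:
            nxt = path[-1].copy()
            nxt[axis] += 1
            path.append(nxt)
        slots = [int(p[0] + 2 * p[1] + 4 * p[2]) for p in path]
        v = _CORNERS[slots].astype(float)
        if np.linalg.det(v[1:] - v[0]) < 0:
            slots[1], slots[2] = slots[2], slots[1]
        tets.append(slots)
    return np.array(tets, dtype=np.int64)


KUHN_TETS = _kuhn_tets()

#: Scenario-level tags resolved to the disjoint ring tags they cover.
_TAG_UNIONS: dict[str, tuple[str, ...]] = {
    "l1": ("l1",),
    "l2": ("l1", "l2"),
    "l3": ("l1", "l2", "l3"),
    "l4": ("l1", "l2", "l3", "kp1"),
    "kp1": ("kp1",),
    "f1": ("f1",),
    "f2": ("f1", "f2"),
    "f3": ("f1", "f2", "f3"),
    "f4": ("f1", "f2", "f3", "f4"),
    "kp2": ("kp2",),
    "intact_bone": ("intact_bone",),
    "opening": ("opening",),
}

#: Ring tags belonging to the lateral / floor wall (for load assignment).
LATERAL_RING_TAGS = frozenset({"l1", "l2", "l3", "kp1"})
FLOOR_RING_TAGS = frozenset({"f1", "f2", "f3", "f4", "kp2"})


def expand_tag(tag: str) -> tuple[str, ...]:
    try:
        return _TAG_UNIONS[tag]
    except KeyError:
        raise UnknownTagError(f"unknown patch tag {tag!r}") from None


@dataclass
class TetMesh:
    """Labelled tetrahedral mesh with a tagged boundary surface.

    Attributes
    ----------
    nodes:
        Node coordinates in world mm, shape (n, 3).
    tets:
        Tetrahedra as node quadruples with positive signed volume.
    tet_labels:
        Tissue label per element.
    boundary_tris:
        Boundary triangles (node triples), each belonging to exactly one
        tetrahedron.
    boundary_tet:
        Owning element of each boundary triangle.
    boundary_normals:
        Outward unit normal of each boundary triangle.
    boundary_tags:
        Patch tag of each boundary triangle.
    boundary_face_keys:
        Source voxel-face key of each boundary triangle (matches
        :class:`~orbitmech.anatomy.PatchSet` encoding).
    """

    nodes: np.ndarray
    tets: np.ndarray
    tet_labels: np.ndarray
    boundary_tris: np.ndarray
    boundary_tet: np.ndarray
    boundary_normals: np.ndarray
    boundary_tags: np.ndarray
    boundary_face_keys: np.ndarray
    spacing: float

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_tets(self) -> int:
        return int(self.tets.shape[0])

    def with_nodes(self, nodes: np.ndarray, normals: np.ndarray | None = None) -> "TetMesh":
        return replace(
            self,
            nodes=np.asarray(nodes, dtype=float),
            boundary_normals=self.boundary_normals if normals is None else normals,
        )

    def boundary_areas(self) -> np.ndarray:
        """Area of every boundary triangle in mm^2."""
        p = self.nodes[self.boundary_tris]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )


def signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each tetrahedron in mm^3."""
    p = nodes[tets]
    return np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    ) / 6.0


def voxels_to_tetmesh(
    labels: LabelVolume, tissues: tuple[Tissue, ...] = SOFT_TISSUES
) -> TetMesh:
    """Mesh the selected tissues, six tetrahedra per voxel.

    The total mesh volume equals the labelled voxel volume exactly and
    every element inherits its voxel's tissue label.
    """
    mask = labels.mask(*tissues)
    vox = np.argwhere(mask)
    if vox.shape[0] == 0:
        raise MeshError("no soft-tissue voxels to mesh")
    shape = labels.shape
    lat_shape = (shape[0] + 1, shape[1] + 1, shape[2] + 1)

    # Lattice ids of the 8 corners of every voxel (corner i spans voxel
    # indices i-0.5 .. i+0.5; corner lattice coordinate = voxel index + offset).
    corner_idx = vox[:, None, :] + _CORNERS[None, :, :]  # (k, 8, 3)
    corner_flat = np.ravel_multi_index(
        (corner_idx[..., 0], corner_idx[..., 1], corner_idx[..., 2]), lat_shape
    )
    used, inverse = np.unique(corner_flat, return_inverse=True)
    node_ids = inverse.reshape(corner_flat.shape)

    lat = np.stack(np.unravel_index(used, lat_shape), axis=1).astype(float)
    nodes = labels.index_to_world(lat - 0.5)

    tets = node_ids[:, KUHN_TETS].reshape(-1, 4)
    tet_labels = np.repeat(labels.data[mask.nonzero()], 6)
    voxel_of_tet = np.repeat(np.arange(vox.shape[0]), 6)

    vols = signed_volumes(nodes, tets)
    if not (vols > 0).all():
        raise MeshError("non-positive tetrahedron produced by subdivision")

    # Boundary: tet faces that occur exactly once.
    faces = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    sk = key[order]
    new = np.ones(sk.shape[0], dtype=bool)
    new[1:] = (sk[1:] != sk[:-1]).any(axis=1)
    group = np.cumsum(new) - 1
    counts = np.bincount(group)
    single = counts[group] == 1
    b_face_rows = order[single]
    boundary_tris = faces[b_face_rows]
    boundary_tet = b_face_rows // 4

    # Axis/side of each boundary face from node lattice coordinates.
    lat_int = lat.astype(np.int64)
    tri_lat = lat_int[boundary_tris]  # (nb, 3, 3)
    same = (tri_lat[:, 0] == tri_lat[:, 1]) & (tri_lat[:, 0] == tri_lat[:, 2])
    axes = np.argmax(same, axis=1)
    plane = tri_lat[np.arange(len(axes)), 0, axes]
    owner_vox = vox[voxel_of_tet[boundary_tet]]
    owner_along = owner_vox[np.arange(len(axes)), axes]
    side = (plane == owner_along + 1).astype(np.int64)  # 1 -> +axis face

    normals = np.zeros((len(axes), 3))
    normals[np.arange(len(axes)), axes] = np.where(side == 1, 1.0, -1.0)
    # rotate axis-aligned lattice normals into world orientation
    normals = normals @ (labels.affine[:3, :3] / labels.spacing).T

    owner_flat = np.ravel_multi_index(owner_vox.T, shape)
    face_keys = (owner_flat * 3 + axes) * 2 + side

    tags = np.full(len(axes), "intact_bone", dtype="<U12")
    # Faces against non-bone, non-soft space are the anterior opening.
    nb_vox = owner_vox.copy()
    nb_vox[np.arange(len(axes)), axes] += np.where(side == 1, 1, -1)
    inside = ((nb_vox >= 0) & (nb_vox < np.array(shape))).all(axis=1)
    nb_label = np.zeros(len(axes), dtype=labels.data.dtype)
    nb_label[inside] = labels.data[tuple(nb_vox[inside].T)]
    tags[nb_label != Tissue.BONE] = "opening"

    return TetMesh(
        nodes=nodes,
        tets=tets,
        tet_labels=tet_labels.astype(np.uint8),
        boundary_tris=boundary_tris,
        boundary_tet=boundary_tet,
        boundary_normals=normals,
        boundary_tags=tags,
        boundary_face_keys=face_keys,
        spacing=float(labels.spacing[0]),
    )


def tag_boundary(mesh: TetMesh, patches: PatchSet) -> TetMesh:
    """Tag boundary triangles by the resection patch covering their face.

    Nested cumulative masks are reduced to disjoint rings (the innermost
    tag wins); a face claimed by two unrelated tags raises
    :class:`PatchOverlapError`.  Bone-backed faces outside every patch
    stay ``intact_bone``; faces open to air keep the ``opening`` tag.
    """
    rings = patches.rings()
    face_tag: dict[int, str] = {}
    for tag, keys in rings.items():
        for k in keys.tolist():
            if k in face_tag and face_tag[k] != tag:
                raise PatchOverlapError(
                    f"face {k} claimed by both {face_tag[k]!r} and {tag!r}"
                )
            face_tag[k] = tag

    tags = mesh.boundary_tags.copy()
    bone_backed = tags == "intact_bone"
    for i in np.flatnonzero(bone_backed):
        t = face_tag.get(int(mesh.boundary_face_keys[i]))
        if t is not None:
            tags[i] = t
    return replace(mesh, boundary_tags=tags)


def patch_area(mesh: TetMesh, tag: str) -> float:
    """Total area of a tag (or scenario-level tag union) in cm^2."""
    rings = expand_tag(tag)
    sel = np.isin(mesh.boundary_tags, rings)
    if not sel.any() and tag not in ("opening", "intact_bone"):
        present = set(np.unique(mesh.boundary_tags))
        if not set(rings) & present:
            raise UnknownTagError(f"tag {tag!r} not present on mesh boundary")
    return float(mesh.boundary_areas()[sel].sum()) / 100.0


def tissue_volume(mesh: TetMesh, tissues: tuple[Tissue, ...] = SOFT_TISSUES) -> float:
    """Summed signed element volume over the given tissues, in cm^3."""
    sel = np.isin(mesh.tet_labels, np.asarray(tissues, dtype=mesh.tet_labels.dtype))
    return float(signed_volumes(mesh.nodes, mesh.tets)[sel].sum()) / 1000.0
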