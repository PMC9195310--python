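"""Landmark-based rigid registration (Kabsch) of pre-/post-surgery models.

The closed-form SVD solution is used, with the reflection branch
suppressed so the estimate is always a proper rotation (det = +1), as
required when registering skull models that must not be mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RegistrationError
from .meshing import TetMesh


@dataclass(frozen=True)
class LandmarkSet:
    """Paired source/target 3-D landmark coordinates in mm."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.source, dtype=float))
        tgt = np.atleast_2d(np.asarray(self.target, dtype=float))
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", tgt)
        if src.shape != tgt.shape or src.shape[1] != 3:
            raise RegistrationError("source/target must be matching (n, 3) arrays")
        if src.shape[0] < 3:
            raise RegistrationError("at least 3 landmark pairs are required")
        centered = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
            raise RegistrationError("landmarks are collinear; rotation not unique")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def rigid_register(lm: LandmarkSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform and its RMSD in mm.

    Minimizes ``sum ||R x_i + t - y_i||^2`` over proper rotations R and
    translations t (Kabsch/Umeyama without scaling).
    """
    x, y = lm.source, lm.target
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = yc - r @ xc
    tf = RigidTransform(r, t)
    resid = tf.apply(x) - y
    rmsd = float(np.sqrt((resid**2).sum() / x.shape[0]))
    return tf, rmsd


def apply_transform(mesh: TetMesh, transform: RigidTransform) -> TetMesh:
    """Map mesh node coordinates (and boundary normals) rigidly.

    Volumes and areas are preserved to machine precision.
    """
    nodes = transform.apply(mesh.nodes)
    normals = mesh.boundary_normals @ transform.rotation.T
    return mesh.with_nodes(nodes, normals)
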