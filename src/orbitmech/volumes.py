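"""In-memory containers for 3-D scalar volumes.

Two thin wrappers around a numpy array plus a voxel-to-world affine are
used throughout the pipeline: :class:`ImageVolume` for Hounsfield-unit
(HU) grids (pseudo-CT) and :class:`LabelVolume` for per-voxel tissue
labels.  Coordinates follow the neuroimaging convention: the affine maps
0-based voxel indices to world millimetres on RAS axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import ValidationError


class Tissue(IntEnum):
    """Tissue labels used by the synthetic anatomy and the segmenter."""

    BACKGROUND = 0
    BONE = 1
    FAT = 2
    MUSCLE = 3
    BULBUS = 4


#: Labels that constitute deformable orbital soft tissue.
SOFT_TISSUES = (Tissue.FAT, Tissue.MUSCLE, Tissue.BULBUS)


@dataclass
class _Volume:
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices, shape (n, 3), to world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.index_to_world(idx).reshape(nx, ny, nz, 3)


class ImageVolume(_Volume):
    """A 3-D grid of Hounsfield units."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.float32, copy=False)


class LabelVolume(_Volume):
    """A 3-D grid of integer tissue labels (see :class:`Tissue`)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValidationError("label data must be integer-typed")

    def mask(self, *tissues: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        return np.isin(self.data, np.asarray(tissues, dtype=self.data.dtype))

    def count(self, *tissues: int) -> int:
        return int(self.mask(*tissues).sum())

    def volume_cm3(self, *tissues: int) -> float:
        """Total labelled volume of the given tissues in cm^3."""
        return self.count(*tissues) * self.voxel_volume / 1000.0

    def soft_tissue_volume_cm3(self) -> float:
        return self.volume_cm3(*SOFT_TISSUES)
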