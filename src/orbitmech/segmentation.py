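"""Threshold-and-seed tissue segmentation of HU volumes.

Each tissue is characterized by an HU interval; ties between tissues
with overlapping intervals (muscle/bulbus, and the narrow fat/muscle
overlap) are resolved by spatial seed regions and a priority order.
Voxels matching no rule remain background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .anatomy import HUModel, OrbitGeometry
from .errors import EmptyTissueError, ValidationError
from .volumes import ImageVolume, LabelVolume, SOFT_TISSUES, Tissue


# ---------------------------------------------------------------------------
# Seed regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphereSeed:
    center: tuple[float, float, float]
    radius: float

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        return np.linalg.norm(xyz - np.asarray(self.center), axis=-1) <= self.radius


@dataclass(frozen=True)
class CapsuleSeed:
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        p0, p1 = np.asarray(self.p0), np.asarray(self.p1)
        d = p1 - p0
        denom = float(d @ d)
        t = np.clip(((xyz - p0) @ d) / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = p0 + np.multiply.outer(t, d)
        return np.linalg.norm(xyz - closest, axis=-1) <= self.radius


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


class HUInterval(NamedTuple):
    lo: float
    hi: float


@dataclass
class SegmentationRule:
    """Per-tissue HU intervals, priority order, and optional seed regions.

    ``priority`` lists tissues from highest to lowest precedence; a voxel
    is assigned the highest-priority tissue whose interval contains its
    HU and whose seed region (if any) contains the voxel centre.
    ``keep_largest_component`` discards isolated speckles per soft tissue
    that arise from HU sampling noise.
    """

    intervals: dict[Tissue, HUInterval]
    priority: Sequence[Tissue] = (Tissue.BONE, Tissue.BULBUS, Tissue.MUSCLE, Tissue.FAT)
    seeds: dict[Tissue, list] = field(default_factory=dict)
    keep_largest_component: bool = False

    def validate(self) -> None:
        if len(set(self.priority)) != len(self.priority):
            raise ValidationError("each priority must appear exactly once")
        for tissue in self.priority:
            if tissue not in self.intervals:
                raise ValidationError(
                    f"no HU interval for prioritized tissue {Tissue(tissue).name}"
                )

    @classmethod
    def from_hu_model(
        cls,
        hu: HUModel,
        geometry: OrbitGeometry | None = None,
        seed_margin_mm: float = 1.0,
        keep_largest_component: bool = False,
    ) -> "SegmentationRule":
        """Thresholds from an HU model; seeds from the synthetic geometry.

        The bulbus/muscle HU ranges overlap entirely and muscle overlaps
        the top of the fat range, so pure thresholding cannot separate
        them; when the generating geometry is known, the bulbus gets a
        spherical seed and each rectus muscle a capsule seed (the tissue
        shape dilated by ``seed_margin_mm``).
        """
        intervals = {
            t: HUInterval(s.lo, s.hi) for t, s in hu.tissues.items()
        }
        seeds: dict[Tissue, list] = {}
        if geometry is not None:
            if geometry.bulbus_radius > 0:
                seeds[Tissue.BULBUS] = [
                    SphereSeed(geometry.bulbus_center, geometry.bulbus_radius + seed_margin_mm)
                ]
            if geometry.muscle_segments:
                seeds[Tissue.MUSCLE] = [
                    CapsuleSeed(p0, p1, geometry.muscle_radius + seed_margin_mm)
                    for p0, p1 in geometry.muscle_segments
                ]
        return cls(
            intervals=intervals,
            seeds=seeds,
            keep_largest_component=keep_largest_component,
        )


def segment(volume: ImageVolume, rule: SegmentationRule) -> LabelVolume:
    """Assign every voxel the highest-priority matching tissue.

    Lower-priority tissues are painted first and overwritten by higher
    ones, so the final label of a voxel is the highest-priority tissue
    whose HU interval and seed region both contain it.
    """
    rule.validate()
    hu = volume.data
    centers = None
    labels = np.zeros(volume.shape, dtype=np.uint8)
    for tissue in reversed(list(rule.priority)):
        lo, hi = rule.intervals[tissue]
        mask = (hu >= lo) & (hu <= hi)
        if tissue in rule.seeds and rule.seeds[tissue]:
            if centers is None:
                centers = volume.voxel_centers().reshape(-1, 3)
            inside = np.zeros(centers.shape[0], dtype=bool)
            for seed in rule.seeds[tissue]:
                inside |= seed.contains(centers)
            mask &= inside.reshape(volume.shape)
        labels[mask] = tissue
    if rule.keep_largest_component:
        labels = _largest_components(labels)
    return LabelVolume(labels, volume.affine.copy())


def _largest_components(labels: np.ndarray) -> np.ndarray:
    out = labels.copy()
    for tissue in SOFT_TISSUES:
        mask = labels == tissue
        if not mask.any():
            continue
        comp, n = ndimage.label(mask)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        out[mask & (comp != keep)] = Tissue.BACKGROUND
    return out


class HUStats(NamedTuple):
    min: float
    max: float
    median: float
    mean: float


def hu_stats(volume: ImageVolume, labels: LabelVolume, tissue: Tissue) -> HUStats:
    """Exact order statistics of one tissue's HU values."""
    if volume.shape != labels.shape:
        raise ValidationError("volume and labels have different shapes")
    values = volume.data[labels.data == tissue]
    if values.size == 0:
        raise EmptyTissueError(f"tissue {Tissue(tissue).name} has no voxels")
    v = values.astype(np.float64)
    return HUStats(float(v.min()), float(v.max()), float(np.median(v)), float(v.mean()))
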