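"""Parametric synthetic orbital anatomy and pseudo-CT rendering.

The orbit is modelled as a posteriorly tapered elliptic cone (the bony
cavity) capped anteriorly by a half-ellipsoid bulge that plays the role
of the open anterior aperture.  The cavity is wrapped in a bone shell of
constant thickness, except anterior of the aperture plane where the
orbit opens to air.  Inside the cavity sit an eyeball (bulbus), four
rectus muscles running from the orbital apex to the globe, and fat
filling the remainder.

World coordinates are millimetres with the cone axis along ``z``:
the aperture plane is ``z = 0``, the apex at ``z = -L``; ``+x`` is the
lateral direction (towards the lateral wall) and ``-y`` is inferior
(towards the orbital floor).

All cavity-defining lengths are scaled uniformly so that the analytic
cavity volume matches the requested target (default 59.6 cm^3, a
pre-surgery orbital volume typical of severe endocrine orbitopathy).
Geometry generation is fully deterministic; randomness enters only when
Hounsfield units are rendered on top of the labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq, least_squares
from scipy.stats import truncnorm

from .errors import (
    GeometryError,
    MissingDistributionError,
    PatchAreaError,
    ValidationError,
)
from .volumes import ImageVolume, LabelVolume, Tissue

__all__ = [
    "OrbitSpec",
    "OrbitGeometry",
    "HUModel",
    "TissueHU",
    "PatchPlan",
    "PatchSet",
    "build_orbit",
    "render_hu",
    "plan_patches",
    "scaled_geometry",
]


# ---------------------------------------------------------------------------
# Orbit specification and derived geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrbitSpec:
    """Parameters of the synthetic orbit.

    Parameters
    ----------
    target_volume_cm3:
        Cavity (soft tissue) volume the generator aims for; the default
        of 59.6 cm^3 is the pre-surgery orbital volume of the reference
        simulation subject.
    opening_half_axes_mm:
        Half-axes ``(a0, b0)`` of the elliptic aperture cross-section
        before volume scaling.
    apex_depth_mm:
        Distance from aperture plane to orbital apex before scaling.
    cap_depth_mm:
        Depth of the anterior half-ellipsoid bulge (the open aperture).
    shell_thickness_mm:
        Bone shell thickness; not volume-scaled.
    bulbus_radius_mm, bulbus_center_depth_mm:
        Globe radius and how far posterior of the aperture plane its
        centre sits (both volume-scaled).
    muscle_count, muscle_radius_mm:
        Number of rectus muscles and their tube radius (scaled).
    voxel_spacing_mm:
        Isotropic voxel edge length of the generated volumes.
    volume_tol:
        Relative tolerance for the voxelized cavity volume against the
        target.
    seed:
        Default random seed, consumed only by :func:`render_hu`; the
        geometry itself is deterministic.
    """

    target_volume_cm3: float = 59.6
    opening_half_axes_mm: tuple[float, float] = (26.0, 24.0)
    apex_depth_mm: float = 50.0
    cap_depth_mm: float = 8.0
    shell_thickness_mm: float = 2.0
    bulbus_radius_mm: float = 11.0
    bulbus_center_depth_mm: float = 6.0
    muscle_count: int = 4
    muscle_radius_mm: float = 3.5
    voxel_spacing_mm: float = 1.0
    volume_tol: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        lengths = {
            "opening half-axis a0": self.opening_half_axes_mm[0],
            "opening half-axis b0": self.opening_half_axes_mm[1],
            "apex depth": self.apex_depth_mm,
            "cap depth": self.cap_depth_mm,
            "shell thickness": self.shell_thickness_mm,
            "muscle radius": self.muscle_radius_mm,
            "voxel spacing": self.voxel_spacing_mm,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValidationError(f"{name} must be > 0, got {value}")
        if self.bulbus_radius_mm < 0:
            raise ValidationError("bulbus radius must be >= 0")
        if self.target_volume_cm3 <= 0:
            raise ValidationError("target volume must be > 0")
        if self.muscle_count < 0:
            raise ValidationError("muscle count must be >= 0")
        if self.shell_thickness_mm < self.voxel_spacing_mm:
            raise GeometryError(
                "bone shell thinner than one voxel: "
                f"{self.shell_thickness_mm} mm shell at "
                f"{self.voxel_spacing_mm} mm spacing"
            )

    def with_spacing(self, spacing_mm: float) -> "OrbitSpec":
        return replace(self, voxel_spacing_mm=spacing_mm)


@dataclass(frozen=True)
class OrbitGeometry:
    """Volume-scaled analytic geometry derived from an :class:`OrbitSpec`."""

    a0: float
    b0: float
    depth: float
    cap: float
    shell: float
    bulbus_radius: float
    bulbus_center: tuple[float, float, float]
    muscle_radius: float
    muscle_segments: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...]
    scale: float

    @property
    def cavity_volume_mm3(self) -> float:
        """Analytic cavity volume: elliptic cone plus anterior half-ellipsoid."""
        cone = math.pi * self.a0 * self.b0 * self.depth / 3.0
        cap = 2.0 * math.pi * self.a0 * self.b0 * self.cap / 3.0
        return cone + cap

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Vectorized cavity membership test for world points (n, 3)."""
        x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
        inside = np.zeros(x.shape, dtype=bool)
        cone = (z <= 0) & (z >= -self.depth)
        with np.errstate(divide="ignore", invalid="ignore"):
            taper = 1.0 + z / self.depth
            r2 = (x / (self.a0 * taper)) ** 2 + (y / (self.b0 * taper)) ** 2
        inside |= cone & (taper > 0) & (r2 <= 1.0)
        cap = (z > 0) & (
            (x / self.a0) ** 2 + (y / self.b0) ** 2 + (z / self.cap) ** 2 <= 1.0
        )
        return inside | cap

    def wall_radius(self, azimuth_deg: float, depth_fraction: float) -> np.ndarray:
        """Point on the cavity wall at a given azimuth and fractional depth."""
        t = math.radians(azimuth_deg)
        taper = 1.0 - depth_fraction
        return np.array(
            [
                self.a0 * taper * math.cos(t),
                self.b0 * taper * math.sin(t),
                -depth_fraction * self.depth,
            ]
        )


def scaled_geometry(spec: OrbitSpec) -> OrbitGeometry:
    """Scale the parametric shape so the analytic cavity volume hits the target.

    A single uniform length scale is applied to the cavity, bulbus and
    muscles (the shell thickness is left as specified), then feasibility
    of the scaled configuration is checked analytically.
    """
    spec.validate()
    a0, b0 = spec.opening_half_axes_mm
    raw = (
        math.pi * a0 * b0 * spec.apex_depth_mm / 3.0
        + 2.0 * math.pi * a0 * b0 * spec.cap_depth_mm / 3.0
    )
    s = (spec.target_volume_cm3 * 1000.0 / raw) ** (1.0 / 3.0)
    geo_a0, geo_b0 = a0 * s, b0 * s
    depth, cap = spec.apex_depth_mm * s, spec.cap_depth_mm * s
    rb = spec.bulbus_radius_mm * s
    zb = -spec.bulbus_center_depth_mm * s
    rm = spec.muscle_radius_mm * s

    bulbus_center = (0.0, 0.0, zb)
    # Rectus muscle paths: straight capsules from just anterior of the apex
    # to insertion points on the globe equator (lateral, superior, medial,
    # inferior for the default count of four).
    apex = np.array([0.0, 0.0, -depth + 2.0 * s])
    directions = [(1.0, 0.0), (0.0, 1.0), (-1.0, 0.0), (0.0, -1.0)]
    segments = []
    for dx, dy in directions[: spec.muscle_count]:
        insertion = np.array([0.95 * rb * dx, 0.95 * rb * dy, zb])
        segments.append((tuple(apex), tuple(insertion)))

    geo = OrbitGeometry(
        a0=geo_a0,
        b0=geo_b0,
        depth=depth,
        cap=cap,
        shell=spec.shell_thickness_mm,
        bulbus_radius=rb,
        bulbus_center=bulbus_center,
        muscle_radius=rm,
        muscle_segments=tuple(segments),
        scale=s,
    )
    _check_feasible(geo)
    return geo


def _check_feasible(geo: OrbitGeometry) -> None:
    """Analytic feasibility checks; raises naming the violated invariant."""
    if geo.bulbus_radius == 0.0:
        return
    # Sample the bulbus sphere surface and require every point strictly
    # inside the cavity.
    u = np.linspace(0, math.pi, 24)
    v = np.linspace(0, 2 * math.pi, 48, endpoint=False)
    uu, vv = np.meshgrid(u, v)
    pts = np.stack(
        [
            geo.bulbus_radius * np.sin(uu) * np.cos(vv) + geo.bulbus_center[0],
            geo.bulbus_radius * np.sin(uu) * np.sin(vv) + geo.bulbus_center[1],
            geo.bulbus_radius * np.cos(uu) + geo.bulbus_center[2],
        ],
        axis=-1,
    ).reshape(-1, 3)
    if not geo.contains(pts).all():
        raise GeometryError(
            "bulbus not strictly inside cavity: globe of radius "
            f"{geo.bulbus_radius:.1f} mm at depth {-geo.bulbus_center[2]:.1f} mm "
            "pierces the cavity wall"
        )


# ---------------------------------------------------------------------------
# Label volume generation
# ---------------------------------------------------------------------------


def _segment_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from each point to the line segment p0-p1 (vectorized)."""
    d = p1 - p0
    denom = float(d @ d)
    t = np.clip(((points - p0) @ d) / denom, 0.0, 1.0) if denom > 0 else 0.0
    closest = p0 + np.multiply.outer(t, d)
    return np.linalg.norm(points - closest, axis=-1)


def build_orbit(spec: OrbitSpec) -> LabelVolume:
    """Voxelize the parametric orbit into a :class:`LabelVolume`.

    Every voxel receives exactly one label from {background, bone, fat,
    muscle, bulbus}.  The cavity soft-tissue volume (fat + muscle +
    bulbus) is validated against the spec target within ``spec.volume_tol``.
    The result is a pure function of the spec — no randomness.
    """
    geo = scaled_geometry(spec)
    h = spec.voxel_spacing_mm
    t = geo.shell
    pad = 2.0 * h

    lo = np.array([-geo.a0 - t - pad, -geo.b0 - t - pad, -geo.depth - t - pad])
    hi = np.array([geo.a0 + t + pad, geo.b0 + t + pad, geo.cap + pad])
    shape = np.ceil((hi - lo) / h).astype(int)
    affine = np.eye(4)
    affine[:3, :3] *= h
    affine[:3, 3] = lo + h / 2.0  # centre of voxel (0,0,0)

    nx, ny, nz = shape
    centers = (
        np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        * h
        + affine[:3, 3]
    )

    cavity = geo.contains(centers).reshape(nx, ny, nz)

    # Bone: shell around the cavity, open anterior of the aperture plane.
    r_vox = max(int(round(t / h)), 1)
    ball = _ball_structure(r_vox)
    shell = ndimage.binary_dilation(cavity, structure=ball) & ~cavity
    zc = centers[:, 2].reshape(nx, ny, nz)
    bone = shell & (zc <= 0.0)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[bone] = Tissue.BONE
    labels[cavity] = Tissue.FAT

    flat = centers
    if spec.muscle_count > 0:
        muscle = np.zeros(nx * ny * nz, dtype=bool)
        for p0, p1 in geo.muscle_segments:
            d = _segment_distance(flat, np.asarray(p0), np.asarray(p1))
            muscle |= d <= geo.muscle_radius
        muscle = muscle.reshape(nx, ny, nz) & cavity
        labels[muscle] = Tissue.MUSCLE

    if geo.bulbus_radius > 0:
        d = np.linalg.norm(flat - np.asarray(geo.bulbus_center), axis=1)
        bulbus = (d <= geo.bulbus_radius).reshape(nx, ny, nz) & cavity
        labels[bulbus] = Tissue.BULBUS

    vol = LabelVolume(labels, affine)
    soft = vol.soft_tissue_volume_cm3()
    rel = abs(soft - spec.target_volume_cm3) / spec.target_volume_cm3
    if rel > spec.volume_tol:
        raise GeometryError(
            f"voxelized cavity volume {soft:.2f} cm^3 deviates "
            f"{100 * rel:.2f}% from target {spec.target_volume_cm3} cm^3 "
            f"(tolerance {100 * spec.volume_tol:.0f}%)"
        )
    return vol


def _ball_structure(r: int) -> np.ndarray:
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return x * x + y * y + z * z <= r * r + 1e-9


# ---------------------------------------------------------------------------
# Hounsfield-unit model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueHU:
    """Summary statistics of one tissue's HU distribution."""

    lo: float
    hi: float
    median: float
    mean: float

    def validate(self, name: str = "tissue") -> None:
        if not (self.lo <= self.median <= self.hi):
            raise ValidationError(f"{name}: median outside [min, max]")
        if not (self.lo <= self.mean <= self.hi):
            raise ValidationError(f"{name}: mean outside [min, max]")


#: Reference per-tissue HU statistics (min, max, median, mean) measured on
#: clinical orbital CT.
DEFAULT_HU_STATS: dict[Tissue, TissueHU] = {
    Tissue.BONE: TissueHU(95, 3071, 893, 813),
    Tissue.FAT: TissueHU(-207, -36, -93, -92),
    Tissue.MUSCLE: TissueHU(-50, 86, 1, 0),
    Tissue.BULBUS: TissueHU(-10, 81, 32, 32),
}

_Z995 = 2.5758293035489004  # 99.5th percentile of the standard normal


@dataclass
class HUModel:
    """Truncated-normal HU sampling model.

    For each tissue a truncated normal on ``[lo, hi]`` is fitted to the
    four reference statistics: (mu, sigma) are chosen by weighted least
    squares over the mean, the median, and the min/max interpreted as
    the 0.5th/99.5th percentiles, after which mu is refined (sigma held
    fixed) so the distribution mean matches the stated mean exactly.
    The truncated-normal family cannot represent a mean below the median
    on a lower-heavy interval (the bone case); there the mean is exact
    and the median absorbs the residual.
    """

    tissues: dict[Tissue, TissueHU] = field(
        default_factory=lambda: dict(DEFAULT_HU_STATS)
    )
    background_hu: float = -1000.0

    def __post_init__(self) -> None:
        for tissue, stats in self.tissues.items():
            stats.validate(Tissue(tissue).name.lower())
        self._fits: dict[Tissue, tuple[float, float]] = {}

    # -- fitting ----------------------------------------------------------
    def fit(self, tissue: Tissue) -> tuple[float, float]:
        """Return the fitted ``(mu, sigma)`` for a tissue (cached)."""
        if tissue not in self._fits:
            self._fits[tissue] = _fit_truncnorm(self.tissues[tissue])
        return self._fits[tissue]

    def distribution(self, tissue: Tissue):
        """The frozen scipy truncated-normal distribution for a tissue."""
        stats = self.tissues[tissue]
        mu, sigma = self.fit(tissue)
        a, b = (stats.lo - mu) / sigma, (stats.hi - mu) / sigma
        return truncnorm(a, b, loc=mu, scale=sigma)

    def sample(self, tissue: Tissue, n: int, rng: np.random.Generator) -> np.ndarray:
        stats = self.tissues[tissue]
        values = self.distribution(tissue).rvs(size=n, random_state=rng)
        return np.clip(values, stats.lo, stats.hi)


def _fit_truncnorm(stats: TissueHU) -> tuple[float, float]:
    lo, hi, med, mean = stats.lo, stats.hi, stats.median, stats.mean
    span = hi - lo
    if span == 0:
        return float(lo), 1e-9

    def _dist(mu, sigma):
        return truncnorm((lo - mu) / sigma, (hi - mu) / sigma, loc=mu, scale=sigma)

    def resid(p):
        mu, log_sigma = p
        d = _dist(mu, math.exp(log_sigma))
        q = d.ppf([0.005, 0.995])
        return [
            (d.mean() - mean) / 0.25,
            (d.median() - med) / 0.5,
            (q[0] - lo) / (0.05 * span),
            (q[1] - hi) / (0.05 * span),
        ]

    sigma0 = span / (2.0 * _Z995)
    sol = least_squares(resid, [0.5 * (med + mean), math.log(sigma0)], xtol=1e-14)
    sigma = float(math.exp(sol.x[1]))

    def mu_for_exact_mean(s: float) -> float:
        # mu such that the true truncated mean equals the stated mean
        return float(
            brentq(lambda m: _dist(m, s).mean() - mean, lo - 10 * s, hi + 10 * s,
                   xtol=1e-10)
        )

    # With the mean matched exactly, the median absorbs the family's
    # residual skew; shrink sigma moderately if that brings the true
    # median within 1.5 HU of the stated one (achievable for the
    # soft tissues, not for bone's mean < median on a lower-heavy range).
    mu = mu_for_exact_mean(sigma)
    if abs(_dist(mu, sigma).median() - med) > 1.5:
        for scale in np.arange(0.95, 0.29, -0.05):
            s_try = sigma0 * scale if sigma > sigma0 else sigma * scale
            mu_try = mu_for_exact_mean(s_try)
            if abs(_dist(mu_try, s_try).median() - med) <= 1.5:
                mu, sigma = mu_try, s_try
                break
    return mu, sigma


def render_hu(labels: LabelVolume, hu: HUModel, seed: int | None = None) -> ImageVolume:
    """Draw an HU value for every voxel from its tissue's distribution.

    Background voxels receive the configured air HU (default -1000).
    Reproducible for a fixed seed; two renders with the same seed are
    bit-identical.
    """
    present = [Tissue(v) for v in np.unique(labels.data) if v != Tissue.BACKGROUND]
    missing = [t.name.lower() for t in present if t not in hu.tissues]
    if missing:
        raise MissingDistributionError(
            f"no HU distribution for present label(s): {', '.join(missing)}"
        )
    rng = np.random.default_rng(seed)
    out = np.full(labels.shape, hu.background_hu, dtype=np.float32)
    for tissue in present:
        mask = labels.data == tissue
        out[mask] = hu.sample(tissue, int(mask.sum()), rng)
    return ImageVolume(out, labels.affine.copy())


# ---------------------------------------------------------------------------
# Resection patch planning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchPlan:
    """Nested resection-patch areas and their anchoring on the walls.

    Lateral areas are cumulative for the graded scenarios l1..l4 with the
    outermost ring l4 \\ l3 being lateral key point 1 (the deep lateral
    "lacrimal keyhole"); floor areas are cumulative for f1..f4.  Key
    point 2 is a separate small patch bridging the posterior junction of
    the lateral and floor walls (the basin of the inferior orbital
    fissure); its default area 0.44 cm^2 is the difference between the
    combined two-wall resection areas with and without it.
    """

    lateral_areas_cm2: tuple[float, ...] = (2.91, 5.55, 7.87, 9.28)
    floor_areas_cm2: tuple[float, ...] = (3.31, 6.04, 7.58, 9.69)
    kp2_area_cm2: float = 0.44
    lateral_sector_deg: tuple[float, float] = (-45.0, 45.0)
    floor_sector_deg: tuple[float, float] = (-135.0, -45.0)
    lateral_anchor_depth: float = 0.45
    floor_anchor_depth: float = 0.45
    kp2_azimuth_deg: float = -45.0
    kp2_anchor_depth: float = 0.65
    area_tol: float = 0.05

    def validate(self) -> None:
        for name, areas in (
            ("lateral", self.lateral_areas_cm2),
            ("floor", self.floor_areas_cm2),
        ):
            if any(a < 0 for a in areas):
                raise ValidationError(f"{name} areas must be >= 0")
            if any(b < a for a, b in zip(areas, areas[1:])):
                raise ValidationError(f"{name} areas must be non-decreasing (nested)")
        if self.kp2_area_cm2 < 0:
            raise ValidationError("kp2 area must be >= 0")


LATERAL_TAGS = ("l1", "l2", "l3", "l4")
FLOOR_TAGS = ("f1", "f2", "f3", "f4")


@dataclass
class PatchSet:
    """Voxel-face masks for the planned resection patches.

    Faces are encoded as integers ``(flat_voxel * 3 + axis) * 2 + side``
    where ``flat_voxel`` indexes the label grid in C order, ``axis`` in
    {0, 1, 2} and ``side`` is 1 for the +axis face.  Masks for l1..l4 and
    f1..f4 are cumulative (strictly nested); ``kp1 = l4 \\ l3`` and
    ``kp2`` are stored explicitly and are disjoint from every cumulative
    family other than their own.
    """

    masks: dict[str, np.ndarray]
    face_area_cm2: float
    shape: tuple[int, int, int]

    def area(self, tag: str) -> float:
        return len(self.masks[tag]) * self.face_area_cm2

    def rings(self) -> dict[str, np.ndarray]:
        """Disjoint per-tag face sets (nested families reduced to rings).

        The outermost lateral ring ``l4 \\ l3`` is emitted under its own
        name ``kp1``; every other ring keeps its family tag.
        """
        out: dict[str, np.ndarray] = {}
        for family in (LATERAL_TAGS, FLOOR_TAGS):
            prev: np.ndarray | None = None
            for tag in family:
                cur = self.masks[tag]
                ring = cur if prev is None else np.setdiff1d(cur, prev, assume_unique=True)
                if tag != "l4":
                    out[tag] = ring
                prev = cur
        out["kp1"] = self.masks["kp1"]
        out["kp2"] = self.masks["kp2"]
        return out


def _wall_faces(labels: LabelVolume, neighbor: Tissue) -> tuple[np.ndarray, np.ndarray]:
    """Faces between soft-tissue voxels and ``neighbor``-labelled voxels.

    Returns (face_keys, centroids_world).
    """
    from .volumes import SOFT_TISSUES

    data = labels.data
    soft = np.isin(data, SOFT_TISSUES)
    nb = data == neighbor
    keys = []
    cents = []
    shape = data.shape
    h = labels.spacing
    for axis in range(3):
        for side, shift in ((1, -1), (0, 1)):
            nb_sh = np.roll(nb, shift=shift, axis=axis)
            # roll wraps around; mask out the wrapped slab
            edge = [slice(None)] * 3
            edge[axis] = slice(-1, None) if shift == -1 else slice(0, 1)
            nb_sh[tuple(edge)] = False
            face = soft & nb_sh
            idx = np.argwhere(face)
            if idx.size == 0:
                continue
            flat = np.ravel_multi_index(idx.T, shape)
            keys.append((flat * 3 + axis) * 2 + side)
            offset = np.zeros(3)
            offset[axis] = 0.5 if side == 1 else -0.5
            cents.append(labels.index_to_world(idx + offset))
    if not keys:
        return np.empty(0, dtype=np.int64), np.empty((0, 3))
    return np.concatenate(keys), np.concatenate(cents)


def plan_patches(
    labels: LabelVolume, plan: PatchPlan, geometry: OrbitGeometry | None = None,
    spec: OrbitSpec | None = None,
) -> PatchSet:
    """Lay out the nested resection patches on the bone-cavity interface.

    Patches grow greedily outwards from a wall anchor: candidate faces in
    a wall's azimuthal sector are sorted by distance from the anchor and
    accumulated until the requested area is met (choosing the face count
    whose cumulative area is closest).  Nesting of the cumulative masks
    is therefore exact set inclusion, and ``area(l4) - area(l3) ==
    area(kp1)`` holds exactly on the same discretization.
    """
    plan.validate()
    if geometry is None:
        geometry = scaled_geometry(spec if spec is not None else OrbitSpec(
            voxel_spacing_mm=float(labels.spacing[0])
        ))
    keys, cents = _wall_faces(labels, Tissue.BONE)
    if keys.size == 0:
        raise PatchAreaError("no bone-cavity interface faces found")
    h = float(labels.spacing[0])
    face_area_cm2 = h * h / 100.0
    azimuth = np.degrees(np.arctan2(cents[:, 1], cents[:, 0]))

    masks: dict[str, np.ndarray] = {}
    used = np.zeros(keys.shape[0], dtype=bool)

    for wall, tags, areas, sector, anchor_depth, anchor_az in (
        (
            "lateral",
            LATERAL_TAGS,
            plan.lateral_areas_cm2,
            plan.lateral_sector_deg,
            plan.lateral_anchor_depth,
            0.0,
        ),
        (
            "floor",
            FLOOR_TAGS,
            plan.floor_areas_cm2,
            plan.floor_sector_deg,
            plan.floor_anchor_depth,
            -90.0,
        ),
    ):
        in_sector = (azimuth >= sector[0]) & (azimuth < sector[1])
        cand = np.flatnonzero(in_sector)
        anchor = geometry.wall_radius(anchor_az, anchor_depth)
        order = cand[np.argsort(np.linalg.norm(cents[cand] - anchor, axis=1))]
        counts = _nested_counts(
            [a for a in areas], face_area_cm2, order.size, wall, plan.area_tol
        )
        prev = 0
        for tag, n in zip(tags, counts):
            masks[tag] = np.sort(keys[order[:n]])
            prev = n
        used[order[:counts[-1]]] = True

    masks["kp1"] = np.setdiff1d(masks["l4"], masks["l3"], assume_unique=True)

    # kp2: bridge at the posterior lateral-floor junction, disjoint from
    # the two cumulative families.
    cand = np.flatnonzero(~used)
    anchor = geometry.wall_radius(plan.kp2_azimuth_deg, plan.kp2_anchor_depth)
    order = cand[np.argsort(np.linalg.norm(cents[cand] - anchor, axis=1))]
    counts = _nested_counts(
        [plan.kp2_area_cm2], face_area_cm2, order.size, "lateral-floor junction",
        plan.area_tol,
    )
    masks["kp2"] = np.sort(keys[order[: counts[0]]])

    return PatchSet(masks=masks, face_area_cm2=face_area_cm2, shape=labels.shape)


def _nested_counts(
    areas_cm2: list[float],
    face_area_cm2: float,
    available: int,
    wall: str,
    tol: float,
) -> list[int]:
    counts = []
    prev = 0
    for a in areas_cm2:
        n = int(round(a / face_area_cm2))
        if a > 0:
            n = max(n, prev + 1, 1)
        if n > available:
            raise PatchAreaError(
                f"requested area {a:.2f} cm^2 exceeds available {wall} wall "
                f"area {available * face_area_cm2:.2f} cm^2"
            )
        realized = n * face_area_cm2
        if a > 0 and abs(realized - a) / a > tol:
            raise PatchAreaError(
                f"{wall} patch of {a:.2f} cm^2 realized as {realized:.2f} cm^2 "
                f"(> {100 * tol:.0f}% off) at this voxel spacing"
            )
        counts.append(n)
        prev = n
    return counts
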