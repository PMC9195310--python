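"""Linear-elastic finite element solver on labelled tetrahedral meshes.

The constitutive model is isotropic, homogeneous-per-tissue Hooke
elasticity in the linearized (small-strain) regime,

    sigma(eps) = E / (1 + nu) * (eps + nu / (1 - 2 nu) * tr(eps) * I),

with a reference modulus ``E`` (fat tissue, normalized to 1), Poisson
ratio ``nu``, and per-tissue stiffness multipliers (muscle and bulbus
stiffer than fat by a configurable ratio).  Because only the ratio of
surface traction to modulus enters the displacement field, tractions
are expressed in the same normalized units as ``E``.

Discretization: 4-node constant-strain tetrahedra.  Dirichlet
conditions fix soft-tissue nodes along intact bone; resected patches
receive dead-load tractions along the undeformed outward surface
normal with consistent (area/3 per node) lumping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import DegenerateElementError, SolverError, ValidationError
from .meshing import TetMesh
from .volumes import Tissue

__all__ = [
    "MaterialModel",
    "LoadCase",
    "BoundaryConditions",
    "DisplacementField",
    "hooke_stress",
    "elastic_matrix",
    "element_stiffness",
    "assemble_stiffness",
    "assemble_loads",
    "build_boundary_conditions",
    "assemble_and_solve",
    "ElasticSystem",
    "element_strains",
    "element_stresses",
]


@dataclass(frozen=True)
class MaterialModel:
    """Reference modulus, Poisson ratio and per-tissue stiffness ratios.

    Defaults are the calibrated values of the decompression model:
    relative muscle stiffness 5 (the bulbus inherits the muscle ratio)
    and effective Poisson ratio 0.1.  ``E`` is a normalized reference
    modulus for fat; absolute stiffness is unidentifiable from volume
    data, so tractions carry the scale.
    """

    E: float = 1.0
    nu: float = 0.1
    multipliers: dict[int, float] = field(
        default_factory=lambda: {
            int(Tissue.FAT): 1.0,
            int(Tissue.MUSCLE): 5.0,
            int(Tissue.BULBUS): 5.0,
        }
    )

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValidationError("E must be > 0")
        if not (0.0 <= self.nu < 0.5):
            raise ValidationError(
                f"Poisson ratio must be in [0, 0.5), got {self.nu} "
                "(incompressible limit unsupported)"
            )
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValidationError("stiffness multipliers must be > 0")

    def modulus_for(self, label: int) -> float:
        return self.E * self.multipliers.get(int(label), 1.0)


@dataclass(frozen=True)
class LoadCase:
    """Outward-normal surface tractions per boundary patch tag.

    ``tractions`` maps ring tags to traction magnitude (normalized
    force/area); positive values pull the surface along the undeformed
    outward normal, modelling the pressure-driven outflow of orbital
    tissue through a resected wall.
    """

    tractions: dict[str, float]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.tractions.values()):
            raise ValidationError("traction magnitudes must be >= 0")


@dataclass(frozen=True)
class BoundaryConditions:
    """Fixed dofs (with values) and the assembled nodal load vector."""

    fixed_dofs: np.ndarray
    fixed_values: np.ndarray
    forces: np.ndarray


@dataclass(frozen=True)
class DisplacementField:
    """Per-node displacement vectors in mm."""

    u: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.u).all():
            raise ValidationError("displacement field contains non-finite values")


# ---------------------------------------------------------------------------
# Constitutive law
# ---------------------------------------------------------------------------


def hooke_stress(strain: np.ndarray, material: MaterialModel) -> np.ndarray:
    """Cauchy stress from linearized strain for the Hooke material."""
    eps = np.asarray(strain, dtype=float)
    e, nu = material.E, material.nu
    return e / (1.0 + nu) * (eps + nu / (1.0 - 2.0 * nu) * np.trace(eps) * np.eye(3))


def elastic_matrix(e: float, nu: float) -> np.ndarray:
    """6x6 elasticity matrix in Voigt order (xx, yy, zz, xy, yz, zx).

    Engineering shear strains are used, so the shear diagonal carries
    the shear modulus ``mu = E / (2 (1 + nu))``.
    """
    lam = e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = e / (2.0 * (1.0 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] += 2.0 * mu
    d[np.arange(3, 6), np.arange(3, 6)] = mu
    return d


def _grads_volumes(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (m, 4, 3) and volumes (m,) per element."""
    p = nodes[tets]  # (m, 4, 3)
    m = np.concatenate([np.ones((p.shape[0], 4, 1)), p], axis=2)  # (m, 4, 4)
    det = np.linalg.det(m)
    vols = det / 6.0
    if (vols <= 0).any():
        raise DegenerateElementError(
            f"{int((vols <= 0).sum())} tetrahedra have non-positive volume"
        )
    inv = np.linalg.inv(m)
    grads = inv[:, 1:4, :].transpose(0, 2, 1)  # dN_i/dx_j
    return grads, vols


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (m, 6, 12), Voigt engineering shear."""
    m = grads.shape[0]
    b = np.zeros((m, 6, 12))
    gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
    cols = np.arange(4) * 3
    b[:, 0, cols + 0] = gx
    b[:, 1, cols + 1] = gy
    b[:, 2, cols + 2] = gz
    b[:, 3, cols + 0] = gy
    b[:, 3, cols + 1] = gx
    b[:, 4, cols + 1] = gz
    b[:, 4, cols + 2] = gy
    b[:, 5, cols + 0] = gz
    b[:, 5, cols + 2] = gx
    return b


def element_stiffness(
    coords: np.ndarray, material: MaterialModel, label: int = int(Tissue.FAT)
) -> np.ndarray:
    """12x12 stiffness of a single constant-strain tetrahedron."""
    coords = np.asarray(coords, dtype=float).reshape(1, 4, 3)
    grads, vols = _grads_volumes(coords.reshape(4, 3), np.arange(4).reshape(1, 4))
    if vols[0] <= 0:
        raise DegenerateElementError(
            f"tetrahedron has non-positive volume {vols[0]:.3e}"
        )
    b = _b_matrices(grads)[0]
    d = elastic_matrix(material.modulus_for(label), material.nu)
    return vols[0] * b.T @ d @ b


def assemble_stiffness(mesh: TetMesh, material: MaterialModel) -> sp.csr_matrix:
    """Global stiffness matrix (3n x 3n, CSR) for the labelled mesh."""
    grads, vols = _grads_volumes(mesh.nodes, mesh.tets)
    if (vols <= 0).any():
        raise DegenerateElementError("mesh contains non-positive elements")
    b = _b_matrices(grads)
    d_unit = elastic_matrix(1.0, material.nu)
    lut = {int(l): material.modulus_for(l) for l in np.unique(mesh.tet_labels)}
    scale = np.vectorize(lut.get)(mesh.tet_labels.astype(int)) * vols
    ke = np.einsum("mji,jk,mkl->mil", b, d_unit, b) * scale[:, None, None]

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return k


def assemble_loads(mesh: TetMesh, tractions: dict[str, float]) -> np.ndarray:
    """Consistent nodal forces from per-tag outward-normal tractions.

    Each loaded triangle distributes ``traction * area / 3`` to each of
    its nodes along the (undeformed) outward normal.
    """
    f = np.zeros(3 * mesh.n_nodes)
    if not tractions:
        return f
    areas = mesh.boundary_areas()
    for tag, p in tractions.items():
        if p == 0.0:
            continue
        sel = np.flatnonzero(mesh.boundary_tags == tag)
        if sel.size == 0:
            continue
        force = (p / 3.0) * areas[sel, None] * mesh.boundary_normals[sel]  # (s, 3)
        nodes = mesh.boundary_tris[sel]  # (s, 3)
        dofs = (3 * nodes[:, :, None] + np.arange(3)).reshape(-1)
        np.add.at(f, dofs, np.repeat(force, 3, axis=0).reshape(-1))
    return f


def build_boundary_conditions(
    mesh: TetMesh, load: LoadCase, resected: frozenset[str] | set[str]
) -> BoundaryConditions:
    """Dirichlet fixation on bone-backed boundary outside the resection.

    All soft-tissue nodes on bone-backed boundary triangles whose tag is
    not in ``resected`` are fixed to zero displacement (the tissue is
    tethered to intact bone, including at patch rims, where Dirichlet
    wins over the traction load).  Triangles of resected tags carry the
    tractions of ``load``; the anterior opening is traction-free.
    """
    resected = set(resected)
    bone_backed = mesh.boundary_tags != "opening"
    fixed_tris = bone_backed & ~np.isin(mesh.boundary_tags, sorted(resected))
    fixed_nodes = np.unique(mesh.boundary_tris[fixed_tris])
    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    tractions = {t: p for t, p in load.tractions.items() if t in resected}
    forces = assemble_loads(mesh, tractions)
    return BoundaryConditions(
        fixed_dofs=fixed_dofs,
        fixed_values=np.zeros(fixed_dofs.shape[0]),
        forces=forces,
    )


def solve_constrained(
    k: sp.csr_matrix,
    f: np.ndarray,
    fixed_dofs: np.ndarray,
    fixed_values: np.ndarray,
    tol: float = 1e-8,
) -> np.ndarray:
    """Solve K u = f with prescribed dofs eliminated; check the residual."""
    n = k.shape[0]
    if fixed_dofs.size == 0:
        raise SolverError("no Dirichlet constraints; the system is singular")
    free = np.setdiff1d(np.arange(n), fixed_dofs, assume_unique=False)
    kff = k[free][:, free].tocsc()
    rhs = f[free] - k[free][:, fixed_dofs] @ fixed_values
    try:
        lu = spla.splu(kff)
        uf = lu.solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - factorization failure
        raise SolverError(f"sparse factorization failed: {exc}") from exc
    denom = max(float(np.linalg.norm(rhs)), 1e-30)
    resid = float(np.linalg.norm(kff @ uf - rhs)) / denom
    if resid > tol:
        raise SolverError(f"solver residual {resid:.2e} exceeds tolerance {tol:.1e}")
    u = np.zeros(n)
    u[free] = uf
    u[fixed_dofs] = fixed_values
    return u


def assemble_and_solve(
    mesh: TetMesh,
    material: MaterialModel,
    load: LoadCase,
    resected: frozenset[str] | set[str],
    tol: float = 1e-8,
) -> DisplacementField:
    """Assemble and solve the elastostatic problem for one scenario."""
    system = ElasticSystem(mesh, material, resected, tol=tol)
    return system.solve(load)


class ElasticSystem:
    """Factorized elastic operator for repeated load cases.

    The stiffness matrix and its boundary conditions depend only on the
    material and the set of resected tags, so grid searches over
    traction magnitudes reuse one factorization and superpose unit-load
    solutions.
    """

    def __init__(
        self,
        mesh: TetMesh,
        material: MaterialModel,
        resected: frozenset[str] | set[str],
        tol: float = 1e-8,
        stiffness: sp.csr_matrix | None = None,
    ) -> None:
        self.mesh = mesh
        self.material = material
        self.resected = frozenset(resected)
        self.tol = tol
        k = assemble_stiffness(mesh, material) if stiffness is None else stiffness
        bc = build_boundary_conditions(mesh, LoadCase(tractions={}), resected)
        if bc.fixed_dofs.size == 0:
            raise SolverError("no Dirichlet constraints; the system is singular")
        self._fixed = bc.fixed_dofs
        n = k.shape[0]
        self._free = np.setdiff1d(np.arange(n), self._fixed)
        self._kff = k[self._free][:, self._free].tocsc()
        self._lu = spla.splu(self._kff)
        self._n = n

    def solve_forces(self, f: np.ndarray) -> np.ndarray:
        rhs = f[self._free]
        uf = self._lu.solve(rhs)
        denom = max(float(np.linalg.norm(rhs)), 1e-30)
        resid = float(np.linalg.norm(self._kff @ uf - rhs)) / denom
        if rhs.any() and resid > self.tol:
            raise SolverError(
                f"solver residual {resid:.2e} exceeds tolerance {self.tol:.1e}"
            )
        u = np.zeros(self._n)
        u[self._free] = uf
        return u

    def solve(self, load: LoadCase) -> DisplacementField:
        tractions = {t: p for t, p in load.tractions.items() if t in self.resected}
        f = assemble_loads(self.mesh, tractions)
        u = self.solve_forces(f)
        return DisplacementField(u.reshape(-1, 3))


# ---------------------------------------------------------------------------
# Derived element fields
# ---------------------------------------------------------------------------


def element_strains(mesh: TetMesh, field_: DisplacementField) -> np.ndarray:
    """Linearized strain tensor per element, shape (m, 3, 3)."""
    grads, _ = _grads_volumes(mesh.nodes, mesh.tets)
    ue = field_.u[mesh.tets]  # (m, 4, 3)
    g = np.einsum("mai,maj->mij", ue, grads)  # du_i/dx_j
    return 0.5 * (g + g.transpose(0, 2, 1))


def element_stresses(
    mesh: TetMesh, field_: DisplacementField, material: MaterialModel
) -> np.ndarray:
    eps = element_strains(mesh, field_)
    tr = np.trace(eps, axis1=1, axis2=2)
    e_el = np.array([material.modulus_for(l) for l in mesh.tet_labels])
    nu = material.nu
    eye = np.eye(3)[None]
    return (e_el / (1 + nu))[:, None, None] * (
        eps + (nu / (1 - 2 * nu)) * tr[:, None, None] * eye
    )
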