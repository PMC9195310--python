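"""Shared fixtures and small mesh-construction helpers.

Heavy artifacts (the synthetic orbit at different resolutions, the full
scenario sweep) are session-scoped so the whole suite builds each of
them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from orbitmech import HUModel, OrbitSpec, PatchPlan, build_orbit, render_hu
from orbitmech.analysis import WallPressures, build_report, run_scenarios
from orbitmech.elasticity import MaterialModel
from orbitmech.pipeline import build_simulation
from orbitmech.volumes import LabelVolume, Tissue

RENDER_SEED = 20260  # fixed seed for every pseudo-CT rendered in the suite


# ---------------------------------------------------------------------------
# Mesh-construction helpers (importable from test modules via `conftest`)
# ---------------------------------------------------------------------------


def block_labels(nx: int, ny: int, nz: int, h: float = 1.0,
                 tissue: Tissue = Tissue.FAT) -> LabelVolume:
    """A solid block of one soft tissue; node lattice planes at multiples of h."""
    data = np.full((nx, ny, nz), int(tissue), dtype=np.uint8)
    aff = np.eye(4)
    aff[:3, :3] *= h
    aff[:3, 3] = h / 2.0  # voxel corners sit exactly on 0, h, 2h, ...
    return LabelVolume(data, aff)


def mask_labels(mask: np.ndarray, h: float = 1.0,
                tissue: Tissue = Tissue.FAT) -> LabelVolume:
    data = np.where(mask, int(tissue), 0).astype(np.uint8)
    aff = np.eye(4)
    aff[:3, :3] *= h
    aff[:3, 3] = h / 2.0
    return LabelVolume(data, aff)


def octant_shell_mesh(h: float, a: float = 10.0, b: float = 20.0):
    """One octant of a thick spherical shell, boundary faces tagged
    inner / outer / sym (coordinate symmetry planes)."""
    from orbitmech.meshing import voxels_to_tetmesh

    n = int(np.ceil((b + 2 * h) / h))
    c = (np.arange(n) + 0.5) * h
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    labels = mask_labels((r >= a) & (r <= b), h=h)
    mesh = voxels_to_tetmesh(labels)
    cent = mesh.nodes[mesh.boundary_tris].mean(axis=1)
    axis = np.argmax(np.abs(mesh.boundary_normals), axis=1)
    plane = cent[np.arange(len(axis)), axis]
    sym = np.abs(plane) < h / 4
    rc = np.linalg.norm(cent, axis=1)
    inner = (~sym) & (rc < (a + b) / 2)
    mesh.boundary_tags = np.where(
        sym, "sym", np.where(inner, "inner", "outer")
    ).astype("<U12")
    return mesh


def symmetry_fixed_dofs(mesh, h: float) -> np.ndarray:
    """Roller constraints (normal dof fixed) on the three coordinate planes."""
    fixed = [
        3 * np.flatnonzero(np.abs(mesh.nodes[:, k]) < h / 4) + k for k in range(3)
    ]
    return np.unique(np.concatenate(fixed))


# ---------------------------------------------------------------------------
# Session fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def hu_model() -> HUModel:
    return HUModel()


@pytest.fixture(scope="session")
def orbit_1mm() -> LabelVolume:
    """Default synthetic orbit at the native 1 mm spacing."""
    return build_orbit(OrbitSpec())


@pytest.fixture(scope="session")
def pseudo_ct(orbit_1mm, hu_model):
    return render_hu(orbit_1mm, hu_model, seed=RENDER_SEED)


@pytest.fixture(scope="session")
def world_2mm():
    """Tagged simulation world at 2 mm, the resolution of the scenario runs."""
    return build_simulation(spacing_mm=2.0)


@pytest.fixture(scope="session")
def material() -> MaterialModel:
    return MaterialModel()


@pytest.fixture(scope="session")
def pressures() -> WallPressures:
    return WallPressures()


@pytest.fixture(scope="session")
def scenario_report(world_2mm, material, pressures):
    """All ten graded resection scenarios solved once, as a report table."""
    results = run_scenarios(world_2mm.mesh, material, pressures)
    return build_report(results)
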