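"""End-to-end helpers tying the pipeline stages together.

These are the entry points the analysis drivers, the command-line
interface and the test suite share: build the synthetic world once, get
back a tagged tetrahedral mesh ready for scenario simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .anatomy import (
    HUModel,
    OrbitGeometry,
    OrbitSpec,
    PatchPlan,
    PatchSet,
    build_orbit,
    plan_patches,
    render_hu,
    scaled_geometry,
)
from .meshing import TetMesh, tag_boundary, voxels_to_tetmesh
from .volumes import ImageVolume, LabelVolume


@dataclass
class SimulationWorld:
    """Everything the scenario analysis needs, built from one spec."""

    spec: OrbitSpec
    geometry: OrbitGeometry
    labels: LabelVolume
    patches: PatchSet
    mesh: TetMesh
    image: ImageVolume | None = None


def build_simulation(
    spec: OrbitSpec | None = None,
    plan: PatchPlan | None = None,
    spacing_mm: float | None = None,
    hu: HUModel | None = None,
    render_seed: int | None = None,
) -> SimulationWorld:
    """Build orbit labels, patch plan and a tagged soft-tissue mesh.

    ``spacing_mm`` overrides the spec's voxel spacing (coarser grids for
    FEM work, fine grids for image statistics).  When ``hu`` is given, a
    pseudo-CT is rendered with ``render_seed`` (or the spec seed).
    """
    spec = spec or OrbitSpec()
    if spacing_mm is not None:
        spec = spec.with_spacing(spacing_mm)
        if spec.shell_thickness_mm < spacing_mm:
            # the shell only provides the rigid bone boundary; keep it at
            # least one voxel thick on coarse grids
            spec = replace(spec, shell_thickness_mm=spacing_mm)
    plan = plan or PatchPlan()
    geometry = scaled_geometry(spec)
    labels = build_orbit(spec)
    patches = plan_patches(labels, plan, geometry=geometry)
    mesh = tag_boundary(voxels_to_tetmesh(labels), patches)
    image = None
    if hu is not None:
        seed = spec.seed if render_seed is None else render_seed
        image = render_hu(labels, hu, seed)
    return SimulationWorld(
        spec=spec, geometry=geometry, labels=labels, patches=patches,
        mesh=mesh, image=image,
    )
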