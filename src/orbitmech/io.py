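"""Format round-tripping: NIfTI volumes, VTK meshes, STL surfaces,
landmark CSVs, transforms, reports, YAML configs and provenance sidecars.

All artifacts written by this module can be read back losslessly (data
to machine precision, labels and tags exactly).  Deterministic stages
produce byte-identical files on re-runs with equal provenance, so no
timestamps are embedded anywhere.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FormatError
from .meshing import TetMesh
from .registration import LandmarkSet, RigidTransform
from .volumes import ImageVolume, LabelVolume


# -- NIfTI ------------------------------------------------------------------


def write_nifti(volume: ImageVolume | LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    data = volume.data
    if isinstance(volume, LabelVolume):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume.affine)
    img.to_filename(str(path))
    return path


def read_image_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float32), img.affine)


def read_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    return LabelVolume(np.asarray(img.dataobj).astype(np.uint8), img.affine)


# -- VTK (legacy ASCII unstructured grid) -----------------------------------


def write_mesh_vtk(
    mesh: TetMesh, path: str | Path, point_data: dict[str, np.ndarray] | None = None
) -> Path:
    """Write tets + element labels (+ optional point vectors, e.g. u)."""
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_tets
    lines = [
        "# vtk DataFile Version 3.0",
        "orbitmech tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{v:.17g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    lines.append(f"CELL_TYPES {m}")
    lines += ["10"] * m
    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS tissue int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(l)) for l in mesh.tet_labels]
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.shape != (n, 3):
                raise FormatError(f"point data {name!r} must have shape ({n}, 3)")
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{v:.17g}" for v in p) for p in arr]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_mesh_vtk(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Read back nodes, tets, labels and point data from a legacy VTK file."""
    tokens = Path(path).read_text().split("\n")
    i = 0

    def expect(prefix: str) -> str:
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        if i >= len(tokens) or not tokens[i].startswith(prefix):
            raise FormatError(
                f"{path}: expected {prefix!r} at line {i + 1}, got "
                f"{tokens[i][:40]!r}" if i < len(tokens) else f"{path}: truncated"
            )
        line = tokens[i]
        i += 1
        return line

    expect("# vtk DataFile")
    i += 1  # title
    expect("ASCII")
    expect("DATASET UNSTRUCTURED_GRID")
    n = int(expect("POINTS").split()[1])
    nodes = np.array([tokens[i + j].split() for j in range(n)], dtype=float)
    i += n
    m = int(expect("CELLS").split()[1])
    cells = np.array([tokens[i + j].split() for j in range(m)], dtype=int)
    if (cells[:, 0] != 4).any():
        raise FormatError(f"{path}: non-tetrahedral cell found")
    tets = cells[:, 1:]
    i += m
    expect("CELL_TYPES")
    i += m
    labels = np.array([], dtype=np.uint8)
    point_data: dict[str, np.ndarray] = {}
    while i < len(tokens):
        line = tokens[i].strip()
        i += 1
        if not line:
            continue
        if line.startswith("CELL_DATA"):
            expect("SCALARS")
            expect("LOOKUP_TABLE")
            labels = np.array(tokens[i : i + m], dtype=np.uint8)
            i += m
        elif line.startswith("POINT_DATA"):
            continue
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            point_data[name] = np.array(
                [tokens[i + j].split() for j in range(n)], dtype=float
            )
            i += n
        else:
            raise FormatError(f"{path}: unexpected section {line[:40]!r}")
    return nodes, tets, labels, point_data


def write_boundary_stl(mesh: TetMesh, tag: str, path: str | Path) -> Path:
    """Export one boundary patch (or the whole surface with tag=None) as STL."""
    import trimesh

    from .meshing import expand_tag

    sel = np.isin(mesh.boundary_tags, expand_tag(tag))
    tris = mesh.boundary_tris[sel]
    surf = trimesh.Trimesh(vertices=mesh.nodes, faces=tris, process=False)
    surf.export(str(path))
    return Path(path)


def write_boundary_tags_json(mesh: TetMesh, path: str | Path) -> Path:
    """Sidecar mapping each boundary face key to its patch tag."""
    payload = {
        "face_keys": mesh.boundary_face_keys.tolist(),
        "tags": mesh.boundary_tags.tolist(),
    }
    Path(path).write_text(json.dumps(payload))
    return Path(path)


# -- landmarks & transforms -------------------------------------------------


def read_landmarks(source_csv: str | Path, target_csv: str | Path) -> LandmarkSet:
    """Pair two ``id,x,y,z`` CSV files by landmark id."""
    src = pd.read_csv(source_csv).set_index("id")
    tgt = pd.read_csv(target_csv).set_index("id")
    common = src.index.intersection(tgt.index)
    if len(common) < 3:
        raise FormatError("fewer than 3 shared landmark ids between the files")
    cols = ["x", "y", "z"]
    return LandmarkSet(src.loc[common, cols].to_numpy(), tgt.loc[common, cols].to_numpy())


def write_landmarks(points: np.ndarray, path: str | Path) -> Path:
    df = pd.DataFrame(points, columns=["x", "y", "z"])
    df.insert(0, "id", np.arange(len(df)))
    df.to_csv(path, index=False)
    return Path(path)


def write_transform(tf: RigidTransform, rmsd: float, path: str | Path) -> Path:
    payload = {"matrix": tf.matrix.tolist(), "rmsd_mm": rmsd}
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def read_transform(path: str | Path) -> tuple[RigidTransform, float]:
    payload = json.loads(Path(path).read_text())
    m = np.asarray(payload["matrix"], dtype=float)
    if m.shape != (4, 4):
        raise FormatError(f"{path}: transform matrix must be 4x4")
    return RigidTransform(m[:3, :3], m[:3, 3]), float(payload["rmsd_mm"])


# -- reports, configs, provenance -------------------------------------------


def write_report(df: pd.DataFrame, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    df.to_csv(csv_path, index=False)
    csv_path.with_suffix(".json").write_text(
        df.to_json(orient="records", indent=1)
    )
    return csv_path


def read_report(csv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def write_yaml(obj: dict, path: str | Path) -> Path:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
    return Path(path)


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def provenance(config: dict, seed: int | None) -> dict:
    """Provenance block stamped next to every artifact: config hash,
    seed, package version.  No timestamps, so reruns are byte-identical."""
    canonical = yaml.safe_dump(config, sort_keys=True)
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }


def write_provenance(path: str | Path, config: dict, seed: int | None) -> Path:
    sidecar = Path(str(path) + ".provenance.json")
    sidecar.write_text(json.dumps(provenance(config, seed), indent=1, sort_keys=True))
    return sidecar
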