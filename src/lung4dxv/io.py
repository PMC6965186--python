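"""Readers and writers: TIFF/NIfTI volumes, projection sets, trees, fields.

Formats
-------
* 3D volumes: multi-page TIFF stacks (``.tif``/``.tiff``, via tifffile)
  or NIfTI (``.nii``/``.nii.gz``, via nibabel; voxel size carried in the
  affine/zooms).
* 4D series: one file per phase, zero-padded phase index in the
  filename, plus a JSON sidecar with phase times and voxel size.
* Projection sets: TIFF stack + sidecar CSV with columns
  ``frame_index, angle_deg, phase_tag``.
* Airway trees: legacy-ASCII VTK polylines (points + radius, generation
  and optional per-segment scalars), a CSV edge list, and a JSON
  round-trip format.
* Displacement/expansion fields: CSV (node coords, vector, quality,
  flags) and VTK image data for visualization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
import tifffile

from .core import AirwaySegment, AirwayTree, Volume4D
from .gated_recon import ProjectionSet
from .velocimetry import DisplacementField, ExpansionField, GridSpec

__all__ = [
    "UnsupportedFormatError",
    "read_volume",
    "write_volume",
    "read_volume4d",
    "write_volume4d",
    "read_projections",
    "write_projections",
    "tree_to_vtk",
    "tree_to_csv",
    "tree_to_json",
    "tree_from_json",
    "field_to_csv",
    "expansion_to_vtk",
]

_TIFF_EXT = (".tif", ".tiff")
_NIFTI_EXT = (".nii", ".nii.gz")


class UnsupportedFormatError(ValueError):
    """File extension not among the supported volume formats."""


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_EXT)


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in _TIFF_EXT


def write_volume(path: str | Path, volume: np.ndarray, voxel_size: float = 1.0) -> None:
    """Write a 3D volume as a TIFF stack or NIfTI (by extension).

    NIfTI stores ``voxel_size`` in the affine; TIFF stacks carry it in
    the ImageJ-style metadata (best effort).
    """
    path = Path(path)
    volume = np.asarray(volume)
    if _is_tiff(path):
        tifffile.imwrite(
            path, volume, metadata={"spacing": voxel_size, "unit": "um"}, imagej=False
        )
    elif _is_nifti(path):
        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        nib.save(nib.Nifti1Image(np.asanyarray(volume), affine), str(path))
    else:
        raise UnsupportedFormatError(
            f"unsupported volume format {path.suffix!r} (use .tif/.tiff or .nii/.nii.gz)"
        )


def read_volume(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a 3D volume; returns (array, voxel_size).

    Voxel size defaults to 1.0 for formats that do not carry it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if _is_tiff(path):
        return np.asarray(tifffile.imread(path)), 1.0
    if _is_nifti(path):
        img = nib.load(str(path))
        vox = float(img.header.get_zooms()[0])
        return np.asarray(img.dataobj), vox
    raise UnsupportedFormatError(
        f"unsupported volume format {path.suffix!r} (use .tif/.tiff or .nii/.nii.gz)"
    )


def write_volume4d(
    directory: str | Path, vol4d: Volume4D, fmt: str = "tif", prefix: str = "phase"
) -> list[Path]:
    """Write one volume per phase (zero-padded index) plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(2, len(str(vol4d.n_phases - 1)))
    paths = []
    for i in range(vol4d.n_phases):
        p = directory / f"{prefix}_{i:0{width}d}.{fmt}"
        write_volume(p, vol4d.phase(i), vol4d.voxel_size)
        paths.append(p)
    meta = {
        "voxel_size": vol4d.voxel_size,
        "phase_times_ms": vol4d.phase_times.tolist(),
        "files": [p.name for p in paths],
    }
    (directory / f"{prefix}_series.json").write_text(json.dumps(meta, indent=2))
    return paths


def read_volume4d(directory: str | Path, prefix: str = "phase") -> Volume4D:
    directory = Path(directory)
    meta_path = directory / f"{prefix}_series.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"series sidecar not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    vols = [read_volume(directory / name)[0] for name in meta["files"]]
    return Volume4D(
        np.stack(vols),
        voxel_size=meta["voxel_size"],
        phase_times=np.array(meta["phase_times_ms"]),
    )


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def write_projections(stack_path: str | Path, meta_path: str | Path,
                      projections: ProjectionSet) -> None:
    tifffile.imwrite(Path(stack_path), np.asarray(projections.images, dtype=np.float32))
    pd.DataFrame(
        {
            "frame_index": np.arange(len(projections)),
            "angle_deg": projections.angles,
            "phase_tag": projections.phase_tags,
        }
    ).to_csv(meta_path, index=False)


def read_projections(stack_path: str | Path, meta_path: str | Path) -> ProjectionSet:
    stack_path, meta_path = Path(stack_path), Path(meta_path)
    for p in (stack_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"projection input not found: {p}")
    images = np.asarray(tifffile.imread(stack_path))
    meta = pd.read_csv(meta_path).sort_values("frame_index")
    return ProjectionSet(
        images=images,
        angles=meta["angle_deg"].to_numpy(),
        phase_tags=meta["phase_tag"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def tree_to_vtk(
    path: str | Path,
    tree: AirwayTree,
    segment_scalars: dict[str, dict[int, float]] | None = None,
) -> None:
    """Write the tree as legacy-ASCII VTK polylines.

    Point data: ``radius`` and ``generation`` always; any entry of
    ``segment_scalars`` (name -> {segment_id: value}) is broadcast to the
    segment's centerline points — e.g. cumulative air volume per phase,
    or the expiratory time constant.
    """
    pts = []
    lines = []
    radius = []
    generation = []
    extra: dict[str, list[float]] = {k: [] for k in (segment_scalars or {})}
    offset = 0
    for sid in sorted(tree.segments):
        seg = tree.segments[sid]
        n = len(seg.points)
        # VTK point order (x, y, z)
        pts.extend(seg.points[:, ::-1].tolist())
        lines.append(list(range(offset, offset + n)))
        radius.extend(seg.radii.tolist())
        generation.extend([seg.generation] * n)
        for name, mapping in (segment_scalars or {}).items():
            extra[name].extend([mapping.get(sid, 0.0)] * n)
        offset += n

    out = ["# vtk DataFile Version 3.0", "airway tree", "ASCII", "DATASET POLYDATA"]
    out.append(f"POINTS {len(pts)} float")
    out.extend(" ".join(f"{v:.4f}" for v in p) for p in pts)
    total = sum(len(l) + 1 for l in lines)
    out.append(f"LINES {len(lines)} {total}")
    out.extend(f"{len(l)} " + " ".join(map(str, l)) for l in lines)
    out.append(f"POINT_DATA {len(pts)}")
    for name, vals in [("radius", radius), ("generation", generation)] + list(extra.items()):
        out.append(f"SCALARS {name} float 1")
        out.append("LOOKUP_TABLE default")
        out.extend(f"{v:.6g}" for v in vals)
    Path(path).write_text("\n".join(out) + "\n")


def tree_to_csv(path: str | Path, tree: AirwayTree) -> None:
    """CSV edge list: segment_id, parent_id, generation, length, mean_radius."""
    rows = []
    for sid in sorted(tree.segments):
        seg = tree.segments[sid]
        rows.append(
            {
                "segment_id": seg.id,
                "parent_id": -1 if seg.parent_id is None else seg.parent_id,
                "generation": seg.generation,
                "length": seg.length,
                "mean_radius": seg.mean_radius,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def tree_to_json(path: str | Path, tree: AirwayTree) -> None:
    data = {
        "root_id": tree.root_id,
        "segments": [
            {
                "id": s.id,
                "parent_id": s.parent_id,
                "generation": s.generation,
                "points": s.points.tolist(),
                "radii": s.radii.tolist(),
            }
            for s in tree.segments.values()
        ],
    }
    Path(path).write_text(json.dumps(data))


def tree_from_json(path: str | Path) -> AirwayTree:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tree file not found: {path}")
    data = json.loads(path.read_text())
    segments = {
        s["id"]: AirwaySegment(
            id=s["id"], parent_id=s["parent_id"], generation=s["generation"],
            points=np.array(s["points"]), radii=np.array(s["radii"]),
        )
        for s in data["segments"]
    }
    return AirwayTree(segments=segments, root_id=data["root_id"])


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------


def field_to_csv(path: str | Path, fld: DisplacementField) -> None:
    """Node table: z,y,x, u,v,w (voxels), quality, valid, filled."""
    coords = fld.grid.node_coords().reshape(-1, 3)
    v = fld.vectors.reshape(-1, 3)
    pd.DataFrame(
        {
            "z": coords[:, 0], "y": coords[:, 1], "x": coords[:, 2],
            "u_z": v[:, 0], "u_y": v[:, 1], "u_x": v[:, 2],
            "quality": fld.quality.ravel(),
            "valid": fld.valid.ravel().astype(int),
            "filled": fld.filled.ravel().astype(int),
        }
    ).to_csv(path, index=False)


def expansion_to_vtk(path: str | Path, exp: ExpansionField) -> None:
    """Expansion field as legacy-ASCII VTK structured points."""
    g = exp.grid
    nz, ny, nx = exp.values.shape
    out = [
        "# vtk DataFile Version 3.0", "expansion field", "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {g.origin[2]} {g.origin[1]} {g.origin[0]}",
        f"SPACING {g.spacing} {g.spacing} {g.spacing}",
        f"POINT_DATA {nz * ny * nx}",
        "SCALARS expansion float 1",
        "LOOKUP_TABLE default",
    ]
    vals = np.where(exp.valid, exp.values, np.nan)
    out.extend(f"{v:.6g}" for v in vals.ravel())
    Path(path).write_text("\n".join(out) + "\n")
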