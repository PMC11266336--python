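"""NIfTI-1 image / label-map I/O with JSON sidecar metadata.

Images are written as ``.nii`` or ``.nii.gz`` with a diagonal affine built
from spacing and origin; the unit and provenance travel in a ``.json``
sidecar next to the volume, since NIfTI has no standard slot for either.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import ActivityImage, LabelMap, VoxelGrid


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(grid: VoxelGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    affine = img.affine
    rotation = affine[:3, :3]
    if not np.allclose(rotation, np.diag(np.diag(rotation)), atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = np.diag(rotation)
    if np.any(spacing <= 0):
        raise ValueError("NIfTI affine implies non-positive voxel spacing")
    return VoxelGrid(tuple(int(n) for n in img.shape), tuple(spacing), tuple(affine[:3, 3]))


def _load(path) -> tuple[np.ndarray, VoxelGrid, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D in {path}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite voxels in {path}")
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(data, dtype=float), _grid_from_nifti(img), meta


def read_image(path) -> ActivityImage:
    """Read an activity image (NIfTI-1 + optional JSON sidecar)."""
    data, grid, meta = _load(path)
    return ActivityImage(
        grid=grid,
        values=data,
        unit=meta.get("unit", "Bq_per_mL"),
        corrected=bool(meta.get("corrected", False)),
        provenance=meta.get("provenance", {}),
    )


def write_image(image: ActivityImage, path) -> Path:
    """Write an activity image; values/spacing/origin round-trip within 1e-6."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nifti = nib.Nifti1Image(image.values.astype(np.float64), _affine(image.grid))
    nifti.header.set_zooms(image.grid.spacing)
    nib.save(nifti, str(path))
    meta = {
        "unit": image.unit,
        "corrected": image.corrected,
        "provenance": image.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_labels(path) -> LabelMap:
    """Read a label map; floating-point volumes with integral values are cast exactly."""
    data, grid, meta = _load(path)
    names = {int(k): v for k, v in meta.get("names", {}).items()}
    if not names:
        present = set(int(v) for v in np.unique(np.round(data))) - {0}
        names = {k: f"region_{k}" for k in present}
    return LabelMap(grid=grid, labels=data, names=names)


def write_labels(labels: LabelMap, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nifti = nib.Nifti1Image(labels.labels.astype(np.int16), _affine(labels.grid))
    nifti.header.set_zooms(labels.grid.spacing)
    nib.save(nifti, str(path))
    _sidecar_path(path).write_text(json.dumps({"names": labels.names}, indent=1))
    return path
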