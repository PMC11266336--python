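"""Voxel-grid data model and binary-mask morphology.

The working representation throughout the package is a regular 3-D voxel
grid with per-axis spacing in mm.  Physical coordinates refer to voxel
*centers*; voxel indices are 0-based, so the center of voxel (i, j, k)
sits at ``origin + (i, j, k) * spacing``.  The canonical concentration
unit is Bq/mL (values quoted in MBq/L convert by a factor of 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class EmptyMaskError(ValueError):
    """Raised when a morphological operation produces an empty mask."""


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a regular 3-D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing : tuple of float
        Voxel size along each axis in mm; all components > 0.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("VoxelGrid is strictly 3-D")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, index) -> np.ndarray:
        """Physical coordinates (mm) of voxel-center ``index`` (may be fractional)."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def physical_to_index(self, point) -> np.ndarray:
        """Continuous voxel index of physical point ``point`` (mm)."""
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Voxel-center physical coordinates along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def isclose(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=tol, atol=tol)
            and np.allclose(self.origin, other.origin, rtol=tol, atol=tol)
        )


@dataclass
class ActivityImage:
    """A scalar activity-concentration volume on a :class:`VoxelGrid`.

    ``unit`` is ``"Bq_per_mL"`` for quantitative images or ``"counts"``.
    Ground-truth and simulated images are non-negative; PVC output may
    legitimately go negative and carries ``corrected=True``.
    """

    grid: VoxelGrid
    values: np.ndarray
    unit: str = "Bq_per_mL"
    corrected: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.unit not in ("Bq_per_mL", "counts"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite voxels")
        if not self.corrected and np.any(self.values < 0):
            raise ValueError("uncorrected activity image has negative voxels")

    def with_values(self, values, corrected: bool | None = None, **prov) -> "ActivityImage":
        return ActivityImage(
            grid=self.grid,
            values=values,
            unit=self.unit,
            corrected=self.corrected if corrected is None else corrected,
            provenance={**self.provenance, **prov},
        )


@dataclass
class LabelMap:
    """Integer region assignment per voxel (one label per voxel).

    Label 0 is reserved for "outside body / uncorrected".  Every nonzero
    label present in ``labels`` must appear in ``names``.
    """

    grid: VoxelGrid
    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("label volume has non-integral values")
            labels = np.round(labels).astype(np.int32)
        if np.any(labels < 0):
            raise ValueError("labels must be non-negative")
        self.labels = labels.astype(np.int32, copy=False)
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from the names table")

    @property
    def region_ids(self) -> list[int]:
        """Sorted nonzero labels present in the map."""
        return sorted(set(int(v) for v in np.unique(self.labels)) - {0})

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def region_sizes(self) -> dict[int, int]:
        return {k: int(np.count_nonzero(self.labels == k)) for k in self.region_ids}

    def copy(self) -> "LabelMap":
        return LabelMap(self.grid, self.labels.copy(), dict(self.names))


def _target_grid(grid: VoxelGrid, target_spacing) -> VoxelGrid:
    """New grid covering the same physical extent with edge-aligned outer faces."""
    target_spacing = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,))
    if np.any(target_spacing <= 0):
        raise ValueError("target_spacing must be > 0")
    old_spacing = np.asarray(grid.spacing)
    extent = np.asarray(grid.shape) * old_spacing
    new_shape = np.maximum(1, np.rint(extent / target_spacing).astype(int))
    new_origin = (
        np.asarray(grid.origin) - old_spacing / 2.0 + target_spacing / 2.0
    )
    return VoxelGrid(tuple(new_shape), tuple(target_spacing), tuple(new_origin))


def resample_nearest(obj, target_spacing):
    """Resample an :class:`ActivityImage` or :class:`LabelMap` by nearest neighbor.

    Assignment is done in physical coordinates; resampling to the object's
    own spacing is the identity, and label maps never gain new labels.
    """
    grid = obj.grid
    new_grid = _target_grid(grid, target_spacing)
    if np.allclose(new_grid.spacing, grid.spacing):
        # identity: same spacing implies identical grid by construction
        if isinstance(obj, LabelMap):
            return LabelMap(grid, obj.labels.copy(), dict(obj.names))
        return replace(obj, values=obj.values.copy())

    idx = []
    for ax in range(3):
        coords = new_grid.axis_coordinates(ax)
        src = np.rint((coords - grid.origin[ax]) / grid.spacing[ax]).astype(int)
        idx.append(np.clip(src, 0, grid.shape[ax] - 1))
    ix, iy, iz = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")

    if isinstance(obj, LabelMap):
        return LabelMap(new_grid, obj.labels[ix, iy, iz], dict(obj.names))
    return ActivityImage(
        grid=new_grid,
        values=obj.values[ix, iy, iz],
        unit=obj.unit,
        corrected=obj.corrected,
        provenance=dict(obj.provenance),
    )


def _as_bool(mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask.astype(bool)
    return mask


def erode_mask(mask, distance_mm: float, spacing) -> np.ndarray:
    """Erode a binary mask by a physical Euclidean distance.

    Keeps voxels whose Euclidean distance to the mask complement exceeds
    ``distance_mm``, using the exact Euclidean distance transform (not an
    iterated structuring element), so the erosion is isotropic in mm even
    on anisotropic grids.

    Raises
    ------
    EmptyMaskError
        If the erosion empties the mask.
    """
    if distance_mm < 0:
        raise ValueError("distance_mm must be >= 0")
    mask = _as_bool(mask)
    if distance_mm == 0:
        out = mask.copy()
    else:
        dist = ndimage.distance_transform_edt(mask, sampling=spacing)
        out = dist > distance_mm
    if not out.any():
        raise EmptyMaskError(
            f"erosion by {distance_mm} mm emptied the mask "
            f"(largest interior depth {float(np.max(ndimage.distance_transform_edt(mask, sampling=spacing))):.2f} mm)"
        )
    return out


def dilate_mask_voxels(mask, radius_voxels: float) -> np.ndarray:
    """Dilate by a Euclidean ball of ``radius_voxels`` in index space."""
    mask = _as_bool(mask)
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_voxels


def shell_mask(mask, thickness_voxels: int) -> np.ndarray:
    """Shell of given voxel thickness around a mask, disjoint from it.

    The shell is the Euclidean-ball dilation by ``thickness_voxels`` minus
    the mask itself.
    """
    if thickness_voxels < 1:
        raise ValueError("thickness_voxels must be >= 1")
    mask = _as_bool(mask)
    return dilate_mask_voxels(mask, thickness_voxels) & ~mask
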