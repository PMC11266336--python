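"""Digital analogues of the modified IEC body phantoms.

Builds voxelized ground-truth activity images and 11-region label maps
for an IEC-like body phantom carrying six hot spheres, a cold lung
insert, a cold holder plate, and a pair of kidney-shaped inserts whose
volume and surface-to-volume ratio are fitted to the printed kidney
pairs of the emulated study.

The kidney surrogate is a parametric "bean": an ellipsoid with a fixed
anatomical aspect ratio (1 : 0.55 : 0.35, long axis in-plane) minus a
large hilum indentation sphere biting along the short axis.  The bite
depth is the primary surface-to-volume knob (a deep bite yields a
thin-walled, high-S:V shell at constant smoothness); an in-plane
elongation factor is the fallback knob when the bite saturates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage

from . import reference
from .core import ActivityImage, LabelMap, VoxelGrid
from .shapes import Bean, EllipticalCylinder, Shape, Sphere, rasterize_shape, surface_to_volume

#: Label assignment of the 11 segmented structures.
KIDNEY_LABELS = (1, 2)  # left (x < 0), right (x > 0)
SPHERE_LABELS = (3, 4, 5, 6, 7, 8)  # by ascending diameter
LUNG_LABEL = 9
HOLDER_LABEL = 10
BACKGROUND_LABEL = 11

LABEL_NAMES = {
    1: "kidney_L",
    2: "kidney_R",
    3: "sphere_10mm",
    4: "sphere_13mm",
    5: "sphere_17mm",
    6: "sphere_22mm",
    7: "sphere_28mm",
    8: "sphere_37mm",
    9: "lung_insert",
    10: "holder",
    11: "background",
}

#: Fixed bean-shape constants (aspect ratio and relative hilum radius).
BEAN_ASPECT = (1.0, 0.55, 0.35)
HILUM_RADIUS_FACTOR = 2.0
BITE_DEPTH_CAP = 0.88
ELONGATION_MAX = 2.5


class ClearanceError(ValueError):
    """A structure violates the minimum-clearance layout invariant."""


class InfeasibleSurrogateError(ValueError):
    """Requested kidney (volume, S:V) pair is outside the bean's range."""


def equal_volume_sphere_sv(volume_cm3: float) -> float:
    """S:V (cm^-1) of the sphere with the given volume — the lower bound
    over all shapes (the sphere minimizes surface at fixed volume)."""
    radius_cm = (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 3.0 / radius_cm


@dataclass(frozen=True)
class KidneySurrogateParams:
    """Fitted bean-shape parameters (mm) plus achieved/target metrics."""

    semi_axes: tuple[float, float, float]  # (x, y=long, z=short) semi-axes, mm
    hilum_radius: float  # mm
    hilum_offset: float  # distance of hilum-sphere center along +z, mm
    elongation: float
    bite_depth: float  # dimensionless lambda in [0, 1)
    achieved_volume: float  # cm^3
    achieved_surface: float  # cm^2
    achieved_sv: float  # cm^-1
    target_volume: float  # cm^3
    target_sv: float  # cm^-1

    def shape(self, center=(0.0, 0.0, 0.0), flip_bite: bool = False) -> Bean:
        """Analytic bean at ``center``; ``flip_bite`` mirrors the hilum to -z."""
        sign = -1.0 if flip_bite else 1.0
        cx, cy, cz = center
        return Bean(
            center=(cx, cy, cz),
            semi_axes=self.semi_axes,
            hilum_center=(cx, cy, cz + sign * self.hilum_offset),
            hilum_radius=self.hilum_radius,
        )


@dataclass
class KidneySurrogate:
    params: KidneySurrogateParams
    mask: np.ndarray
    occupancy: np.ndarray
    grid: VoxelGrid


def _bean_geometry(scale: float, elongation: float, bite_depth: float):
    """Semi-axes and hilum placement for the canonical (origin-centered) bean."""
    e = elongation
    a = BEAN_ASPECT[0] * scale * math.sqrt(e)  # long, in-plane (y)
    b = BEAN_ASPECT[1] * scale * math.sqrt(e)  # middle, in-plane (x)
    c = BEAN_ASPECT[2] * scale / e  # short (z)
    hilum_radius = HILUM_RADIUS_FACTOR * a
    hilum_offset = c + hilum_radius - bite_depth * 2.0 * c
    return (b, a, c), hilum_radius, hilum_offset


def _canonical_bean(scale: float, elongation: float, bite_depth: float) -> Bean:
    semi, r_h, d = _bean_geometry(scale, elongation, bite_depth)
    return Bean((0.0, 0.0, 0.0), semi, (0.0, 0.0, d), r_h)


def _local_grid(shape: Shape, spacing: float, margin_voxels: int = 2) -> VoxelGrid:
    lo, hi = shape.bounds()
    lo = lo - margin_voxels * spacing
    hi = hi + margin_voxels * spacing
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    return VoxelGrid(tuple(n), (spacing,) * 3, tuple(lo))


def _measure_bean(scale, elongation, bite_depth, spacing, supersample):
    bean = _canonical_bean(scale, elongation, bite_depth)
    grid = _local_grid(bean, spacing)
    occ = rasterize_shape(bean, grid, supersample)
    vol, surf, sv = surface_to_volume(occ >= 0.5, spacing, occ)
    return vol, surf, sv, occ, grid


def make_kidney_surrogate(
    target_volume: float,
    target_sv: float,
    spacing: float = 1.0,
    supersample: int = 3,
    tol: float = 0.01,
) -> KidneySurrogate:
    """Fit a bean surrogate to a (volume cm^3, S:V cm^-1) target pair.

    A two-stage monotone search: the bite depth (and, when it saturates,
    the elongation factor) is solved against the scale-normalized S:V,
    then the isotropic scale is solved against the volume; both are
    polished jointly at the output resolution until each achieved value
    is within ``tol`` of its target (the contract is 2%).

    Raises
    ------
    InfeasibleSurrogateError
        If ``target_sv`` is below 1.05x the equal-volume-sphere bound or
        outside the shape family's achievable range.
    """
    if target_volume <= 0 or target_sv <= 0:
        raise ValueError("targets must be positive")
    sphere_sv = equal_volume_sphere_sv(target_volume)
    if target_sv < 1.05 * sphere_sv:
        raise InfeasibleSurrogateError(
            f"target S:V {target_sv:.2f} cm^-1 is below 1.05x the equal-volume "
            f"sphere bound ({sphere_sv:.2f} cm^-1); no shape at this smoothness "
            "can reach it"
        )

    coarse_spacing = max(spacing, 1.8)
    coarse_ss = 2
    base_scale = (target_volume * 1000.0 / 0.8063) ** (1.0 / 3.0)

    def sv_normalized(elongation, bite_depth):
        # S:V rescaled to the target volume; scale-invariant shape descriptor
        vol, _, sv, _, _ = _measure_bean(
            base_scale, elongation, bite_depth, coarse_spacing, coarse_ss
        )
        return sv * (vol / target_volume) ** (1.0 / 3.0)

    # -- stage 1: bite depth (primary), elongation (fallback) ---------------
    elongation = 1.0
    lo, hi = 0.0, BITE_DEPTH_CAP
    f_lo = sv_normalized(elongation, lo)
    f_hi = sv_normalized(elongation, hi)
    if target_sv < f_lo:
        raise InfeasibleSurrogateError(
            f"target S:V {target_sv:.2f} cm^-1 is below the un-indented bean's "
            f"{f_lo:.2f} cm^-1 at this volume; achievable range is about "
            f"[{f_lo:.2f}, {sv_normalized(ELONGATION_MAX, BITE_DEPTH_CAP):.2f}]"
        )
    if target_sv <= f_hi:
        bite_depth = _bisect(lambda lam: sv_normalized(elongation, lam) - target_sv, lo, hi)
    else:
        bite_depth = BITE_DEPTH_CAP
        g_hi = sv_normalized(ELONGATION_MAX, bite_depth)
        if target_sv > g_hi:
            raise InfeasibleSurrogateError(
                f"target S:V {target_sv:.2f} cm^-1 exceeds the bean family's "
                f"maximum ~{g_hi:.2f} cm^-1 at this volume; achievable range is "
                f"about [{f_lo:.2f}, {g_hi:.2f}]"
            )
        elongation = _bisect(
            lambda e: sv_normalized(e, bite_depth) - target_sv, 1.0, ELONGATION_MAX
        )

    # -- stage 2: scale for volume, polished at the output resolution -------
    vol, _, sv, _, _ = _measure_bean(
        base_scale, elongation, bite_depth, coarse_spacing, coarse_ss
    )
    scale = base_scale * (target_volume / vol) ** (1.0 / 3.0)

    # Joint polish at the output resolution.  The volume is extremely
    # sensitive to the bite depth near the cap, so the two knobs are
    # relaxed sequentially: converge the scale for volume, then take one
    # damped bite-depth step against the residual S:V error.
    dsv_dlam = _slope(lambda lam: sv_normalized(elongation, lam), bite_depth, 0.03, BITE_DEPTH_CAP)
    converged = False
    for _ in range(12):
        for _ in range(4):
            vol, surf, sv, occ, grid = _measure_bean(
                scale, elongation, bite_depth, spacing, supersample
            )
            vol_err = vol / target_volume - 1.0
            if abs(vol_err) < 0.4 * tol:
                break
            scale *= (target_volume / vol) ** (1.0 / 3.0)
        sv_err = sv / target_sv - 1.0
        if abs(vol_err) < tol and abs(sv_err) < tol:
            converged = True
            break
        step = float(np.clip(0.8 * (target_sv - sv) / dsv_dlam, -0.04, 0.04))
        bite_depth = float(np.clip(bite_depth + step, 0.0, BITE_DEPTH_CAP))
    if not converged and (abs(vol_err) > 0.02 or abs(sv_err) > 0.02):
        raise InfeasibleSurrogateError(
            f"surrogate fit did not converge: volume error {100 * vol_err:.1f}%, "
            f"S:V error {100 * sv_err:.1f}% at spacing {spacing} mm"
        )

    semi, r_h, d = _bean_geometry(scale, elongation, bite_depth)
    params = KidneySurrogateParams(
        semi_axes=semi,
        hilum_radius=r_h,
        hilum_offset=d,
        elongation=elongation,
        bite_depth=bite_depth,
        achieved_volume=vol,
        achieved_surface=surf,
        achieved_sv=sv,
        target_volume=target_volume,
        target_sv=target_sv,
    )
    return KidneySurrogate(params=params, mask=occ >= 0.5, occupancy=occ, grid=grid)


def _bisect(func, lo, hi, n_iter=24, tol=1e-3):
    f_lo = func(lo)
    if f_lo >= 0:
        return lo
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f_mid = func(mid)
        if abs(f_mid) < tol:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _slope(func, x, dx, x_max):
    x0 = min(x, x_max - dx)
    return max((func(x0 + dx) - func(x0)) / dx, 1e-6)


@lru_cache(maxsize=32)
def fit_kidney_pair(kidney_set: str, spacing: float = 2.21, supersample: int = 3):
    """Fit (left, right) surrogate parameters for one printed kidney pair."""
    geometry = reference.KIDNEY_GEOMETRY[kidney_set]
    fits = {}
    for side in ("L", "R"):
        volume, _, sv = geometry[side]
        fits[side] = make_kidney_surrogate(volume, sv, spacing=spacing, supersample=supersample).params
    return fits["L"], fits["R"]


# ---------------------------------------------------------------------------
# Phantom specification and assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSettings:
    """Poisson count-noise model: expected counts per voxel equal
    concentration (Bq/mL) x voxel volume (mL) x kappa (counts/Bq)."""

    kappa: float = 0.0438  # ~ CF 18.26 counts/s/MBq x 2400 s acquisition
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0 when noise is enabled")


def default_grid(spacing: float = reference.WORKING_SPACING_MM) -> VoxelGrid:
    """Working grid: isotropic voxels over a 350 x 260 x 220 mm FOV, centered,
    leaving >= 4 sigma of air around the body so kernel mass is conserved."""
    fov = np.array([353.6, 260.8, 221.0])
    shape = np.rint(fov / spacing).astype(int)
    origin = -(shape - 1) / 2.0 * spacing
    return VoxelGrid(tuple(shape), (spacing,) * 3, tuple(origin))


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one modified IEC phantom instance.

    Concentrations are in Bq/mL.  All structures must keep >= 10 mm
    clearance from each other and from the body shell.
    """

    kidneys: tuple[KidneySurrogateParams, KidneySurrogateParams]  # (left, right)
    background_conc: float
    target_conc: float
    grid: VoxelGrid = field(default_factory=default_grid)
    body_semi_axes_xy: tuple[float, float] = (150.0, 110.0)
    body_half_length: float = 90.0
    lung_radius: float = 25.5
    lung_z_range: tuple[float, float] = (-55.0, 80.0)
    holder_semi_axes_xy: tuple[float, float] = (127.5, 93.5)
    holder_z_range: tuple[float, float] = (-79.5, -69.5)
    sphere_diameters: tuple[float, ...] = reference.SPHERE_DIAMETERS_MM
    sphere_ring_radius: float = 57.0
    sphere_plane_z: float = 40.0
    kidney_centers: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (-80.0, 0.0, -32.0),
        (80.0, 0.0, -32.0),
    )
    noise: NoiseSettings | None = None
    supersample: int = 3

    def __post_init__(self):
        if self.background_conc <= 0 or self.target_conc <= 0:
            raise ValueError("concentrations must be > 0")

    @property
    def tbr(self) -> float:
        return self.target_conc / self.background_conc

    def structures(self) -> dict[int, Shape]:
        """Analytic insert shapes keyed by label."""
        shapes: dict[int, Shape] = {}
        for label, center, params in zip(KIDNEY_LABELS, self.kidney_centers, self.kidneys):
            shapes[label] = params.shape(center=center)
        diameters = sorted(self.sphere_diameters)
        # largest sphere at angle 0, then descending around the ring
        angles = np.deg2rad(np.arange(6) * 60.0)
        for label, diameter, theta in zip(SPHERE_LABELS, diameters, angles[::-1]):
            center = (
                self.sphere_ring_radius * math.cos(theta),
                self.sphere_ring_radius * math.sin(theta),
                self.sphere_plane_z,
            )
            shapes[label] = Sphere(center, diameter / 2.0)
        z0, z1 = self.lung_z_range
        shapes[LUNG_LABEL] = EllipticalCylinder(
            (0.0, 0.0, (z0 + z1) / 2.0), (self.lung_radius, self.lung_radius), (z1 - z0) / 2.0
        )
        z0, z1 = self.holder_z_range
        shapes[HOLDER_LABEL] = EllipticalCylinder(
            (0.0, 0.0, (z0 + z1) / 2.0), self.holder_semi_axes_xy, (z1 - z0) / 2.0
        )
        return shapes

    def body_shape(self) -> EllipticalCylinder:
        return EllipticalCylinder((0.0, 0.0, 0.0), self.body_semi_axes_xy, self.body_half_length)


def iec_phantom_spec(
    phantom: str = "iec1",
    acquisition: int = 0,
    grid: VoxelGrid | None = None,
    noise: NoiseSettings | None = None,
) -> PhantomSpec:
    """Spec for one of the three reference phantoms at one acquisition row.

    Concentrations are taken from the reference schedule (MBq/L) and
    converted to Bq/mL.
    """
    schedule = reference.CONCENTRATION_SCHEDULE[phantom]
    grid = grid or default_grid()
    kidney_set = reference.PHANTOM_KIDNEY_SET[phantom]
    left, right = fit_kidney_pair(kidney_set, spacing=float(grid.spacing[0]))
    return PhantomSpec(
        kidneys=(left, right),
        background_conc=schedule["background"][acquisition] * reference.MBQ_PER_L_TO_BQ_PER_ML,
        target_conc=schedule["target"][acquisition] * reference.MBQ_PER_L_TO_BQ_PER_ML,
        grid=grid,
        noise=noise,
    )


@dataclass
class PhantomFields:
    """Rasterized building blocks shared by all concentration rows."""

    labels: LabelMap
    body_mask: np.ndarray
    background_field: np.ndarray  # fractional background occupancy
    target_field: np.ndarray  # fractional sphere+kidney occupancy
    insert_occupancy: dict[int, np.ndarray]


def rasterize_fields(spec: PhantomSpec, validate: bool = True) -> PhantomFields:
    grid = spec.grid
    body_occ = rasterize_shape(spec.body_shape(), grid, spec.supersample)
    body_mask = body_occ >= 0.5

    shapes = spec.structures()
    occupancy = {
        label: rasterize_shape(shape, grid, spec.supersample) for label, shape in shapes.items()
    }
    masks = {label: occ >= 0.5 for label, occ in occupancy.items()}

    labels_arr = np.zeros(grid.shape, dtype=np.int32)
    covered = np.zeros(grid.shape, dtype=bool)
    for label in (*KIDNEY_LABELS, *SPHERE_LABELS, LUNG_LABEL, HOLDER_LABEL):
        mask = masks[label] & ~covered
        labels_arr[mask] = label
        covered |= mask
    background_mask = body_mask & ~covered
    labels_arr[background_mask] = BACKGROUND_LABEL

    labels = LabelMap(grid=grid, labels=labels_arr, names=dict(LABEL_NAMES))

    if validate:
        _validate_clearance(spec, masks, body_mask)

    occ_sum = np.zeros(grid.shape)
    target_field = np.zeros(grid.shape)
    for label, occ in occupancy.items():
        occ_sum += occ
        if label in KIDNEY_LABELS or label in SPHERE_LABELS:
            target_field += occ
    background_field = np.clip(body_occ - occ_sum, 0.0, None)

    return PhantomFields(
        labels=labels,
        body_mask=body_mask,
        background_field=background_field,
        target_field=target_field,
        insert_occupancy=occupancy,
    )


def _validate_clearance(spec: PhantomSpec, masks, body_mask, min_clearance_mm: float = 10.0):
    spacing = spec.grid.spacing
    shell_depth = ndimage.distance_transform_edt(body_mask, sampling=spacing)
    items = sorted(masks.items())
    for label, mask in items:
        if not mask.any():
            raise ClearanceError(f"structure {LABEL_NAMES[label]} rasterizes to an empty mask")
        depth = float(shell_depth[mask].min())
        if depth < min_clearance_mm:
            raise ClearanceError(
                f"{LABEL_NAMES[label]} is {depth:.1f} mm from the body shell "
                f"(< {min_clearance_mm} mm)"
            )
    for i, (label_i, mask_i) in enumerate(items):
        dist_to_i = None
        for label_j, mask_j in items[i + 1 :]:
            if dist_to_i is None:
                dist_to_i = ndimage.distance_transform_edt(~mask_i, sampling=spacing)
            gap = float(dist_to_i[mask_j].min())
            if gap < min_clearance_mm:
                raise ClearanceError(
                    f"{LABEL_NAMES[label_i]} and {LABEL_NAMES[label_j]} are "
                    f"{gap:.1f} mm apart (< {min_clearance_mm} mm)"
                )


def _truth_values(spec: PhantomSpec, fields: PhantomFields, boundary: str) -> np.ndarray:
    if boundary == "fractional":
        return (
            spec.background_conc * fields.background_field
            + spec.target_conc * fields.target_field
        )
    if boundary == "labels":
        conc = np.zeros(12)
        conc[list(KIDNEY_LABELS)] = spec.target_conc
        conc[list(SPHERE_LABELS)] = spec.target_conc
        conc[BACKGROUND_LABEL] = spec.background_conc
        return conc[fields.labels.labels]
    raise ValueError(f"unknown boundary mode {boundary!r}")


def assemble_phantom(
    spec: PhantomSpec,
    boundary: str = "fractional",
    validate: bool = True,
    fields: PhantomFields | None = None,
) -> tuple[ActivityImage, LabelMap]:
    """Rasterize a phantom spec into (ground-truth image, 11-region labels).

    ``boundary='fractional'`` mixes concentrations by sub-voxel occupancy
    at structure boundaries (physical truth of a continuous object);
    ``boundary='labels'`` paints each 0.5-threshold label region with its
    nominal concentration (the piecewise-constant premise under which the
    anatomy-based corrections are exact).
    """
    fields = fields or rasterize_fields(spec, validate=validate)
    truth = ActivityImage(
        grid=spec.grid,
        values=_truth_values(spec, fields, boundary),
        unit="Bq_per_mL",
        provenance={
            "kind": "phantom_truth",
            "boundary": boundary,
            "tbr": spec.tbr,
            "background_Bq_per_mL": spec.background_conc,
            "target_Bq_per_mL": spec.target_conc,
        },
    )
    return truth, fields.labels


def tbr_series(
    spec: PhantomSpec,
    backgrounds_MBq_L,
    targets_MBq_L,
    boundary: str = "fractional",
    validate: bool = True,
) -> tuple[list[ActivityImage], LabelMap]:
    """One truth image per concentration row, sharing a single label map.

    Activity can only be added to the phantom, so the background sequence
    must be non-decreasing; targets may drift (decay).  Rows with
    background above target are legitimate (TBR < 1).
    """
    backgrounds = np.asarray(backgrounds_MBq_L, dtype=float)
    targets = np.asarray(targets_MBq_L, dtype=float)
    if backgrounds.shape != targets.shape or backgrounds.ndim != 1:
        raise ValueError("background and target sequences must be equal-length 1-D")
    if np.any(backgrounds <= 0) or np.any(targets <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(backgrounds) < 0):
        raise ValueError("background concentration decreases across rows; activity can only be added")

    fields = rasterize_fields(spec, validate=validate)
    images = []
    for bg, tgt in zip(backgrounds, targets):
        row_spec = replace(
            spec,
            background_conc=bg * reference.MBQ_PER_L_TO_BQ_PER_ML,
            target_conc=tgt * reference.MBQ_PER_L_TO_BQ_PER_ML,
        )
        truth, _ = assemble_phantom(row_spec, boundary=boundary, validate=False, fields=fields)
        images.append(truth)
    return images, fields.labels
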