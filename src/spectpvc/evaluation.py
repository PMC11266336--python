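"""Quantification metrics and robustness sweeps.

Recovery coefficients (RC = C / C_cal), the camera calibration factor
(CF = N_ave / C_cal), line-source FWHM estimation, and the three
robustness sweeps: PSF mismatch, mask-registration mismatch, and
background heterogeneity.  Sweep biases are reported relative to the
matched (unperturbed) correction of the same observation, so they
isolate the perturbation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ActivityImage, EmptyMaskError, LabelMap, erode_mask, shell_mask
from .forward import shift_labels, simulate_observation
from .phantom import (
    BACKGROUND_LABEL,
    KIDNEY_LABELS,
    LUNG_LABEL,
    NoiseSettings,
    PhantomSpec,
    assemble_phantom,
    rasterize_fields,
)
from .psf import PSFModel
from .pvc import METHODS, RegionContext, run_pvc

DEFAULT_BACKGROUND_EROSION_MM = 30.0
DEFAULT_SHELL_THICKNESS_VOXELS = 3


# ---------------------------------------------------------------------------
# Point metrics
# ---------------------------------------------------------------------------


@dataclass
class RCRecord:
    """One recovery-coefficient measurement; RC = C / C_cal."""

    rc: float
    c: float
    c_cal: float
    n_voxels: int
    region: str = ""
    method: str = "uncorrected"
    tbr: float | None = None
    sv: float | None = None


def recovery_coefficient(image, mask, c_cal: float, **meta) -> RCRecord:
    """RC of an image over a mask against the calibrated concentration."""
    if c_cal <= 0:
        raise ValueError("C_cal must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("RC over an empty mask")
    values = image.values if isinstance(image, ActivityImage) else np.asarray(image)
    c = float(values[mask].mean())
    return RCRecord(rc=c / c_cal, c=c, c_cal=c_cal, n_voxels=int(mask.sum()), **meta)


def background_rc(
    image,
    labels: LabelMap,
    c_cal: float,
    background_label: int = BACKGROUND_LABEL,
    erosion_mm: float = DEFAULT_BACKGROUND_EROSION_MM,
    **meta,
) -> RCRecord:
    """RC over the background VOI eroded by 3 cm, clearing spill-over range."""
    eroded = erode_mask(labels.mask(background_label), erosion_mm, labels.grid.spacing)
    return recovery_coefficient(image, eroded, c_cal, region="background", **meta)


def peripheral_shell_rc(
    image,
    kidney_mask,
    labels: LabelMap,
    c_cal: float,
    thickness_voxels: int = DEFAULT_SHELL_THICKNESS_VOXELS,
    background_label: int = BACKGROUND_LABEL,
    **meta,
) -> RCRecord:
    """RC over the three-voxel shell encircling a kidney mask, restricted
    to the background label so neighboring structures are excluded.
    ``c_cal`` here is conventionally the background concentration (the
    shell lies in the background)."""
    shell = shell_mask(kidney_mask, thickness_voxels) & labels.mask(background_label)
    if not shell.any():
        raise EmptyMaskError("peripheral shell is empty after background restriction")
    return recovery_coefficient(image, shell, c_cal, **meta)


@dataclass
class CalibrationResult:
    cf: float
    n_ave: float
    c_cal: float
    voi: dict


def calibration_factor(
    image,
    c_cal: float,
    center=(0.0, 0.0, 0.0),
    diameter_mm: float = 168.0,
    length_mm: float = 146.0,
    axis: int = 2,
) -> CalibrationResult:
    """CF = N_ave / C_cal over a centered cylindrical VOI (default 80% of
    the calibration phantom's inner dimensions)."""
    if c_cal <= 0:
        raise ValueError("C_cal must be > 0")
    grid = image.grid
    coords = [grid.axis_coordinates(ax) for ax in range(3)]
    trans = [ax for ax in range(3) if ax != axis]
    # cylinder must fit inside the grid
    for ax in trans:
        lo, hi = coords[ax][0], coords[ax][-1]
        if center[ax] - diameter_mm / 2 < lo - grid.spacing[ax] / 2 or center[ax] + diameter_mm / 2 > hi + grid.spacing[ax] / 2:
            raise ValueError("calibration VOI extends outside the image grid")
    if center[axis] - length_mm / 2 < coords[axis][0] - grid.spacing[axis] / 2 or center[axis] + length_mm / 2 > coords[axis][-1] + grid.spacing[axis] / 2:
        raise ValueError("calibration VOI extends outside the image grid")

    mesh = np.meshgrid(*coords, indexing="ij")
    radial = (mesh[trans[0]] - center[trans[0]]) ** 2 + (mesh[trans[1]] - center[trans[1]]) ** 2
    mask = (radial <= (diameter_mm / 2) ** 2) & (np.abs(mesh[axis] - center[axis]) <= length_mm / 2)
    n_ave = float(image.values[mask].mean())
    return CalibrationResult(
        cf=n_ave / c_cal,
        n_ave=n_ave,
        c_cal=c_cal,
        voi={"center": tuple(center), "diameter_mm": diameter_mm, "length_mm": length_mm, "axis": axis},
    )


def cf_decrease_percent(cf_low_activity: float, cf_high_activity: float) -> float:
    """Relative CF decrease (%) between a low-activity and a high-activity
    recording — the saturation/dead-time stability check."""
    return 100.0 * (cf_low_activity - cf_high_activity) / cf_low_activity


@dataclass
class FWHMEstimate:
    fwhm_mm: float
    resolution_limited: bool
    profile: np.ndarray
    positions_mm: np.ndarray


def estimate_fwhm(
    image, axis: int, window_mm: float = 40.0, cross_voxels: int = 3
) -> FWHMEstimate:
    """FWHM of a line-source image along one axis.

    Takes a profile of ``window_mm`` length through the intensity maximum,
    summing over a ``cross_voxels`` x ``cross_voxels`` cross-section in
    the two remaining axes, and interpolates the half-maximum crossings
    linearly on both flanks.
    """
    values = image.values if isinstance(image, ActivityImage) else np.asarray(image)
    grid = image.grid
    peak = np.unravel_index(np.argmax(values), values.shape)
    half_window = int(round(window_mm / 2.0 / grid.spacing[axis]))
    lo = peak[axis] - half_window
    hi = peak[axis] + half_window
    if lo < 0 or hi >= values.shape[axis]:
        raise ValueError("profile window extends outside the grid")

    half_cross = cross_voxels // 2
    slicer = []
    for ax in range(3):
        if ax == axis:
            slicer.append(slice(lo, hi + 1))
        else:
            a0, a1 = peak[ax] - half_cross, peak[ax] + half_cross
            if a0 < 0 or a1 >= values.shape[ax]:
                raise ValueError("cross-section extends outside the grid")
            slicer.append(slice(a0, a1 + 1))
    block = values[tuple(slicer)]
    sum_axes = tuple(ax for ax in range(3) if ax != axis)
    profile = block.sum(axis=sum_axes)
    positions = (np.arange(lo, hi + 1) - peak[axis]) * grid.spacing[axis]

    peak_idx = int(np.argmax(profile))
    half = profile[peak_idx] / 2.0

    def crossing(direction: int) -> float:
        i = peak_idx
        while 0 <= i + direction < profile.size and profile[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= profile.size:
            raise ValueError("profile does not cross half-maximum on both flanks")
        frac = (profile[i] - half) / (profile[i] - profile[j])
        return positions[i] + frac * (positions[j] - positions[i])

    fwhm = crossing(+1) - crossing(-1)
    return FWHMEstimate(
        fwhm_mm=float(fwhm),
        resolution_limited=bool(fwhm < 1.5 * grid.spacing[axis]),
        profile=profile,
        positions_mm=positions,
    )


# ---------------------------------------------------------------------------
# Phantom runs
# ---------------------------------------------------------------------------


@dataclass
class PhantomRun:
    """One simulated acquisition bundled with everything the sweeps need."""

    spec: PhantomSpec
    truth: ActivityImage
    labels: LabelMap
    psf: PSFModel
    observed: ActivityImage
    context: RegionContext
    name: str = "phantom"

    def c_true(self, label: int) -> float:
        if label in KIDNEY_LABELS or label in range(3, 9):
            return self.spec.target_conc
        if label == BACKGROUND_LABEL:
            return self.spec.background_conc
        return 0.0


def prepare_run(
    spec: PhantomSpec,
    psf: PSFModel | None = None,
    boundary: str = "labels",
    noise: NoiseSettings | None = None,
    name: str = "phantom",
    validate: bool = True,
) -> PhantomRun:
    """Assemble, blur (and optionally add noise to) one phantom spec."""
    psf = psf or PSFModel()
    fields = rasterize_fields(spec, validate=validate)
    truth, labels = assemble_phantom(spec, boundary=boundary, validate=False, fields=fields)
    observed = simulate_observation(truth, psf, noise=noise or spec.noise)
    return PhantomRun(
        spec=spec,
        truth=truth,
        labels=labels,
        psf=psf,
        observed=observed,
        context=RegionContext(labels, psf),
        name=name,
    )


def kidney_rc_table(
    run: PhantomRun,
    methods=METHODS,
    context: RegionContext | None = None,
    image: ActivityImage | None = None,
    n_iter: int = 10,
) -> pd.DataFrame:
    """Corrected kidney RCs for several methods on one observation.

    Region-based methods take C from the linear solve; voxel-based
    methods measure the mean of the corrected image over the crisp kidney
    mask.  Rows: (method, label, region, c, rc).
    """
    ctx = context or run.context
    img = image or run.observed
    rows = []
    for method in methods:
        C, corrected = run_pvc(img, ctx, method=method, n_iter=n_iter)
        for label in KIDNEY_LABELS:
            if corrected is None:
                c = C[label]
            else:
                c = float(corrected.values[ctx.mask(label)].mean())
            c_cal = run.c_true(label)
            rows.append(
                {
                    "method": method,
                    "label": label,
                    "region": run.labels.names[label],
                    "c": c,
                    "rc": c / c_cal,
                }
            )
    return pd.DataFrame(rows)


def uncorrected_kidney_rc(run: PhantomRun) -> dict[int, float]:
    return {
        label: float(run.observed.values[run.context.mask(label)].mean()) / run.c_true(label)
        for label in KIDNEY_LABELS
    }


# ---------------------------------------------------------------------------
# Robustness sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Tidy sweep output: one row per (axis value, method, kidney)."""

    kind: str  # "psf_mismatch" | "registration" | "heterogeneity"
    table: pd.DataFrame
    skipped: list = field(default_factory=list)

    def mean_bias(self, signed: bool = True) -> pd.DataFrame:
        """Kidney-averaged bias per (method, axis value); signed or absolute."""
        df = self.table.copy()
        col = "bias_pct" if signed else "abs_bias_pct"
        df["abs_bias_pct"] = df["bias_pct"].abs()
        return df.groupby(["method", "axis_value"])[col].mean().reset_index()

    def method_bias(self, method: str, signed: bool = True) -> pd.Series:
        df = self.mean_bias(signed=signed)
        df = df[df["method"] == method]
        return df.set_index("axis_value").iloc[:, -1]


def _bias_frame(reference: pd.DataFrame, perturbed: pd.DataFrame, axis_value) -> pd.DataFrame:
    merged = perturbed.merge(
        reference[["method", "label", "rc"]], on=["method", "label"], suffixes=("", "_ref")
    )
    merged["bias_pct"] = 100.0 * (merged["rc"] - merged["rc_ref"]) / merged["rc_ref"]
    merged["axis_value"] = axis_value
    return merged


def psf_mismatch_sweep(
    run: PhantomRun, deltas_mm=(-6, -4, -2, 0, 2, 4, 6), methods=METHODS
) -> SweepResult:
    """Re-correct with a mis-specified PSF (FWHM + delta on every axis).

    The observation is left untouched; only the correction PSF changes.
    Bias is relative to the matched-PSF correction (delta 0).
    """
    reference = kidney_rc_table(run, methods)
    frames = []
    skipped = []
    for delta in deltas_mm:
        if min(run.psf.fwhm) + delta < 0:
            skipped.append(float(delta))
            continue
        if delta == 0:
            perturbed = reference
            ctx = run.context
        else:
            ctx = RegionContext(run.labels, run.psf.perturbed(delta))
            perturbed = kidney_rc_table(run, methods, context=ctx)
        frames.append(_bias_frame(reference, perturbed, float(delta)))
    return SweepResult("psf_mismatch", pd.concat(frames, ignore_index=True), skipped)


def registration_sweep(
    run: PhantomRun,
    max_offset_voxels: int = 3,
    axes=(0, 1, 2),
    methods=METHODS,
    joint: bool = True,
) -> SweepResult:
    """Translate the kidney masks (jointly by default, as one rigid
    registration error) and re-correct with the shifted segmentation.

    Rows carry the signed offset per axis; ``axis_value`` is the offset
    magnitude in voxels with 0 the unshifted reference.
    """
    reference = kidney_rc_table(run, methods)
    frames = [_bias_frame(reference, reference, 0.0)]
    shift_groups = [list(KIDNEY_LABELS)] if joint else [[k] for k in KIDNEY_LABELS]
    for axis in axes:
        for sign in (+1, -1):
            for magnitude in range(1, max_offset_voxels + 1):
                offset = [0, 0, 0]
                offset[axis] = sign * magnitude
                for group in shift_groups:
                    shifted = shift_labels(run.labels, offset, group)
                    ctx = run.context.updated(shifted)
                    perturbed = kidney_rc_table(run, methods, context=ctx)
                    frame = _bias_frame(reference, perturbed, float(magnitude))
                    frame["shift_axis"] = axis
                    frame["shift_sign"] = sign
                    frames.append(frame)
    return SweepResult("registration", pd.concat(frames, ignore_index=True))


def merge_lung_into_background(
    labels: LabelMap,
    lung_label: int = LUNG_LABEL,
    background_label: int = BACKGROUND_LABEL,
) -> LabelMap:
    """Label map with the lung-insert segmentation absorbed into the
    background (the heterogeneity then sits inside one region)."""
    arr = labels.labels.copy()
    lung_mask = arr == lung_label
    if not lung_mask.any():
        raise ValueError("label map has no lung insert to merge")
    arr[lung_mask] = background_label
    names = {k: v for k, v in labels.names.items() if k != lung_label}
    return LabelMap(labels.grid, arr, names)


def apply_background_heterogeneity(
    observed: ActivityImage,
    labels: LabelMap,
    ratio: float,
    lung_label: int = LUNG_LABEL,
    background_label: int = BACKGROUND_LABEL,
) -> tuple[ActivityImage, LabelMap]:
    """Add uniform activity to the observed image's lung voxels so the
    merged-background mean rises by exactly ``ratio``.

    The added activity is confined to the lung voxels (the image is
    untouched elsewhere).  Ratios below 1 are unattainable since activity
    can only be added.
    """
    if ratio < 1.0:
        raise ValueError("heterogeneity ratio below 1 is unattainable (activity is only added)")
    merged = merge_lung_into_background(labels, lung_label, background_label)
    lung_mask = labels.labels == lung_label
    merged_mask = merged.labels == background_label
    base_mean = float(observed.values[merged_mask].mean())
    delta = (ratio - 1.0) * base_mean * merged_mask.sum() / lung_mask.sum()
    values = observed.values.copy()
    values[lung_mask] += delta
    return observed.with_values(values, heterogeneity_ratio=float(ratio)), merged


def heterogeneity_sweep(
    run: PhantomRun, ratios=tuple(np.arange(1.0, 4.01, 0.25)), methods=METHODS
) -> SweepResult:
    """Violate the background-uniformity assumption.

    The lung-insert segmentation is merged into the background and
    activity is added uniformly to the observed image's lung voxels so
    that the merged-background mean rises by the requested heterogeneity
    ratio.  The correction then sees a single, no-longer-uniform
    background region.  Bias is relative to the ratio-1 (merged, no
    added activity) reference.
    """
    merged_labels = merge_lung_into_background(run.labels)
    ctx = run.context.updated(merged_labels)

    reference = kidney_rc_table(run, methods, context=ctx)  # ratio-1 baseline
    frames = []
    for ratio in ratios:
        if ratio == 1.0:
            table = reference
        else:
            image, _ = apply_background_heterogeneity(run.observed, run.labels, ratio)
            table = kidney_rc_table(run, methods, context=ctx, image=image)
        frames.append(_bias_frame(reference, table, float(ratio)))
    return SweepResult("heterogeneity", pd.concat(frames, ignore_index=True))


def bias_vs_sv_regression(biases, svs) -> tuple[float, float, float]:
    """Ordinary least squares of bias on S:V; returns (slope, intercept, R^2)."""
    svs = np.asarray(svs, dtype=float)
    biases = np.asarray(biases, dtype=float)
    if len(np.unique(svs)) < 3:
        raise ValueError("need at least 3 distinct S:V values")
    fit = stats.linregress(svs, biases)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
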