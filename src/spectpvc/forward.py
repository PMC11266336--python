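"""Image-degradation forward model.

Stands in for acquisition plus reconstruction: stationary anisotropic
Gaussian-PSF convolution, optional Poisson count noise, and the rigid
label-mask shift used to emulate SPECT-CT misregistration.  It does not
model attenuation, scatter, dead time or reconstruction regularization.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import ActivityImage, LabelMap
from .phantom import BACKGROUND_LABEL, NoiseSettings
from .psf import PSFModel, convolve


def simulate_observation(
    truth: ActivityImage, psf: PSFModel, noise: NoiseSettings | None = None
) -> ActivityImage:
    """Blur a ground-truth image with the system PSF, optionally adding
    Poisson count noise.

    With noise, the expected count in each voxel is concentration (Bq/mL)
    x voxel volume (mL) x kappa (counts/Bq); the sampled counts are
    converted back to concentration, so the noise level scales as
    1/sqrt(expected counts).
    """
    if np.any(truth.values < 0):
        raise ValueError("ground truth must be non-negative")
    observed = convolve(truth, psf)
    provenance = {"kind": "observed", "psf_fwhm_mm": psf.fwhm}
    if noise is not None:
        voxel_ml = truth.grid.voxel_volume_mm3 / 1000.0
        expected_counts = observed.values * voxel_ml * noise.kappa
        rng = np.random.default_rng(noise.seed)
        counts = rng.poisson(expected_counts)
        observed = observed.with_values(counts / (voxel_ml * noise.kappa))
        provenance.update({"noise_kappa": noise.kappa, "noise_seed": noise.seed})
    observed.provenance.update(provenance)
    return observed


def shift_labels(
    labels: LabelMap,
    offset_voxels,
    labels_to_shift,
    background_label: int = BACKGROUND_LABEL,
) -> LabelMap:
    """Rigidly translate selected labels by an integer voxel offset.

    Vacated voxels fall back to ``background_label``; voxels the shifted
    masks enter are overwritten.  The operation is deliberately not
    invertible: shifting back does not restore labels overwritten on the
    way out.  Mask portions pushed off the grid are clipped with a
    warning, recorded in the returned map's provenance.
    """
    offset = np.asarray(offset_voxels, dtype=int)
    if offset.shape != (3,):
        raise ValueError("offset must be a 3-vector of integers")
    if np.any(np.abs(offset) >= np.asarray(labels.grid.shape)):
        raise ValueError("offset exceeds the grid extent")

    arr = labels.labels.copy()
    clipped = {}
    shifted_masks = {}
    for label in labels_to_shift:
        mask = labels.labels == label
        if not mask.any():
            raise ValueError(f"label {label} absent from the label map")
        shifted = _shift_bool(mask, offset)
        lost = int(mask.sum() - shifted.sum())
        if lost:
            clipped[int(label)] = lost
            warnings.warn(
                f"shift {tuple(offset)} clips {lost} voxels of label {label}",
                stacklevel=2,
            )
        arr[mask] = background_label
        shifted_masks[label] = shifted
    for label, shifted in shifted_masks.items():
        arr[shifted] = label
    # shifting into air would silently relabel air; flag it in provenance
    entered_air = {
        int(label): int(np.count_nonzero(shifted & (labels.labels == 0)))
        for label, shifted in shifted_masks.items()
    }
    entered_air = {k: v for k, v in entered_air.items() if v}
    if entered_air:
        warnings.warn(f"shifted labels entered air (label 0): {entered_air}", stacklevel=2)

    out = LabelMap(labels.grid, arr, dict(labels.names))
    out.provenance = {
        "shift_voxels": tuple(int(o) for o in offset),
        "shifted_labels": [int(l) for l in labels_to_shift],
        "clipped_voxels": clipped,
        "entered_air_voxels": entered_air,
    }
    return out


def _shift_bool(mask: np.ndarray, offset: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for ax, o in enumerate(offset):
        n = mask.shape[ax]
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = mask[tuple(src)]
    return out
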