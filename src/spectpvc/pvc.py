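"""Anatomy-based partial volume correction.

Seven methods built from PSF-blurred segmentation masks:

* region-based: GTM (geometric transfer matrix) and Labbé, which solve a
  linear spill-over system for the corrected region means C;
* voxel-based: MTC and RBV, seeded by either GTM or Labbé means, and
  Iterative Yang (IY), which bootstraps its means from the image itself.

All methods assume uniform activity within each segmented region, a
stationary PSF, and masks registered to the image.  Label 0 (air) is
excluded from correction and from all means; the background is a full
region like any other.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage

from .core import ActivityImage, LabelMap
from .psf import PSFModel, convolve_values

METHODS = ("gtm", "labbe", "gtm+mtc", "labbe+mtc", "gtm+rbv", "labbe+rbv", "iy")

#: Solves are refused above this condition number.
CONDITION_LIMIT = 1e8
#: Voxels where a blurred-mask denominator falls below this fraction of its
#: in-region maximum are left uncorrected (the denominators vanish away
#: from the region and would otherwise amplify noise without bound).
DENOMINATOR_GUARD = 1e-3


class IllConditionedError(np.linalg.LinAlgError):
    pass


@dataclass
class RegionMeans:
    """Per-region mean activity values (uncorrected A or corrected C)."""

    region_ids: tuple[int, ...]
    values: np.ndarray
    kind: str  # "uncorrected_A" | "corrected_C"
    estimator: str  # "gtm" | "labbe" | "iy" | "image"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids),):
            raise ValueError("one value per region required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("region means must be finite")

    def as_dict(self) -> dict[int, float]:
        return {k: float(v) for k, v in zip(self.region_ids, self.values)}

    def __getitem__(self, label: int) -> float:
        return float(self.values[self.region_ids.index(label)])


@dataclass
class SpillOverMatrix:
    """Spill-over coefficients G_{i,j}: contribution of region i to region j,
    normalized by the size of the receiving region j."""

    G: np.ndarray
    region_ids: tuple[int, ...]
    region_sizes: np.ndarray
    mode: str  # "gtm" | "labbe"
    condition_number: float

    @property
    def transfer(self) -> np.ndarray:
        """Row-normalized transfer matrix W with W[j, i] the fraction of
        region j's observed mean contributed by region i; the observation
        model is A = W C."""
        K = self.G * self.region_sizes[None, :]  # K[i, j], symmetric
        return K.T / self.region_sizes[:, None]


class RegionContext:
    """Caches per-region masks and their PSF-blurred counterparts.

    Building the blurred masks is the dominant cost of every method (one
    3-D convolution per region), so sweeps share and incrementally update
    a context instead of recomputing it.
    """

    def __init__(self, labels: LabelMap, psf: PSFModel):
        self.labels = labels
        self.psf = psf
        self.spacing = labels.grid.spacing
        self.region_ids = tuple(labels.region_ids)
        if not self.region_ids:
            raise ValueError("label map has no nonzero regions")
        self._masks = {k: labels.labels == k for k in self.region_ids}
        self.sizes = np.array([self._masks[k].sum() for k in self.region_ids], dtype=float)
        if np.any(self.sizes == 0):
            raise ValueError("empty region in label map")
        self._blurred: dict[int, np.ndarray] = {}
        self._spill: dict[str, SpillOverMatrix] = {}

    def mask(self, label: int) -> np.ndarray:
        return self._masks[label]

    def size(self, label: int) -> float:
        return float(self.sizes[self.region_ids.index(label)])

    def blurred(self, label: int) -> np.ndarray:
        if label not in self._blurred:
            self._blurred[label] = convolve_values(
                self._masks[label].astype(float), self.psf, self.spacing
            )
        return self._blurred[label]

    def paint(self, means: RegionMeans) -> np.ndarray:
        """Piecewise-constant image S = sum_j C_j s_j (zero outside regions)."""
        lut = np.zeros(max(self.region_ids) + 1)
        lut[list(means.region_ids)] = means.values
        return lut[self.labels.labels]

    def region_means(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(
            ndimage.mean(values, labels=self.labels.labels, index=list(self.region_ids))
        )

    def spillover(self, mode: str) -> SpillOverMatrix:
        if mode not in ("gtm", "labbe"):
            raise ValueError(f"unknown spill-over mode {mode!r}")
        if mode not in self._spill:
            n = len(self.region_ids)
            K = np.empty((n, n))
            if mode == "gtm":
                for i, ki in enumerate(self.region_ids):
                    bi = self.blurred(ki)
                    K[i, :] = ndimage.sum_labels(
                        bi, labels=self.labels.labels, index=list(self.region_ids)
                    )
            else:
                flat = [self.blurred(k).ravel() for k in self.region_ids]
                for i in range(n):
                    for j in range(i, n):
                        K[i, j] = K[j, i] = float(np.dot(flat[i], flat[j]))
            G = K / self.sizes[None, :]
            W = K.T / self.sizes[:, None]
            self._spill[mode] = SpillOverMatrix(
                G=G,
                region_ids=self.region_ids,
                region_sizes=self.sizes.copy(),
                mode=mode,
                condition_number=float(np.linalg.cond(W)),
            )
        return self._spill[mode]

    def updated(self, labels: LabelMap) -> "RegionContext":
        """Context for a modified label map, re-blurring only changed regions."""
        new = RegionContext(labels, self.psf)
        for k in new.region_ids:
            if k in self._blurred and np.array_equal(self._masks[k], new._masks[k]):
                new._blurred[k] = self._blurred[k]
        return new


def _context(labels, psf) -> RegionContext:
    return labels if isinstance(labels, RegionContext) else RegionContext(labels, psf)


def _values(image) -> np.ndarray:
    return image.values if isinstance(image, ActivityImage) else np.asarray(image, float)


# ---------------------------------------------------------------------------
# Region-based stage
# ---------------------------------------------------------------------------


def region_means_gtm(image, labels: LabelMap | RegionContext, psf: PSFModel | None = None) -> RegionMeans:
    """Uncorrected means A_i over the crisp segmentation masks s_i."""
    ctx = _context(labels, psf)
    return RegionMeans(ctx.region_ids, ctx.region_means(_values(image)), "uncorrected_A", "gtm")


def region_means_labbe(
    image,
    labels: LabelMap | RegionContext,
    psf: PSFModel | None = None,
    normalization: str = "crisp",
) -> RegionMeans:
    """Uncorrected means weighted by the blurred masks s_i * h.

    ``normalization='crisp'`` divides by the crisp mask size |s_i| (as the
    transfer-matrix normalization requires); ``'blurred'`` divides by the
    blurred-mask mass instead.  The two coincide whenever the kernel
    support stays inside the grid (the blur preserves mask mass).
    """
    ctx = _context(labels, psf)
    vals = _values(image)
    A = np.empty(len(ctx.region_ids))
    for i, k in enumerate(ctx.region_ids):
        b = ctx.blurred(k)
        num = float(np.dot(b.ravel(), vals.ravel()))
        if normalization == "crisp":
            A[i] = num / ctx.size(k)
        elif normalization == "blurred":
            A[i] = num / float(b.sum())
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
    return RegionMeans(ctx.region_ids, A, "uncorrected_A", "labbe")


def build_spillover_matrix(
    labels: LabelMap | RegionContext, psf: PSFModel | None = None, mode: str = "gtm"
) -> SpillOverMatrix:
    """Spill-over matrix G for disjoint regions (one convolution per region).

    GTM mode: G_{i,j} = sum((s_i * h) . s_j) / |s_j|; Labbé mode blurs both
    masks: G_{i,j} = sum((s_i * h) . (s_j * h)) / |s_j|.
    """
    return _context(labels, psf).spillover(mode)


def solve_corrected_means(spill: SpillOverMatrix, A: RegionMeans) -> RegionMeans:
    """Corrected means C from the observation model A = W C.

    W is the row-normalized transfer matrix derived from G (mean observed
    in region j = sum_i of region j's blurred-mask overlap with region i
    times C_i).  The solve uses an LU factorization, never an explicit
    inverse, and verifies the residual.
    """
    if A.region_ids != spill.region_ids:
        raise ValueError("region sets of A and G differ")
    W = spill.transfer
    cond = spill.condition_number
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        coupling = spill.G - np.diag(np.diag(spill.G))
        i, j = np.unravel_index(np.argmax(coupling), coupling.shape)
        raise IllConditionedError(
            f"spill-over matrix condition number {cond:.3g} exceeds "
            f"{CONDITION_LIMIT:.0e}; strongest off-diagonal coupling between "
            f"regions {spill.region_ids[i]} and {spill.region_ids[j]} "
            f"(G = {coupling[i, j]:.3g})"
        )
    C = linalg.lu_solve(linalg.lu_factor(W), A.values)
    residual = np.linalg.norm(W @ C - A.values) / max(np.linalg.norm(A.values), 1e-300)
    if residual > 1e-8:
        raise IllConditionedError(f"linear-solve residual {residual:.3g} above 1e-8")
    return RegionMeans(spill.region_ids, C, "corrected_C", A.estimator)


# ---------------------------------------------------------------------------
# Voxel-based stage
# ---------------------------------------------------------------------------


def _guard_threshold(denom: np.ndarray, mask: np.ndarray) -> float:
    return DENOMINATOR_GUARD * float(denom[mask].max())


def mtc_correct(
    image: ActivityImage,
    labels: LabelMap | RegionContext,
    psf: PSFModel | None = None,
    C: RegionMeans | None = None,
) -> ActivityImage:
    """Multi-target correction: each region is treated in turn as the
    target; its spill-out is corrected from the image itself (division by
    the blurred target mask) and its spill-in is removed using the
    pre-computed corrected means of all other regions.

    Voxels with guarded denominators, and voxels outside every region,
    keep their observed value and are flagged in the provenance.
    """
    if C is None:
        raise ValueError("MTC requires pre-computed corrected means (GTM or Labbé)")
    ctx = _context(labels, psf)
    vals = _values(image)
    S = ctx.paint(C)
    S_blur = convolve_values(S, ctx.psf, ctx.spacing)
    out = vals.copy()
    guarded = {}
    cdict = C.as_dict()
    for k in ctx.region_ids:
        mask = ctx.mask(k)
        denom = ctx.blurred(k)
        # (sum_{i != j} C_i s_i) * h  ==  S*h - C_j (s_j*h)  by linearity
        spill_in = S_blur - cdict[k] * denom
        valid = mask & (denom >= _guard_threshold(denom, mask))
        if not valid.any():
            raise ValueError(f"region {k}: every voxel hit the denominator guard")
        out[valid] = (vals[valid] - spill_in[valid]) / denom[valid]
        n_guarded = int(mask.sum() - valid.sum())
        if n_guarded:
            guarded[k] = n_guarded
    return image.with_values(
        out, corrected=True, method="mtc", seed_estimator=C.estimator, guarded_voxels=guarded
    )


def rbv_correct(
    image: ActivityImage,
    labels: LabelMap | RegionContext,
    psf: PSFModel | None = None,
    C: RegionMeans | None = None,
) -> ActivityImage:
    """Region-based voxel-wise correction: I_c = I . S / (S * h) with
    S the piecewise-constant image of pre-computed corrected means."""
    if C is None:
        raise ValueError("RBV requires pre-computed corrected means (GTM or Labbé)")
    ctx = _context(labels, psf)
    out, guarded = _yang_multiply(_values(image), ctx, C)
    return image.with_values(
        out, corrected=True, method="rbv", seed_estimator=C.estimator, guarded_voxels=guarded
    )


def _yang_multiply(vals: np.ndarray, ctx: RegionContext, means: RegionMeans):
    S = ctx.paint(means)
    if not np.any(S):
        raise ValueError("piecewise-constant image S is identically zero")
    D = convolve_values(S, ctx.psf, ctx.spacing)
    out = vals.copy()
    guarded = {}
    for k in ctx.region_ids:
        mask = ctx.mask(k)
        valid = mask & (D >= _guard_threshold(D, mask))
        out[valid] = vals[valid] * S[valid] / D[valid]
        n_guarded = int(mask.sum() - valid.sum())
        if n_guarded:
            guarded[k] = n_guarded
    return out, guarded


def iy_correct(
    image: ActivityImage,
    labels: LabelMap | RegionContext,
    psf: PSFModel | None = None,
    n_iter: int = 10,
    tol: float = 1e-5,
) -> tuple[ActivityImage, list[RegionMeans]]:
    """Iterative Yang: RBV-like correction whose region means come from
    the image itself.

    Iteration 1 applies the Yang multiplier with means taken directly
    from the observed image; each subsequent iteration re-estimates the
    means from the corrected image and reapplies the multiplier to the
    original observed image.  Stops after ``n_iter`` iterations or when
    the largest relative mean change drops below ``tol``.  Returns the
    corrected image and the full mean trace (initial estimate first).
    """
    ctx = _context(labels, psf)
    vals = _values(image)
    means = RegionMeans(ctx.region_ids, ctx.region_means(vals), "uncorrected_A", "iy")
    trace = [means]
    guarded: dict[int, int] = {}
    out = vals
    for iteration in range(1, n_iter + 1):
        out, guarded = _yang_multiply(vals, ctx, means)
        new_values = ctx.region_means(out)
        if not np.all(np.isfinite(new_values)):
            raise FloatingPointError(f"IY diverged at iteration {iteration}")
        new_means = RegionMeans(ctx.region_ids, new_values, "corrected_C", "iy")
        trace.append(new_means)
        change = np.max(np.abs(new_values - means.values) / np.maximum(np.abs(means.values), 1e-300))
        means = new_means
        if change < tol:
            break
    corrected = image.with_values(
        out, corrected=True, method="iy", iterations=len(trace) - 1, guarded_voxels=guarded
    )
    return corrected, trace


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def _mask_checksum(labels: LabelMap) -> str:
    return f"{zlib.crc32(np.ascontiguousarray(labels.labels)):08x}"


def run_pvc(
    image: ActivityImage,
    labels: LabelMap | RegionContext,
    psf: PSFModel | None = None,
    method: str = "gtm",
    n_iter: int = 10,
    tol: float = 1e-5,
) -> tuple[RegionMeans, ActivityImage | None]:
    """Run one PVC method.

    Region-based methods (``gtm``, ``labbe``) return corrected means and
    no image; voxel-based methods (``gtm+mtc``, ``labbe+mtc``,
    ``gtm+rbv``, ``labbe+rbv``, ``iy``) additionally return the corrected
    image.  For seeded voxel methods the returned means are those of the
    region stage; for IY they are the means of the corrected image.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    ctx = _context(labels, psf)

    if method == "iy":
        corrected, trace = iy_correct(image, ctx, n_iter=n_iter, tol=tol)
        return trace[-1], corrected

    seed = method.split("+")[0]
    if seed == "gtm":
        A = region_means_gtm(image, ctx)
    else:
        A = region_means_labbe(image, ctx)
    C = solve_corrected_means(ctx.spillover(seed), A)

    if method in ("gtm", "labbe"):
        return C, None
    corrector = mtc_correct if method.endswith("mtc") else rbv_correct
    corrected = corrector(image, ctx, C=C)
    if isinstance(labels, LabelMap):
        corrected.provenance["mask_checksum"] = _mask_checksum(labels)
    corrected.provenance["method"] = method
    return C, corrected


def correct_all(
    image: ActivityImage,
    labels: LabelMap | RegionContext,
    psf: PSFModel | None = None,
    methods=METHODS,
    n_iter: int = 10,
    tol: float = 1e-5,
) -> dict[str, tuple[RegionMeans, ActivityImage | None]]:
    """Run several methods on one (image, labels, PSF) triple, sharing the
    blurred-mask cache across methods."""
    ctx = _context(labels, psf)
    return {
        m: run_pvc(image, ctx, method=m, n_iter=n_iter, tol=tol) for m in methods
    }
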