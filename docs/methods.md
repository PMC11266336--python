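# Methods

## Problem

Quantitative ¹⁷⁷Lu SPECT underestimates the activity concentration of
small or irregular structures because the reconstructed resolution
(≈ 9–11 mm FWHM) is comparable to the structures themselves: activity
spills out of a segmented region and neighboring activity spills in (the
partial volume effect, PVE). For kidney dosimetry in radionuclide
therapy this bias reaches tens of percent. Anatomy-based partial volume
correction (PVC) uses a CT-derived segmentation and the system
point-spread function (PSF) to undo the exchange.

This package implements the seven standard anatomy-based corrections and
a fully synthetic test bench — digital analogues of modified IEC body
phantoms carrying kidney-shaped inserts — so every stage is testable
without acquisition data.

## Correction model

Let `s_i` be the binary mask of region i (i = 1…N, one label per voxel,
label 0 = air, background included as a region), `h` the PSF, `I` the
observed image, and `⊛` 3-D convolution. All methods assume uniform
activity per region, a stationary PSF, and masks registered to the image.

**Region-based.** The observed mean of region j mixes the true means
`C_i` through the spill-over matrix. With

- GTM:   `G_ij = Σ((s_i ⊛ h) · s_j) / |s_j|`,  `A_i = mean of I over s_i`
- Labbé: `G_ij = Σ((s_i ⊛ h) · (s_j ⊛ h)) / |s_j|`,
  `A_i = Σ((s_i ⊛ h) · I) / |s_i|`

the observation model is `A_j = Σ_i G_ij · C_i`, i.e. `A = Gᵀ C`; the
solver uses the row-normalized transfer matrix `W_ji = K_ji / |s_j|`
(with `K` the symmetric overlap matrix) and an LU factorization with a
residual check — never an explicit inverse. The condition number is
recorded and solves are refused above 1e8, naming the most strongly
coupled region pair. Note the orientation: with the per-receiving-region
normalization written above, solving the system along the *transpose* of
G is what makes the correction exact in the ideal limit; solving the
printed orientation literally is only equivalent for symmetric layouts.

The Labbé uncorrected means are normalized by the crisp mask size as
written above; a `normalization="blurred"` switch divides by the
blurred-mask mass instead. The two coincide whenever the kernel support
stays inside the grid (blur conserves mask mass).

**Voxel-based.** MTC corrects each region in turn, dividing the observed
values by the blurred target mask (spill-out) after subtracting the
blurred neighborhood built from pre-computed means (spill-in):

    I_c = Σ_j s_j · (I − (Σ_{i≠j} C_i s_i) ⊛ h) / (s_j ⊛ h)

RBV corrects all regions at once with the piecewise-constant image
`S = Σ_j C_j s_j`:  `I_c = I · S / (S ⊛ h)`. Both are seeded by either
GTM or Labbé means. Iterative Yang applies the RBV multiplier with means
taken from the image itself, re-estimating the means from the corrected
image and reapplying the multiplier to the *original* image; the default
is 10 iterations with an additional relative-change stop at 1e-5.

**Denominator guard.** The blurred denominators vanish away from their
region. Voxels where the denominator falls below 1e-3 of its in-region
maximum keep their observed value and are counted in the output
provenance; voxels outside every region are never modified.

## Synthetic phantoms

The generator builds an IEC-like body (elliptical cylinder, interior
300 × 220 mm cross-section, 180 mm long) containing six spheres (10, 13,
17, 22, 28, 37 mm diameter on a 57 mm ring), a cold 51 mm lung-insert
cylinder, a cold 10 mm holder plate, and a pair of kidney surrogates.
Eleven regions (2 kidneys, 6 spheres, lung, holder, background)
partition the body support. All structures keep ≥ 10 mm clearance from
each other and from the shell, validated on the rasterized masks with
exact Euclidean distance transforms. Insert coordinates are not
prescribed by any reference, so the defaults place the sphere ring in
one axial plane, the kidneys laterally below it, and the holder at the
bottom; all are configurable.

**Kidney surrogates.** Patient kidney meshes are replaced by parametric
beans matched on the two quantities that govern the PVE: volume and
surface-to-volume ratio (S:V). The bean is an ellipsoid with anatomical
aspect ratio 1 : 0.55 : 0.35 minus a large hilum sphere (radius twice
the long semi-axis) biting along the short axis. The bite depth is the
primary S:V knob — a deep bite yields a smooth thin-walled bowl, which
is how a smooth surrogate can reach S:V 2.8 cm⁻¹ at 56 cm³ while fitting
the phantom; an in-plane, volume-preserving elongation factor is the
fallback knob when the bite saturates (none of the six reference pairs
needs it). The fit is a two-stage monotone search (bite depth against
scale-normalized S:V on a coarse grid, then isotropic scale against
volume, polished jointly at the output resolution with damped steps);
both achieved values land within 1% of target, against a 2% contract.
Volumes are measured as voxel count × voxel volume; surfaces as the area
of the marching-cubes isosurface of the fractional occupancy field at
0.5 — never by voxel-face counting, which overestimates curved surfaces.

**Rasterization.** Shapes are analytic; occupancy is the fraction of
3 × 3 × 3 sub-voxel sample points inside the solid. Two truth modes
exist, and keeping them distinct matters:

- `boundary="fractional"` mixes concentrations by occupancy at structure
  boundaries — the physical truth of a continuous object sampled on a
  grid. Against the 0.5-threshold analysis masks this already carries a
  digitization PVE of several percent for the high-S:V kidneys, which is
  exactly what CT-based segmentation of a real insert sees.
- `boundary="labels"` paints each label region with its nominal
  concentration — the piecewise-constant premise under which the seven
  corrections are mathematically exact. Exactness claims (and the
  acceptance run) use this mode; edge-artifact and realism checks use
  the fractional mode.

**Concentrations.** The three bundled phantoms follow the reference
schedule: background starting near 30–34 MBq/L with a ~12-fold hotter
target compartment, five further rows with activity added to the
background (target decaying slightly), giving TBR ≈ 12 down to 2. The
canonical internal unit is Bq/mL; MBq/L inputs are converted by ×1000 at
ingest to keep a single unit inside the pipeline.

## Forward model

Acquisition plus reconstruction is abstracted as stationary convolution
with a separable anisotropic Gaussian, FWHM (8.8, 11.0, 9.2) mm along
(x, y, z) — the measured system resolution — sampled per axis, truncated
at 4σ and renormalized to sum exactly 1, with zero-padding boundaries
(the phantom is surrounded by air; wrap-around would fabricate
spill-in). The default 2.21 mm isotropic grid spans a 350 × 260 × 220 mm
field of view, leaving ≥ 4σ of air around the body so kernel mass is
conserved.

Optional Poisson count noise: expected counts per voxel equal
concentration × voxel volume × κ, with κ in counts/Bq; the default
κ = 0.0438 corresponds to a camera sensitivity of ≈ 18.26 counts/s/MBq
integrated over a ≈ 40-minute acquisition and is a modeling choice (no
per-voxel count density is prescribed anywhere). Noise is off by
default; every noisy run carries an explicit seed.

Deliberately not modeled: attenuation, scatter, dead time, and OSEM
reconstruction. Reconstruction regularization makes measured uncorrected
RCs nearly TBR-independent on real systems, which a pure-blur model does
not reproduce; consequently the low-TBR under-correction magnitudes of
the physical study are treated as directional references only, and all
robustness results here isolate the perturbation by referencing the
matched (unperturbed) correction of the same synthetic observation
rather than RC = 1.

## Evaluation

- Recovery coefficient RC = C / C_cal, with C the mean over the
  anatomical mask and C_cal the known true concentration.
- Background control RC over the background mask eroded by 3 cm (exact
  Euclidean distance, clearing the spill-over range).
- Peripheral RCs over 3-voxel-thick shells around the kidney masks,
  restricted to the background label; the reference concentration is the
  background's (the shell lies in background).
- Calibration factor CF = N_ave / C_cal over a cylindrical VOI (default
  168 mm × 146 mm, 80% of the calibration phantom's inner dimensions),
  and the relative CF decrease between two recordings.
- Line-source FWHM from a 40 mm profile with a 3 × 3-voxel cross-section
  through the intensity maximum, half-maximum crossings linearly
  interpolated; estimates below 1.5 voxels are flagged
  resolution-limited.

**Robustness sweeps** (all on the highest-TBR observation):
PSF mismatch (FWHM ± 6 mm in 2 mm steps applied to all axes; per-axis
perturbation available), registration mismatch (kidney masks shifted
jointly ± 3 voxels per axis in 1-voxel steps; vacated voxels become
background, entered voxels are overwritten), and background
heterogeneity (lung segmentation merged into the background and uniform
activity added to the observed image's lung voxels until the merged
background mean rises by a ratio of 1→4 in 0.25 steps; the added
activity is confined to the lung voxels exactly). Biases are reported
per kidney and method, signed and absolute, relative to the unperturbed
reference — zero at the null perturbation by construction.

## Numerical choices

- Convolution: separable `convolve1d` passes, verified against a direct
  shift-and-add sum to 1e-10 relative on small grids.
- One convolution per region builds all spill-over quantities; sweeps
  share a blurred-mask cache and re-blur only regions whose masks
  changed.
- Erosion/dilation use exact Euclidean distance transforms (a physical
  "3 cm" must not depend on the chamfer approximation); shells use
  Euclidean balls in index space on the isotropic working grid.
- Nearest-neighbor resampling aligns outer grid faces, so halving the
  spacing reproduces each source voxel as a 2 × 2 × 2 block and
  resampling to the same spacing is bit-identical.
- Degenerate inputs fail loudly: empty erosions, empty regions,
  ill-conditioned transfer matrices, non-finite voxels, kernels wider
  than the image, shapes outside the grid, and infeasible surrogate
  targets (below 1.05× the equal-volume-sphere S:V bound, or above the
  bean family's reach) all raise with diagnostics.

## Problem sizes

The default working grid is 2.21 mm isotropic (160 × 118 × 100 voxels).
Surrogate S:V reporting uses a 1 mm grid. The bundled property suite
runs the three robustness sweeps on the small-kidney phantom at full
resolution, with the registration sweep exercised along one axis (the
function supports all three); these sizes were chosen so a complete run
of generator + forward model + all seven corrections + sweeps stays in
the minutes range on a single CPU.

## Known limitations

- Stationary PSF only; distance-variant SPECT resolution is out of scope.
- No projection-domain physics (attenuation, scatter, dead time, OSEM),
  so absolute uncorrected-RC magnitudes and low-TBR recovery losses of
  physical acquisitions are reproduced qualitatively, not numerically.
- Kidney surrogates match volume and S:V, not patient shape; claims that
  depend on higher-order shape descriptors are outside the generator's
  reach.
- Passing tests on synthetic phantoms demonstrate algorithmic
  correctness and trend reproduction, not end-to-end accuracy on a real
  camera.
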