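# spectpvc

Anatomy-based partial volume correction (PVC) for quantitative SPECT,
with a fully synthetic kidney-phantom test bench.

Post-therapy ¹⁷⁷Lu SPECT drives kidney dosimetry in radionuclide
therapy, but the ≈ 9–11 mm reconstructed resolution biases the measured
activity concentration of kidneys by tens of percent (the partial
volume effect, PVE). Given a CT-derived segmentation `s_1…s_N` and the
system PSF `h`, anatomy-based PVC undoes the exchange of activity
between regions. This package is for physicists and method developers
who need the seven standard corrections, a controllable digital phantom
to validate them on, and the recovery-coefficient / robustness analyses
built around them.

## Methods implemented

Region-based (corrected means only), solving `A = Gᵀ C` with

```
GTM:    G_ij = Σ (s_i ⊛ h) · s_j / |s_j|          A_i = Σ s_i · I / |s_i|
Labbé:  G_ij = Σ (s_i ⊛ h) · (s_j ⊛ h) / |s_j|    A_i = Σ (s_i ⊛ h) · I / |s_i|
```

and voxel-based (corrected images), seeded by either set of means:

```
MTC:  I_c = Σ_j s_j · (I − (Σ_{i≠j} C_i s_i) ⊛ h) / (s_j ⊛ h)
RBV:  I_c = I · S / (S ⊛ h),   S = Σ_j C_j s_j
IY:   RBV with means bootstrapped from I itself, iterated (default 10×)
```

The synthetic bench reproduces three modified IEC body phantoms — six
spheres (10–37 mm), a cold lung insert, a holder plate, and kidney
surrogates fitted to the printed kidney-pair geometry (volume and
surface-to-volume ratio within 2%) — imaged at six target-to-background
ratios with an anisotropic Gaussian PSF (FWHM 8.8/11.0/9.2 mm) and
optional Poisson count noise. See `docs/methods.md` for the model,
assumptions and design choices.

## Worked example

```python
from spectpvc import (PSFModel, PartialVolumeCorrector, iec_phantom_spec,
                      simulate_observation, assemble_phantom)

spec = iec_phantom_spec("iec1")            # small kidney pair, TBR ~ 11.2
truth, labels = assemble_phantom(spec, boundary="labels")
observed = simulate_observation(truth, PSFModel((8.8, 11.0, 9.2)))

pvc = PartialVolumeCorrector(method="gtm", fwhm=(8.8, 11.0, 9.2)).fit(labels)
corrected_means = pvc.predict(observed)

for label in (1, 2):
    mask = labels.mask(label)
    uncorrected = observed.values[mask].mean()
    corrected = corrected_means[list(pvc.region_ids_).index(label)]
    print(f"{labels.names[label]}: uncorrected RC = {uncorrected / spec.target_conc:.3f}, "
          f"GTM-corrected RC = {corrected / spec.target_conc:.3f}")
```

prints

```
kidney_L: uncorrected RC = 0.687, GTM-corrected RC = 1.000
kidney_R: uncorrected RC = 0.635, GTM-corrected RC = 1.000
```

The recovery coefficient RC = C / C_cal compares the measured mean
concentration with the known filled concentration; 1 means perfect
quantification. Blurring alone costs the small kidney pair 31–37% of
its signal; with matched PSF and masks the correction recovers it
essentially exactly. The same estimator exposes
`transform(observed)` for the voxel-based methods (`gtm+mtc`,
`labbe+rbv`, `iy`, …), and the corrected image can be written back to
NIfTI with `spectpvc.write_image`.

A CLI covers end-to-end runs:

```
spectpvc make-phantom            # truth images + label maps (bundled study config)
spectpvc simulate                # blurred observations
spectpvc correct --image obs.nii.gz --labels labels.nii.gz \
    --fwhm 8.8 11.0 9.2 --method gtm+rbv --out corr.nii.gz --means means.csv
spectpvc evaluate                # RC vs TBR / S:V tables + robustness sweeps
spectpvc report -r results       # summary figures
```

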