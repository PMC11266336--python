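# Default study configuration: three modified IEC phantoms, each imaged at
# six target-to-background ratios with activity progressively added to the
# background.  Concentrations in MBq/L; the working grid is 2.21 mm
# isotropic; the correction PSF is the measured system resolution; the
# iterative-Yang correction runs 10 iterations.
spacing_mm: 2.21
psf_fwhm_mm: [8.8, 11.0, 9.2]
methods: [gtm, labbe, gtm+mtc, labbe+mtc, gtm+rbv, labbe+rbv, iy]
iy_n_iter: 10
iy_tol: 1.0e-5
boundary: fractional
noise: null            # deterministic by default; set {kappa: 0.0438, seed: N} for counts
output_dir: results

phantoms:
  - name: iec1          # small kidney pair
    kidney_set: small
    background_MBq_per_L: [33.8, 39.7, 49.9, 65.1, 96.1, 190.2]
    target_MBq_per_L: [378.7, 375.8, 374.9, 373.8, 372.7, 371.1]
  - name: iec2          # medium kidney pair
    kidney_set: medium
    background_MBq_per_L: [29.6, 34.8, 43.6, 58.6, 88.2, 171.7]
    target_MBq_per_L: [354.8, 352.9, 351.7, 350.9, 349.9, 347.7]
  - name: iec3          # large kidney pair
    kidney_set: large
    background_MBq_per_L: [32.4, 38.4, 48.2, 62.1, 104.4, 192.1]
    target_MBq_per_L: [357.5, 356.6, 355.6, 354.8, 354.1, 353.3]

sweeps:
  psf_deltas_mm: [-6, -4, -2, 0, 2, 4, 6]
  registration_max_offset_voxels: 3
  registration_axes: [0, 1, 2]
  heterogeneity_ratios: [1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5, 2.75, 3.0, 3.25, 3.5, 3.75, 4.0]
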