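"""Reference values of the emulated physical phantom study.

These constants describe the three modified IEC body phantoms the
synthetic generator reproduces: the geometry of the three printed kidney
pairs (volume, surface, surface-to-volume ratio), the measured activity
concentration schedule for the six acquisitions of each phantom, the
measured system PSF, and the tomographic calibration factor of the
camera.  Concentrations are stored in MBq/L as tabulated; the generator
converts to the canonical Bq/mL (x1000) at ingest.
"""

from __future__ import annotations

#: (volume cm^3, surface cm^2, surface-to-volume cm^-1) for each printed kidney.
KIDNEY_GEOMETRY: dict[str, dict[str, tuple[float, float, float]]] = {
    "small": {"R": (56.3, 156.3, 2.8), "L": (70.7, 163.2, 2.3)},
    "medium": {"R": (111.6, 194.7, 1.7), "L": (113.1, 201.2, 1.8)},
    "large": {"R": (159.1, 239.3, 1.5), "L": (161.0, 251.3, 1.6)},
}

#: Activity-concentration schedule per phantom: six acquisitions with
#: activity progressively added to the background (targets decay slightly).
#: Concentrations in MBq/L; TBR as tabulated (= target / background).
CONCENTRATION_SCHEDULE: dict[str, dict[str, tuple[float, ...]]] = {
    "iec1": {  # small kidney pair
        "background": (33.8, 39.7, 49.9, 65.1, 96.1, 190.2),
        "target": (378.7, 375.8, 374.9, 373.8, 372.7, 371.1),
        "tbr": (11.2, 9.5, 7.5, 5.7, 3.9, 2.0),
    },
    "iec2": {  # medium kidney pair
        "background": (29.6, 34.8, 43.6, 58.6, 88.2, 171.7),
        "target": (354.8, 352.9, 351.7, 350.9, 349.9, 347.7),
        "tbr": (12.0, 10.1, 8.1, 6.0, 4.0, 2.0),
    },
    "iec3": {  # large kidney pair
        "background": (32.4, 38.4, 48.2, 62.1, 104.4, 192.1),
        "target": (357.5, 356.6, 355.6, 354.8, 354.1, 353.3),
        "tbr": (11.0, 9.3, 7.4, 5.7, 3.4, 1.8),
    },
}

PHANTOM_KIDNEY_SET = {"iec1": "small", "iec2": "medium", "iec3": "large"}

#: System PSF at the FOV center, mm FWHM along (x, y, z).
PSF_FWHM_MM = (8.8, 11.0, 9.2)

#: Working grid after resampling, mm (isotropic).
WORKING_SPACING_MM = 2.21

#: Acquisition-grid voxel size, mm (isotropic).
ACQUISITION_SPACING_MM = 4.42

#: Mean tomographic calibration factor, counts/s/MBq, and the two extreme
#: values observed over the activity range (low-activity vs high-activity).
CALIBRATION_FACTOR = 18.26
CALIBRATION_FACTOR_EXTREMES = (18.40, 17.95)

#: Standard IEC sphere diameters, mm.
SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)

MBQ_PER_L_TO_BQ_PER_ML = 1000.0
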