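"""Shared fixtures.

The full-resolution phantom runs and the robustness sweeps are expensive
(a few 3-D convolutions each), so they are built once per session and
shared between the property tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from spectpvc import reference
from spectpvc.core import ActivityImage, LabelMap, VoxelGrid
from spectpvc.evaluation import (
    PhantomRun,
    heterogeneity_sweep,
    kidney_rc_table,
    prepare_run,
    psf_mismatch_sweep,
    registration_sweep,
    uncorrected_kidney_rc,
)
from spectpvc.forward import simulate_observation
from spectpvc.phantom import iec_phantom_spec, make_kidney_surrogate, tbr_series
from spectpvc.psf import PSFModel, convolve_values
from spectpvc.pvc import METHODS, RegionContext, run_pvc


# ---------------------------------------------------------------------------
# Small deterministic toy phantom: three regions on a 32^3 grid
# ---------------------------------------------------------------------------


def build_toy(n=32, spacing=2.0, concentrations=(400.0, 350.0, 33.0), seed=0):
    grid = VoxelGrid((n, n, n), (spacing,) * 3)
    x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    lab = np.zeros((n, n, n), dtype=np.int32)
    lab[((x - 10) ** 2 + (y - 12) ** 2 + (z - 16) ** 2) < 36] = 1
    lab[((x - 22) ** 2 + (y - 18) ** 2 + (z - 16) ** 2) < 25] = 2
    body = ((x - 16) ** 2 + (y - 16) ** 2 + (z - 16) ** 2) < 169
    lab[body & (lab == 0)] = 3
    labels = LabelMap(grid, lab, {1: "hot_a", 2: "hot_b", 3: "background"})
    c_true = dict(zip((1, 2, 3), concentrations))
    S = np.zeros((n, n, n))
    for k, v in c_true.items():
        S[lab == k] = v
    return grid, labels, c_true, S


@pytest.fixture(scope="session")
def toy():
    """(grid, labels, C_true, piecewise-constant truth S) for a 3-region toy."""
    return build_toy()


@pytest.fixture(scope="session")
def toy_ideal(toy):
    """Toy observation in the ideal limit: S blurred with the default PSF."""
    grid, labels, c_true, S = toy
    psf = PSFModel()
    observed = ActivityImage(grid, convolve_values(S, psf, grid.spacing))
    return observed, labels, c_true, S, psf


# ---------------------------------------------------------------------------
# Full-resolution IEC-1 phantom (TBR ~ 12) and sweeps
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def iec1_run() -> PhantomRun:
    """IEC-1 (small kidney pair), first concentration row, piecewise-constant
    truth, noise-free observation with the matched PSF."""
    spec = iec_phantom_spec("iec1")
    return prepare_run(spec, boundary="labels", name="iec1")


@pytest.fixture(scope="session")
def iec1_rc_table(iec1_run):
    """Corrected kidney RCs of all seven methods on the matched run."""
    return kidney_rc_table(iec1_run, METHODS)


@pytest.fixture(scope="session")
def psf_sweep(iec1_run):
    return psf_mismatch_sweep(iec1_run, deltas_mm=(-6, -4, -2, 0, 2, 4, 6))


@pytest.fixture(scope="session")
def reg_sweep(iec1_run):
    # one axis keeps the suite fast; the monotonicity/ordering claims are
    # axis-generic and the sweep function itself supports all axes
    return registration_sweep(iec1_run, max_offset_voxels=3, axes=(0,))


@pytest.fixture(scope="session")
def het_sweep(iec1_run):
    return heterogeneity_sweep(iec1_run, ratios=tuple(np.arange(1.0, 4.01, 0.25)))


@pytest.fixture(scope="session")
def iec1_fractional_series():
    """Fractional-boundary truth rows (first and last TBR) of IEC-1, with
    observed images and shared labels: the realistic-segmentation regime
    in which the MTC edge artifact appears."""
    spec = iec_phantom_spec("iec1")
    schedule = reference.CONCENTRATION_SCHEDULE["iec1"]
    images, labels = tbr_series(
        spec, schedule["background"], schedule["target"], boundary="fractional"
    )
    psf = PSFModel()
    ctx = RegionContext(labels, psf)
    rows = {}
    for row in (0, 5):
        observed = simulate_observation(images[row], psf)
        corrected = {
            m: run_pvc(observed, ctx, method=m)[1] for m in ("gtm+mtc", "gtm+rbv")
        }
        rows[row] = {
            "truth": images[row],
            "observed": observed,
            "corrected": corrected,
            "background_Bq_mL": schedule["background"][row] * 1000.0,
            "tbr": schedule["tbr"][row],
        }
    return {"labels": labels, "context": ctx, "rows": rows, "spec": spec}


@pytest.fixture(scope="session")
def surrogate_fits():
    """All six kidney surrogates fitted to the reference geometry on a
    1 mm grid (the resolution used for mesh-based S:V reporting)."""
    fits = {}
    for kidney_set, geometry in reference.KIDNEY_GEOMETRY.items():
        for side, (volume, _, sv) in geometry.items():
            fits[f"{kidney_set}-{side}"] = make_kidney_surrogate(volume, sv, spacing=1.0)
    return fits


@pytest.fixture(scope="session")
def uncorrected_rc_vs_sv():
    """Uncorrected kidney RC and achieved S:V for all six surrogates at the
    highest-TBR row of each phantom."""
    points = []
    for name in ("iec1", "iec2", "iec3"):
        spec = iec_phantom_spec(name)
        run = prepare_run(spec, boundary="labels", name=name)
        rcs = uncorrected_kidney_rc(run)
        for side, label in zip((0, 1), (1, 2)):
            points.append((spec.kidneys[side].achieved_sv, rcs[label]))
    return points
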