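import numpy as np
import pytest

import seedlum as sl

# Published (flux_lm, germination %) calibration rows per species and the
# printed coefficients of the corresponding fitted lines B = a*(Phi*1e6) + b.
CALIBRATION_ROWS = {
    "galega": [(2.15e-6, 35.0), (3.23e-6, 41.0), (3.57e-6, 43.0)],
    "clover": [(3.15e-6, 11.0), (6.17e-6, 15.0), (9.46e-6, 21.0)],
    "alfalfa": [(3.56e-6, 38.0), (8.19e-6, 64.0), (13.8e-6, 76.0)],
}

PRINTED_COEFFS = {
    #            slope  intercept  R^2
    "galega": (5.62, 22.9, 0.9999),
    "clover": (1.59, 5.72, 0.9919),
    "alfalfa": (3.66, 28.2, 0.9315),
}


@pytest.fixture(scope="session")
def registry():
    return sl.default_registry()


@pytest.fixture
def calibration_points():
    def make(species):
        return [
            sl.CalibrationPoint(flux_lm=f, germination_pct=g, species=species)
            for f, g in CALIBRATION_ROWS[species]
        ]

    return make


def gaussian_curve(center, sigma, lo, hi, step=1.0, amplitude=1.0, role="emission"):
    grid = np.arange(lo, hi + step / 2, step)
    return sl.SpectralCurve(
        grid, amplitude * np.exp(-0.5 * ((grid - center) / sigma) ** 2), role=role
    )


def rect_curve(lo, hi, step=1.0, height=1.0, role="sensitivity"):
    """A rectangular band with (near-)sharp 1e-6 nm edge ramps, so the
    piecewise-linear representation matches the ideal step function."""
    inner = np.arange(lo + step, hi - step / 2, step)
    grid = np.concatenate(([lo - 1e-6, lo], inner, [hi, hi + 1e-6]))
    inten = np.full_like(grid, float(height))
    inten[0] = inten[-1] = 0.0
    return sl.SpectralCurve(grid, inten, role=role)
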