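import numpy as np
import pytest

from calphase import CalendarPDF, Determination, gen_calibration_curve


@pytest.fixture(scope="session")
def identity_curve():
    """mu(theta) = theta with negligible curve error: calibration reduces to
    the measurement's own normal error."""
    return gen_calibration_curve((25000, 5000), knot_step=20, wiggle_sd=0.0,
                                 error_level=0.01, seed=1, label="identity")


@pytest.fixture(scope="session")
def wiggly_curve():
    """Realistically wiggly synthetic curve with decadal-scale structure."""
    return gen_calibration_curve((25000, 5000), knot_step=20, wiggle_sd=20.0,
                                 error_level=12.0, seed=42, label="wiggly")


@pytest.fixture
def normal_pdf():
    """Factory for a sharp normal CalendarPDF on the standard 5-yr lattice."""

    def make(mean: float, sd: float = 40.0, resolution: float = 5.0) -> CalendarPDF:
        lo = np.floor((mean - 8 * sd) / resolution) * resolution
        grid = np.arange(lo, mean + 8 * sd, resolution)
        mass = np.exp(-0.5 * ((grid - mean) / sd) ** 2)
        return CalendarPDF(grid, mass / mass.sum(), resolution)

    return make


@pytest.fixture
def det():
    def make(cra: float, sigma: float = 50.0, lab_id: str = "X") -> Determination:
        return Determination(lab_id, cra, sigma)

    return make
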