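import numpy as np
import pytest

from hsitss import (
    SpectralModelParams,
    build_mask,
    calibrate_reflectance,
    draw_tss_values,
    grid_layout,
    make_wavelength_grid,
    render_capture,
)


@pytest.fixture(scope="session")
def grid512():
    return make_wavelength_grid(512, 380.0, 1030.0)


@pytest.fixture(scope="session")
def default_params():
    return SpectralModelParams()


@pytest.fixture(scope="session")
def noise_free_params():
    return SpectralModelParams(noise_sd=0.0, scatter_sd=0.0, saturation_rate=0.0)


@pytest.fixture(scope="session")
def capture(grid512, default_params):
    """One default-parameter capture with 6 fruit blobs, shared across tests."""
    tss = draw_tss_values(6, seed=101)
    return render_capture(
        tss, grid512, grid_layout(6, 9.0), default_params, seed=202
    )


@pytest.fixture(scope="session")
def calibrated(capture):
    return calibrate_reflectance(capture.raw, capture.white, capture.dark)


@pytest.fixture(scope="session")
def fruit_mask(calibrated):
    return build_mask(calibrated)
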