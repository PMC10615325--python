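import numpy as np
import pytest

import foustrack as ft


@pytest.fixture(scope="session")
def loss_model() -> ft.BendLossModel:
    return ft.BendLossModel.calibrated()


@pytest.fixture(scope="session")
def itf() -> ft.ITFModel:
    return ft.ITFModel()


@pytest.fixture(scope="session")
def water() -> ft.MediumSpec:
    return ft.WATER


@pytest.fixture(scope="session")
def sector_probe() -> ft.ProbeModel:
    """16-element 6 MHz phased array, 90-degree sector, focus 5.5 cm."""
    return ft.make_probe("phased_sector", 16, 0.125e-3, 6e6, fov_angle=90.0, focus_depth=0.055)


@pytest.fixture(scope="session")
def linear_probe() -> ft.ProbeModel:
    """128-element linear array, 0.3 mm pitch, mid-band 6.5 MHz."""
    return ft.make_probe("linear", 128, 0.3e-3, 6.5e6, focus_depth=0.055)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
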