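import numpy as np
import pytest

from gelqa import (
    DoseGrid,
    GelResponseModel,
    GridSpec,
    ShotSpec,
    default_mri_grid,
    make_shot_dose_field,
)

CENTER = (100.0, 100.0, 100.0)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """Sagittal-style grid, 12 mm half-extent, fine in plane."""
    return default_mri_grid(extent_mm=12.0)


@pytest.fixture(scope="session")
def shot_4mm() -> ShotSpec:
    return ShotSpec(collimator=4, center=CENTER, prescription_dose=4.0)


@pytest.fixture(scope="session")
def truth_4mm(small_grid, shot_4mm) -> DoseGrid:
    return make_shot_dose_field([shot_4mm], small_grid)


@pytest.fixture(scope="session")
def gel() -> GelResponseModel:
    return GelResponseModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
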