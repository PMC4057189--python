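import numpy as np
import pytest

from qctlung import (
    ARDS_MASS_FRACTIONS,
    AcquisitionSettings,
    NoiseModel,
    PhantomSpec,
    make_phantom,
    simulate_scan,
)

#: The four studied tube-current settings and their measured noise (HU).
NOISE_TABLE = {140.0: 10.0, 60.0: 15.9, 15.0: 37.5, 7.5: 73.8}


@pytest.fixture(scope="session")
def noise_model():
    return NoiseModel.from_table(NOISE_TABLE)


@pytest.fixture(scope="session")
def healthy_phantom():
    return make_phantom(PhantomSpec(condition="healthy", seed=11))


@pytest.fixture(scope="session")
def ards_phantom():
    return make_phantom(
        PhantomSpec(condition="ARDS", target_fractions=dict(ARDS_MASS_FRACTIONS), seed=12)
    )


@pytest.fixture(scope="session")
def small_healthy_phantom():
    """Small grid for fast structural tests."""
    return make_phantom(
        PhantomSpec(
            grid_shape=(64, 64, 32),
            condition="healthy",
            lung_semiaxes=(9.0, 15.0, 8.0),
            lung_offset=13.0,
            body_semiaxes=(29.0, 24.0),
            aorta_radius=3.5,
            aorta_offset=10.0,
            seed=13,
        )
    )


def scan_at(phantom, mas, noise_model, seed):
    return simulate_scan(phantom, AcquisitionSettings(mAs=mas), noise_model, seed=seed)
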