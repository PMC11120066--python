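import numpy as np
import pytest

from brachysafe.physics import load_attenuation, load_conversion, load_spectrum
from brachysafe.transport import (
    DepthDoseSeries,
    TallyResult,
    TransportPhysics,
)


@pytest.fixture(scope="session")
def spectrum():
    return load_spectrum()


@pytest.fixture(scope="session")
def water():
    return load_attenuation("water")


@pytest.fixture(scope="session")
def kerma_curve():
    return load_conversion("kerma_to_h10")


@pytest.fixture(scope="session")
def fluence_curve():
    return load_conversion("fluence_to_h10")


@pytest.fixture(scope="session")
def physics_default():
    return TransportPhysics.default()


@pytest.fixture(scope="session")
def physics_no_scatter():
    return TransportPhysics.default(scatter_enabled=False)


@pytest.fixture(scope="session")
def physics_vacuum(spectrum, fluence_curve):
    return TransportPhysics(
        spectrum=spectrum, attenuation=None, fluence_curve=fluence_curve
    )


def make_series(depths, values, distance_cm=100.0, rel_se=0.0, seed=0):
    """Hand-built DepthDoseSeries for fitting/normalization tests."""
    points = tuple(
        (
            float(z),
            TallyResult(
                h10_per_decay_pSv=float(v),
                rel_se=rel_se,
                n_histories=1,
                seed=seed,
            ),
        )
        for z, v in zip(depths, values)
    )
    return DepthDoseSeries(distance_cm=distance_cm, points=points)


@pytest.fixture
def exp_series():
    z = np.arange(1, 21, dtype=float)
    return make_series(z, 1.4026 * np.exp(-0.3273 * z))
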