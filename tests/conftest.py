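import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import tmstarget as tt

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_head():
    return tt.make_head(85.0, seed=0)


@pytest.fixture(scope="session")
def sphere():
    return tt.SphereConductor(radius=85.0)


@pytest.fixture(scope="session")
def coil(sphere):
    """Default figure-eight coil calibrated on the reference sphere."""
    return tt.calibrated_default_coil(sphere)


@pytest.fixture(scope="session")
def calibration(coil, sphere):
    spec = tt.CalibrationSpec()
    e_ref = tt.e_ref_at_depth(coil, sphere, spec)
    return tt.smt_to_didt(dataclasses.replace(spec, e_ref=e_ref))


@pytest.fixture(scope="session")
def interior_points(sphere):
    """Deterministic cloud of points well inside the sphere."""
    rng = np.random.default_rng(12345)
    u = rng.normal(size=(400, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = sphere.radius * 0.9 * rng.uniform(0.0, 1.0, 400) ** (1 / 3)
    return u * r[:, None]
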