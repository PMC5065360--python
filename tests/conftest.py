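import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    """A small grid shape for fast phantom round trips."""
    return (12, 12, 8)


@pytest.fixture(scope="session")
def scheme():
    from gliodti import default_scheme

    return default_scheme()


@pytest.fixture(scope="session")
def isotropic_phantom():
    """Default isotropic-region phantom, built once per session."""
    from gliodti import build_phantom, default_phantom_spec

    return build_phantom(default_phantom_spec(style="isotropic"))


@pytest.fixture(scope="session")
def prolate_phantom():
    from gliodti import build_phantom, default_phantom_spec

    return build_phantom(default_phantom_spec(style="prolate"))


def small_isotropic_spec(d=1.0e-3, grid=(12, 12, 8)):
    from gliodti import Box, PhantomSpec, Region, isotropic

    return PhantomSpec(
        grid_shape=grid,
        regions=(Region("background_wm", Box((0, 0, 0), grid), isotropic(d), s0=1.0),),
    )


@pytest.fixture(scope="session")
def rotation():
    """A fixed, non-trivial orthonormal rotation matrix."""
    rng = np.random.default_rng(7)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
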