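import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nervedti as nd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return nd.default_scheme()


@pytest.fixture(scope="session")
def straight_noiseless_phantom():
    """Default-geometry phantom, zero drift, zero noise (exact ground truth)."""
    spec = nd.PhantomSpec(fascicle_drift_amplitude=0.0, noise_sigma=0.0)
    return nd.make_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The default noisy phantom (SNR ≈ 14 in the fascicles)."""
    return nd.make_phantom(nd.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom for fast structural tests."""
    return nd.PhantomSpec(
        grid=(40, 40, 6),
        voxel_size=(0.06, 0.06, 0.625),
        nerve_radius=1.1,
        n_fascicles=3,
        target_fascicular_ratio=0.40,
        fascicle_drift_amplitude=0.0,
        perineurium_thickness=0.06,
        seed=7,
    )


def forward_signal(evals, evecs, scheme, s0=100.0):
    """Noiseless Stejskal–Tanner signals for one tensor (test helper)."""
    D = evecs @ np.diag(evals) @ evecs.T
    quad = np.einsum("ij,mi,mj->m", D, scheme.bvecs, scheme.bvecs)
    return s0 * np.exp(-scheme.bvals * quad * 1e-3)
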