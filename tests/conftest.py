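import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mrnquant as mq

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_protocol() -> mq.AcquisitionProtocol:
    """Scaled-down geometry: same echo times and slab layout, coarse grid."""
    return mq.AcquisitionProtocol(matrix=128, slices_per_slab=2)


@pytest.fixture(scope="session")
def noise_free_config() -> mq.CohortConfig:
    """Default cohort parameters with zero noise/SD/jitter (deterministic)."""
    return mq.CohortConfig(n_case=2, n_control=2).noise_free()


@pytest.fixture(scope="session")
def noise_free_frames(small_protocol, noise_free_config):
    """One deterministic mini-cohort pushed through measure + aggregate."""
    return mq.simulate_measure_aggregate(small_protocol, noise_free_config,
                                         seed=7)


def homogeneous_volume(value1=100.0, value2=50.0, shape=(8, 8, 2),
                       te1=14.0, te2=86.0, spacing=1.0, slab_id=1):
    vol = mq.DualEchoVolume(
        image_te1=np.full(shape, float(value1)),
        image_te2=np.full(shape, float(value2)),
        te1=te1, te2=te2, pixel_spacing=spacing, slab_id=slab_id,
    )
    mask = mq.NerveMask(mask=np.ones(shape, dtype=bool), slab_id=slab_id)
    return vol, mask
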