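import numpy as np
import pytest

from wgbc.synthetic import CohortSpec, HubRegion, demo_spec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 2+2-subject, 12-voxel-cube cohort with one hub; shared across tests."""
    spec = CohortSpec(
        n_group_a=2,
        n_group_b=2,
        grid_shape=(12, 12, 12),
        n_volumes=60,
        hub_regions=[HubRegion((4, 6, 6), 2.0, 0.6)],
        rng_seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_effect_cohort():
    """16-voxel grid, 6+6 subjects, planted group effect; for recovery plumbing."""
    return generate_cohort(demo_spec(effect=True, n_per_group=6, grid=16, n_volumes=100, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
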