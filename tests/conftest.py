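import numpy as np
import pytest

from kneealign.phantom import PhantomSpec, default_schema, generate_phantom


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def neutral_phantom():
    return generate_phantom(PhantomSpec(true_atfa=0.0, seed=42))


@pytest.fixture(scope="session")
def valgus_phantom():
    return generate_phantom(PhantomSpec(true_atfa=7.0, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_landmark_arrays(rng, n_sets, n_points, low=10.0, high=110.0):
    """Seeded random (n_points, 2) coordinate arrays."""
    return [rng.uniform(low, high, size=(n_points, 2)) for _ in range(n_sets)]
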