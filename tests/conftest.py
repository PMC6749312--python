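import numpy as np
import pytest

from sparsepose.quatkin import default_skeleton
from sparsepose.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def skel():
    return default_skeleton(1.75)


@pytest.fixture()
def rng():
    # function-scoped so every test draws from a fresh, order-independent stream
    return np.random.default_rng(20260928)


def random_unit_quats(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


@pytest.fixture(scope="session")
def tiny_gait_dataset():
    """3 subjects x 20 s of gait at 60 Hz; shared across training tests."""
    cfg = SyntheticConfig(n_subjects=3, trials=(("gait", 20.0),), seed=7)
    return generate_dataset(cfg)
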