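import numpy as np
import pytest

import glymkit as gk


@pytest.fixture(scope="session")
def two_shell_gtab():
    """The emulated acquisition: 2 x b=0 + 45 @ b=1000 + 90 @ b=2500."""
    return gk.default_gradient_table()


@pytest.fixture(scope="session")
def noise_free_phantom():
    """A noise-free structural phantom shared by segmentation tests."""
    spec = gk.StructuralPhantomSpec(shape=(40, 40, 40), noise_sigma=(0.0, 0.0), seed=3)
    return gk.make_structural_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    return gk.make_synthetic_cohort(gk.CohortGenSpec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
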