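import numpy as np
import pytest

from drowsinet import synthetic


@pytest.fixture()
def rng():
    # fresh per test so results never depend on test execution order
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """8 subjects x 6 frames, default generator conditions."""
    frames, manifest = synthetic.generate_dataset(8, 6, seed=101)
    return frames, manifest


@pytest.fixture(scope="session")
def sample_frame():
    profile = synthetic.generate_subject(3, seed=42)
    return synthetic.render_frame(profile, 0)
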