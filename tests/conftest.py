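import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_carpet():
    """3^5 Sierpinski carpet: big enough for scaling, cheap to analyse."""
    from multifrac import sierpinski_carpet

    return sierpinski_carpet(5)


@pytest.fixture(scope="session")
def mixed_fixture_images():
    """A spread of image types for invariant sweeps (binary, sparse, grayscale)."""
    from multifrac import chaos_game_sierpinski, sierpinski_carpet

    rng = np.random.default_rng(99)
    return {
        "carpet": sierpinski_carpet(4).image.astype(float),
        "chaos": chaos_game_sierpinski(2000, 243, seed=3).image.astype(float),
        "grayscale": rng.random((100, 80)),
        "uniform": np.ones((64, 64)),
        "single_pixel": np.eye(1, 50 * 40).reshape(50, 40),
    }
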