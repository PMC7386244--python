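import numpy as np
import pytest

from spotstack import synth


@pytest.fixture(scope="session")
def section_fixture():
    """One synthetic stained section with ground-truth mask and nuclei."""
    image, truth = synth.simulate_section_image(width=256, height=256, n_nuclei=50,
                                                seed=11)
    return image, truth


@pytest.fixture(scope="session")
def hex_10x10():
    return synth.make_hex_grid(10, 10, spacing_um=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
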