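import numpy as np
import pytest

from craniomech import synthetic_data as synth


@pytest.fixture(scope="session")
def tree32():
    return synth.pure_birth_tree(32, seed=1)


@pytest.fixture(scope="session")
def template_a():
    return synth.make_template("a")


@pytest.fixture(scope="session")
def small_study():
    """Six-taxon synthetic study with meshes, shared across tests."""
    return synth.generate_study(n_taxa=6, seed=7, noise_sd=0.3,
                                target_edge_mm=9.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])
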