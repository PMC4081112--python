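import numpy as np
import pytest

import retrosym as rs


@pytest.fixture(scope="session")
def small_template():
    """12 bilateral pairs + 5 midline points, exactly symmetric."""
    return rs.make_template(rs.TemplateSpec(n_pairs=12, n_midline=5, seed=2))


@pytest.fixture(scope="session")
def medium_template():
    """20 bilateral pairs + 6 midline points, exactly symmetric."""
    return rs.make_template(rs.TemplateSpec(n_pairs=20, n_midline=6, seed=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_config(rng, n=10):
    """Unstructured random landmark configuration."""
    return rs.LandmarkConfiguration(
        [f"l{i}" for i in range(n)], rng.normal(size=(n, 3)))
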