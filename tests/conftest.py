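import numpy as np
import pytest

from mbiclean import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_phantom():
    """A small fully featured phantom: disks, noise, aggregates, crosstalk."""
    spec = PhantomSpec(
        height=96,
        width=96,
        n_cells=4,
        cell_radius=(4, 6),
        n_aggregates=3,
        seed=11,
    )
    return generate_phantom(spec)
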