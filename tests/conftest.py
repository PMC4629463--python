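import numpy as np
import pytest

from neuromass.connectome import StructuralConnectome
from neuromass.synthetic import generate_healthy_connectome


def random_connectome(rng: np.random.Generator, n: int) -> StructuralConnectome:
    """Small random valid connectome for property tests."""
    w = rng.uniform(0, 10, (n, n))
    w = (w + w.T) / 2
    mask = rng.uniform(size=(n, n)) < 0.6
    mask &= mask.T
    w *= mask
    np.fill_diagonal(w, 0)
    lengths = np.where(w > 0, rng.uniform(5, 150, (n, n)), 0.0)
    lengths = np.where(w > 0, (lengths + lengths.T) / 2, 0.0)
    np.fill_diagonal(lengths, 0)
    return StructuralConnectome(
        subject_id=f"rand-{rng.integers(1e6)}",
        region_labels=[f"r{i}" for i in range(n)],
        weights=w,
        lengths=lengths,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_connectome():
    """10-region healthy connectome shared across simulator tests."""
    return generate_healthy_connectome(10, seed=1)
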