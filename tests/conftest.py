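import numpy as np
import pytest

from euscan.variantio import HaplotypeMatrix


def toy_matrix(calls, pops=None, chrom="s1", positions=None, samples=None):
    """Small HaplotypeMatrix from a list-of-lists (individuals x sites)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, s = calls.shape
    if positions is None:
        positions = np.arange(s) * 10
    if pops is None:
        pops = ["p1"] * n
    if samples is None:
        samples = [f"ind{i}" for i in range(n)]
    return HaplotypeMatrix(
        chrom=np.array([chrom] * s, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        calls=calls, samples=samples,
        populations=np.array(pops, dtype=object))


@pytest.fixture
def make_matrix():
    return toy_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """20 individuals x 500 sites with planted missingness, two populations."""
    calls = (rng.random((20, 500)) < rng.uniform(0.02, 0.5, size=500)).astype(np.int8)
    miss = rng.random((20, 500)) < 0.1
    calls[miss] = -1
    depth = rng.integers(0, 12, size=(20, 500)).astype(np.int32)
    m = toy_matrix(calls, pops=["popA"] * 10 + ["popB"] * 10,
                   positions=np.sort(rng.choice(100_000, size=500, replace=False)))
    m.depth = depth
    return m
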