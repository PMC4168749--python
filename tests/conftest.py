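import numpy as np
import pytest

from funcnet import GeneUniverse, NetworkMeta


@pytest.fixture
def universe():
    """Five genes, each with one synonym (greek letters)."""
    return GeneUniverse(
        ["G1", "G2", "G3", "G4", "G5"],
        [["alpha"], ["beta"], ["gamma"], ["delta"], ["epsilon"]],
        organism_name="toy",
    )


@pytest.fixture
def meta():
    return NetworkMeta(name="toy-net", group="co-expression")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
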