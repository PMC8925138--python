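import numpy as np
import pytest

from pairgeom.embedder import StubEmbedder
from pairgeom.msa import tokenize
from pairgeom.network import GeometryModel, NetConfig
from pairgeom.synthetic import (
    SyntheticBackboneSpec,
    SyntheticMsaSpec,
    synthetic_backbone,
    synthetic_msa,
)

@pytest.fixture(scope="session")
def stub():
    return StubEmbedder(seed=0)


@pytest.fixture(scope="session")
def small_msa():
    """8 x 32 synthetic alignment used across contract tests."""
    return synthetic_msa(SyntheticMsaSpec(c=32, r=8, mutation_rate=0.2, seed=1))


@pytest.fixture(scope="session")
def small_embedding(stub, small_msa):
    return stub.embed(tokenize(small_msa))


@pytest.fixture(scope="session")
def tiny_net_config():
    """Shrunk head network for gradient checks and fast training tests."""
    return NetConfig(reduction_channels=(8, 6), trunk_blocks=2, trunk_channels=6,
                     head_bins={"theta": 4, "phi": 3, "omega": 4, "dist": 5}, seed=3)


@pytest.fixture(scope="session")
def helix32():
    return synthetic_backbone(SyntheticBackboneSpec(L=32, architecture="ideal_helix",
                                                    seed=0))


@pytest.fixture(scope="session")
def hth40():
    return synthetic_backbone(
        SyntheticBackboneSpec(L=40, architecture="helix_turn_helix", seed=0)
    )


def random_chain(length: int, seed: int):
    return synthetic_backbone(
        SyntheticBackboneSpec(L=length, architecture="random_chain", seed=seed)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
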