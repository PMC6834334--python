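import numpy as np
import pytest

from multimorbinet import CellNetwork, InteractionNetwork


@pytest.fixture
def path_network() -> CellNetwork:
    """a - b - c - d chain."""
    return CellNetwork(
        cell_type="toy",
        nodes={"a", "b", "c", "d"},
        edges={("a", "b"), ("b", "c"), ("c", "d")},
    )


@pytest.fixture
def star_network() -> CellNetwork:
    """hub h with leaves l1..l4."""
    leaves = {f"l{i}" for i in range(1, 5)}
    return CellNetwork(
        cell_type="star",
        nodes={"h"} | leaves,
        edges={tuple(sorted(("h", l))) for l in leaves},
    )


@pytest.fixture
def small_interactome() -> InteractionNetwork:
    return InteractionNetwork.from_edges(
        [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c"), ("d", "e")]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
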