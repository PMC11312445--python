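import numpy as np
import pytest

from embryomodes.io import CellRecord, CountMatrix, ExpressionPosterior
from embryomodes.synthetic import make_topology


@pytest.fixture
def toy4():
    return make_topology("toy4")


@pytest.fixture
def mirror8():
    return make_topology("mirror8")


@pytest.fixture
def mirror16():
    return make_topology("mirror16")


@pytest.fixture
def small_counts():
    """3 cells x 2 genes with metadata, for I/O round trips."""
    cells = [
        CellRecord("c1", "e1", 16, mother_id="m1"),
        CellRecord("c2", "e1", 16, mother_id="m1"),
        CellRecord("c3", "e2", 16, mother_id="m2"),
    ]
    counts = np.array([[5, 9], [0, 3], [7, 2]])
    return CountMatrix(counts, ["gA", "gB"], cells)


@pytest.fixture
def small_posterior():
    cells = [CellRecord(f"c{i}", f"e{i // 2}", 16) for i in range(4)]
    rng = np.random.default_rng(0)
    X = rng.standard_normal((4, 3))
    eps = np.abs(rng.standard_normal((4, 3))) * 0.1
    return ExpressionPosterior(X, eps, ["g0", "g1", "g2"], cells)
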