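import numpy as np
import pytest

from dartpop.io import CHROMOSOMES, GeneticMap, MarkerMatrix
from dartpop.simulate import default_config, simulate_panel


def make_matrix(scores, genotype_ids=None, marker_ids=None):
    scores = np.asarray(scores, dtype=np.int8)
    n, m = scores.shape
    return MarkerMatrix(
        genotype_ids or [f"g{i}" for i in range(n)],
        marker_ids or [f"m{j}" for j in range(m)],
        scores,
    )


def random_matrix(rng, n, m, missing_rate=0.05):
    scores = rng.integers(0, 2, size=(n, m)).astype(np.int8)
    scores[rng.random((n, m)) < missing_rate] = -1
    return make_matrix(scores)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_panel():
    """Two-group panel (26/66) with ~315 markers, F_ST 0.13, 2D block."""
    cfg = default_config(seed=42, markers_per_chromosome={c: 15 for c in CHROMOSOMES})
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def study_panel():
    """Study-scale panel: 92 genotypes x 1,400 markers, F_ST 0.13."""
    return simulate_panel(default_config(seed=7))
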