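import numpy as np
import pytest

from operonevo import GenomeConfig


@pytest.fixture
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(20260101)


@pytest.fixture
def config():
    """Default genome: L=4900 kb, 3 genes, 100 kb imbalance tolerance."""
    return GenomeConfig()


@pytest.fixture
def small_config():
    return GenomeConfig(length_kb=100, n_genes=3, tolerance_kb=10)


def brute_force_min_arc(positions, length_kb):
    """Independent oracle: the shortest covering arc must start at a gene;
    take the minimum over starting genes of the clockwise arc reaching the
    gene just before it."""
    pos = sorted(positions)
    n = len(pos)
    if n < 2:
        return 0
    spans = []
    for i in range(n):
        start = pos[i]
        end = pos[i - 1]  # last gene reached going clockwise from start
        spans.append((end - start) % length_kb)
    return min(spans)
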