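import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from gmnet import GreyMatterVolume
from gmnet.synthetic import CohortSpec, VolumeSpec, generate_cohort, generate_gm_volume


@pytest.fixture
def planted_volume():
    """Default planted-signal volume: 8 designated pairs, loading 0.9."""
    return generate_gm_volume(VolumeSpec(seed=1))


@pytest.fixture
def uniform_volume():
    """Structureless volume: constant density everywhere (zero variance)."""
    return GreyMatterVolume(data=np.full((6, 6, 6), 0.5))


@pytest.fixture
def small_cohort():
    """Complete (no missingness) 120-subject cohort with a planted
    language interaction of 0.10 per predictor SD."""
    rng = np.random.default_rng(42)
    x = rng.normal(1.5, 0.1, 120)
    spec = CohortSpec(n_subjects=120, missing_rate_per_test=0.0, seed=42)
    table, truth = generate_cohort(spec, x)
    return table, truth


def random_graph_adj(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric boolean adjacency of an Erdos-Renyi graph."""
    a = rng.random((n, n)) < p
    a = np.triu(a, k=1)
    return a | a.T
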