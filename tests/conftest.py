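import numpy as np
import pytest

from sparseclr import SimParams, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def example_draws():
    """One filtered example dataset per library-size-variability level,
    matched latent effects apart from the sample effects (same seed)."""
    out = {}
    for sa in (0.0, 0.5, 1.0):
        params = SimParams(sigma_a=sa, fold_change=3.0, seed=42)
        out[sa] = simulate_dataset(params)
    return out


@pytest.fixture(scope="session")
def toy_counts():
    """Tiny deterministic count table used by the transform tests."""
    from sparseclr import CountMatrix

    counts = np.array([[0, 5, 3, 12],
                       [2, 0, 7, 1],
                       [4, 9, 0, 0],
                       [1, 1, 1, 30]])
    return CountMatrix(counts, [f"s{i}" for i in range(4)],
                       [f"t{j}" for j in range(4)])
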