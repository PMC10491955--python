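import numpy as np
import pytest

from nrfse.data import FrequencyMatrix
from nrfse.similarity import SimilarityView
from nrfse.simulate import SyntheticSpec, generate


def random_similarity(rng: np.random.Generator, n: int) -> SimilarityView:
    S = rng.uniform(size=(n, n))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityView(S)


def random_instance(seed: int, n: int = 10, m: int = 8, density: float = 0.5,
                    x: int = 3, y: int = 2):
    """A random frequency matrix with random symmetric similarity views."""
    rng = np.random.default_rng(seed)
    values = rng.integers(1, 6, size=(n, m))
    values[rng.uniform(size=(n, m)) >= density] = 0
    # guarantee the matrix has some known cells
    if not values.any():
        values[0, 0] = 3
    freq = FrequencyMatrix(values)
    drug_views = [random_similarity(rng, n) for _ in range(x)]
    effect_views = [random_similarity(rng, m) for _ in range(y)]
    return freq, drug_views, effect_views


@pytest.fixture(scope="session")
def small_dataset():
    """Rank-3 synthetic dataset shared by slower model-level tests."""
    return generate(SyntheticSpec(n=40, m=50, rank=3, density=0.4, seed=0))


@pytest.fixture(scope="session")
def cold_dataset():
    """Synthetic dataset with dedicated cold-start drugs and effects."""
    return generate(
        SyntheticSpec(
            n=40, m=50, rank=3, density=0.4, seed=1,
            cold_start_drugs=4, cold_start_effects=3,
        )
    )
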