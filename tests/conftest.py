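import numpy as np
import pytest

from dtilcm import DTIDataset, SyntheticSpec, generate


def make_similarity(rng: np.random.Generator, size: int) -> np.ndarray:
    """A random valid similarity matrix: symmetric, [0,1], unit diagonal."""
    raw = rng.random((size, size))
    sim = (raw + raw.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return sim


def make_dataset(rng: np.random.Generator, m: int = 8, n: int = 5, density: float = 0.3) -> DTIDataset:
    A = (rng.random((m, n)) < density).astype(int)
    # the spy threshold needs a target with >= 2 positives
    A[:3, 0] = 1
    return DTIDataset(
        drug_ids=[f"d{i}" for i in range(m)],
        target_ids=[f"t{j}" for j in range(n)],
        A=A,
        drug_sim=make_similarity(rng, m),
        target_sim=make_similarity(rng, n),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)


@pytest.fixture
def synth_pair():
    """Occluded synthetic dataset plus its revealed ground truth."""
    from dtilcm import reveal

    sd = generate(SyntheticSpec(hidden_fraction=0.15, seed=11))
    return sd, reveal(sd)
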