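import numpy as np
import pytest

from gaelink.evaluation import five_fold_cv
from gaelink.model import Hyperparams
from gaelink.synthetic import SyntheticSpec, simulate_dataset
from gaelink.types import AssociationMatrix, DiseaseDAG, SimilarityMatrix


@pytest.fixture
def identity_assoc():
    return AssociationMatrix(np.eye(2), ["mA", "mB"], ["dA", "dB"])


@pytest.fixture
def chain_dag():
    """g -> p -> i: disease i with parent p and grandparent g."""
    return DiseaseDAG(
        nodes=["i", "p", "g"],
        parent_edges={("i", "p"), ("p", "g")},
        disease_roots={"D": "i"},
    )


@pytest.fixture
def diamond_dag():
    """i has parents p1 and p2, both children of grandparent g."""
    return DiseaseDAG(
        nodes=["i", "p1", "p2", "g"],
        parent_edges={("i", "p1"), ("i", "p2"), ("p1", "g"), ("p2", "g")},
        disease_roots={"D": "i"},
    )


@pytest.fixture
def sibling_dag():
    """i and j share exactly one parent p."""
    return DiseaseDAG(
        nodes=["i", "j", "p"],
        parent_edges={("i", "p"), ("j", "p")},
        disease_roots={"Di": "i", "Dj": "j"},
    )


@pytest.fixture
def xuan_toy_dag():
    """Three diseases; term p lies in exactly 2 of the 3 ancestor closures."""
    return DiseaseDAG(
        nodes=["a", "b", "c", "p"],
        parent_edges={("a", "p"), ("b", "p")},
        disease_roots={"Da": "a", "Db": "b", "Dc": "c"},
    )


def random_similarity(rng: np.random.Generator, k: int) -> SimilarityMatrix:
    """A random valid similarity matrix (symmetric, unit diagonal, [0, 1])."""
    raw = rng.random((k, k))
    values = 0.5 * (raw + raw.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, [f"x{i}" for i in range(k)])


def random_association(
    rng: np.random.Generator, m: int, n: int, density: float = 0.3
) -> AssociationMatrix:
    values = (rng.random((m, n)) < density).astype(float)
    if values.sum() == 0:
        values[rng.integers(m), rng.integers(n)] = 1.0
    return AssociationMatrix(
        values, [f"m{i}" for i in range(m)], [f"d{j}" for j in range(n)]
    )


BENCHMARK_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def benchmark_cv():
    """Five-fold CV mean AUROC on the planted noisy benchmark for every
    loss mode and seed; shared across the acceptance tests that need it."""
    results: dict[str, dict[int, float]] = {}
    for mode in ("full", "attention_only", "reconstruction_only"):
        results[mode] = {}
        for seed in BENCHMARK_SEEDS:
            spec = SyntheticSpec(
                m=200, n=150, latent_rank=3, density=0.03, noise=0.05, seed=seed
            )
            data = simulate_dataset(spec)
            cv = five_fold_cv(
                data.associations, Hyperparams(seed=seed, loss_mode=mode)
            )
            results[mode][seed] = cv.mean_auroc
    return results
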