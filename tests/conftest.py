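import numpy as np
import pytest

from wmrca import (
    ConsensusMatrix,
    FeatureMatrix,
    LayerSpec,
    SimConfig,
    simulate_multiomics,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix():
    """4 features x 3 samples, complete."""
    vals = np.array([
        [1.0, 2.0, 4.0],
        [0.0, 1.0, 0.0],
        [5.0, 5.0, 5.0],
        [2.0, 8.0, 3.0],
    ])
    return FeatureMatrix(vals, ["G1", "G2", "G3", "G4"], ["S1", "S2", "S3"], "mrna")


def two_blob_matrix(n_per_blob=10, n_features=30, shift=10.0, seed=0):
    """Two Gaussian sample blobs separated by `shift` sd: each blob carries
    its own mean pattern on a distinct feature block, so the blobs are
    separated under both Euclidean and correlation geometry.  Returns
    (FeatureMatrix, true labels array)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_blob
    h = n_features // 3
    X = rng.normal(0, 1, size=(n_features, n))
    X[:h, :n_per_blob] += shift
    X[h:2 * h, n_per_blob:] += shift
    samples = [f"S{i}" for i in range(n)]
    truth = np.array([1] * n_per_blob + [2] * n_per_blob)
    return FeatureMatrix(X, [f"g{i}" for i in range(n_features)], samples, "mrna"), truth


@pytest.fixture
def blob_matrix():
    return two_blob_matrix()


def block_consensus(block_sizes, within=1.0, between=0.0):
    """Block-diagonal consensus matrix with the given perfect-ish blocks."""
    n = sum(block_sizes)
    M = np.full((n, n), between)
    off = 0
    for size in block_sizes:
        M[off:off + size, off:off + size] = within
        off += size
    np.fill_diagonal(M, 1.0)
    return ConsensusMatrix(M=M, K=len(block_sizes), n_reps=1,
                           sample_ids=[f"S{i}" for i in range(n)])


def random_consensus(n, rng, K=2):
    """Random valid consensus matrix (symmetric, unit diagonal, [0,1])."""
    A = rng.random((n, n))
    M = (A + A.T) / 2
    np.fill_diagonal(M, 1.0)
    return ConsensusMatrix(M=M, K=K, n_reps=10, sample_ids=[f"S{i}" for i in range(n)])


@pytest.fixture(scope="session")
def strong_signal_sim():
    """Three layers, 60 samples, two strongly separated subtypes."""
    cfg = SimConfig(
        n_samples=60, k_true=2, seed=7,
        layers=[LayerSpec("mrna", 120), LayerSpec("mirna", 80), LayerSpec("methylation", 100)],
    )
    matrices, truth = simulate_multiomics(cfg)
    return cfg, matrices, truth
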