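import numpy as np
import pytest

from smd_scorecard.data_model import FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pair(rng):
    """A 40-sample, 3-feature reference/synthetic pair with a mild shift."""
    ref = FeatureMatrix(rng.normal(0, 1, (40, 3)))
    syn = FeatureMatrix(rng.normal(0.3, 1.1, (40, 3)))
    return ref, syn


def brute_force_manifold_fraction(query: np.ndarray, centers: np.ndarray,
                                  radii: np.ndarray) -> float:
    """O(n^2) membership oracle: fraction of query points within distance
    radius_j of at least one center j."""
    hits = 0
    for q in query:
        if any(np.linalg.norm(q - c) <= r for c, r in zip(centers, radii)):
            hits += 1
    return hits / len(query)


def brute_force_knn_radii(points: np.ndarray, k: int) -> np.ndarray:
    radii = []
    for i, p in enumerate(points):
        d = sorted(
            np.linalg.norm(p - q) for j, q in enumerate(points) if j != i
        )
        radii.append(d[k - 1])
    return np.asarray(radii)
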