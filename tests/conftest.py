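import numpy as np
import pytest

from discseg.phantom import PhantomParams, generate_sample


@pytest.fixture(scope="session")
def phantom_sample():
    """One deterministic 64x64 phantom shared across tests."""
    return generate_sample(PhantomParams(image_size=64, seed=42))


@pytest.fixture(scope="session")
def phantom_batch():
    """A handful of small phantoms for pipeline tests."""
    return [generate_sample(PhantomParams(image_size=64, seed=s)) for s in range(5)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def bfs_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force BFS labeling oracle (labels in discovery order, unranked)."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                queue = [(r, c)]
                labels[r, c] = current
                while queue:
                    rr, cc = queue.pop()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = current
                            queue.append((nr, nc))
    return labels


def brute_force_distance(source: np.ndarray) -> np.ndarray:
    """O(N*M) exhaustive Euclidean distance oracle."""
    source = np.asarray(source).astype(bool)
    src = np.argwhere(source)
    h, w = source.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            out[r, c] = np.sqrt(((src - (r, c)) ** 2).sum(axis=1)).min()
    return out
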