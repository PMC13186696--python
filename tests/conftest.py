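import numpy as np
import pandas as pd
import pytest

from glycoatlas.core import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_924)


def make_table(
    frames, x_nm, y_nm, photons=None, n_frames=None, label="WGA", pixel_size_nm=130.0
) -> LocalizationTable:
    """Build a LocalizationTable from plain sequences."""
    frames = np.asarray(frames, dtype=np.int64)
    if photons is None:
        photons = np.full(len(frames), 1000.0)
    if n_frames is None:
        n_frames = int(frames.max()) + 1 if len(frames) else 1
    locs = pd.DataFrame(
        {
            "frame": frames,
            "x_nm": np.asarray(x_nm, dtype=float),
            "y_nm": np.asarray(y_nm, dtype=float),
            "photons": photons,
        }
    )
    return LocalizationTable(label, n_frames, locs, pixel_size_nm)


def brute_force_components(xy: np.ndarray, radius: float) -> list[frozenset]:
    """O(n^2) union-find over the full pairwise distance matrix (oracle)."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= radius * radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [frozenset(g) for g in groups.values()]


def partition_of(components) -> set[frozenset]:
    return {frozenset(int(i) for i in c) for c in components}
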