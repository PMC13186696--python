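"""Shared spatial primitives: fixed-radius connected components and NN queries.

Both the localization clusterer and the glycan-class grouper reduce to
connected components of the graph linking points at Euclidean distance
<= radius; a cKDTree pair query plus sparse connected components keeps this
near-linear while matching the brute-force union-find definition exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


def radius_component_labels(xy: np.ndarray, radius: float) -> np.ndarray:
    """Component label per point of the distance-<=radius linkage graph."""
    n = len(xy)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    pairs = cKDTree(xy).query_pairs(radius, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def components_from_labels(labels: np.ndarray) -> list[np.ndarray]:
    """Member-index arrays per component, ordered by smallest member index."""
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    boundaries = np.flatnonzero(np.diff(sorted_labels)) + 1
    comps = np.split(order, boundaries)
    comps.sort(key=lambda idx: idx.min() if len(idx) else -1)
    return comps


def nearest_neighbor_distances(
    source_xy: np.ndarray, target_xy: np.ndarray, exclude_self: bool = False
) -> np.ndarray:
    """First-NN distance from each source point to the target set.

    With ``exclude_self`` the source and target are the same set and each
    point's zero-distance self match is skipped.
    """
    tree = cKDTree(target_xy)
    if exclude_self:
        d, _ = tree.query(source_xy, k=2)
        return d[:, 1]
    d, _ = tree.query(source_xy, k=1)
    return d
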