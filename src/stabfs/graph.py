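"""Sample affinity graphs shared by the spectral unsupervised scorers."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import GraphStructureError, ParameterError

__all__ = ["build_affinity_graph"]


def build_affinity_graph(X: np.ndarray, k_neighbors: int = 5,
                         kernel_width: float | str = "auto") -> np.ndarray:
    """Symmetric kNN affinity matrix with heat-kernel weights.

    Edges connect each sample to its ``k_neighbors`` nearest neighbours under
    Euclidean distance (union symmetrisation, no self-loops) and carry weight
    ``exp(-dist**2 / (2 * sigma**2))``.  ``kernel_width="auto"`` sets ``sigma``
    to the mean kNN distance, which makes the weights invariant to a global
    rescaling of the features.  Coincident points get weight 1 (the zero
    distance limit).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise GraphStructureError("cannot build a graph on an empty table")
    if not 1 <= k_neighbors < n:
        raise ParameterError(f"k_neighbors must be in [1, {n - 1}], got {k_neighbors}")

    dist = squareform(pdist(X))
    order = np.argsort(dist, axis=1, kind="stable")
    # column 0 is the point itself (distance 0, stable sort keeps it first)
    knn = order[:, 1: k_neighbors + 1]

    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_neighbors)
    adj[rows, knn.ravel()] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)

    if kernel_width == "auto":
        sigma = float(dist[rows, knn.ravel()].mean())
    else:
        sigma = float(kernel_width)
        if sigma < 0:
            raise ParameterError("kernel_width must be non-negative")

    W = np.zeros((n, n))
    if sigma == 0.0:
        # all neighbour distances zero: well-defined limit, unit weights
        W[adj] = 1.0
    else:
        W[adj] = np.exp(-dist[adj] ** 2 / (2.0 * sigma**2))
    return W
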