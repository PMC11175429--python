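"""Region graph construction for the disease network.

Regions (si-gun-gu administrative districts) are nodes; edges connect each
region to its k nearest neighbours by great-circle distance between
centroids.  The directed k-NN relation is symmetrised by union so no region
is isolated, and the adjacency is renormalised with self-loops,
``A_norm = D^{-1/2} (A + I) D^{-1/2}``, the form every graph convolution in
this package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


def haversine_distance(lonlat_a, lonlat_b) -> np.ndarray:
    """Great-circle distance in km between points given as (lon, lat) degrees.

    Accepts single points or arrays broadcastable against each other along
    the leading axes; the last axis must hold (lon, lat).
    """
    a = np.asarray(lonlat_a, dtype=float)
    b = np.asarray(lonlat_b, dtype=float)
    for arr in (a, b):
        lat = arr[..., 1]
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90] degrees")
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards against rounding for antipodal / identical points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distances(regions: pd.DataFrame) -> np.ndarray:
    """N x N great-circle distance matrix from a regions table (lon, lat)."""
    pts = regions[["lon", "lat"]].to_numpy(dtype=float)
    return haversine_distance(pts[:, None, :], pts[None, :, :])


@dataclass
class DiseaseNetwork:
    """The static region graph G = (V, E) with its normalised adjacency."""

    region_ids: list
    adjacency: np.ndarray
    k: int
    normalized_adjacency: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.normalized_adjacency = normalize_adjacency(self.adjacency)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def to_edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.adjacency))
        return pd.DataFrame(
            {
                "source": [self.region_ids[a] for a in i],
                "target": [self.region_ids[b] for b in j],
            }
        )


def build_knn_graph(regions: pd.DataFrame, k: int) -> DiseaseNetwork:
    """Union-symmetrised k-nearest-neighbour graph over region centroids.

    An edge (i, j) exists when either region is among the other's ``k``
    nearest; distance ties are broken toward the lower region index so the
    construction is deterministic.
    """
    n = len(regions)
    if n < 2:
        raise ValueError("need at least 2 regions")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= N-1, got k={k}, N={n}")
    dist = pairwise_distances(regions)
    np.fill_diagonal(dist, np.inf)
    adjacency = np.zeros((n, n), dtype=float)
    for i in range(n):
        # stable sort on (distance, index): ties go to the lower index
        order = np.lexsort((np.arange(n), dist[i]))
        neighbors = order[:k]
        adjacency[i, neighbors] = 1.0
    adjacency = np.maximum(adjacency, adjacency.T)  # union symmetrisation
    np.fill_diagonal(adjacency, 0.0)
    region_ids = list(regions["region_id"]) if "region_id" in regions else list(range(n))
    return DiseaseNetwork(region_ids=region_ids, adjacency=adjacency, k=k)


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Self-loop symmetric normalisation D^{-1/2} (A + I) D^{-1/2}.

    All eigenvalues of the result lie in [-1, 1], which keeps stacked graph
    convolutions numerically stable.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    a_tilde = a + np.eye(a.shape[0])
    deg = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
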