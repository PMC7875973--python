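"""Distances on the grayordinate axis.

Cortical distances are great-circle distances on the synthetic sphere
(the synthetic geometry places all cortical vertices on a sphere of
known radius, where the great-circle metric is the exact geodesic).
For real surface meshes, shortest-path distance along mesh edges is
provided as the geodesic approximation.  Subcortical voxels use the
Euclidean metric.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .core import Geometry, UsageError

__all__ = [
    "great_circle_distances",
    "cortical_distance_matrix",
    "mesh_geodesic_distances",
    "exclusion_mask",
]


def great_circle_distances(coords: np.ndarray, radius: float | None = None) -> np.ndarray:
    """Pairwise great-circle distances between points on a sphere.

    Parameters
    ----------
    coords :
        ``(n, 3)`` positions assumed to lie on a common sphere centred
        at the origin.
    radius :
        Sphere radius; inferred from the mean point norm when omitted.
    """
    coords = np.asarray(coords, dtype=float)
    norms = np.linalg.norm(coords, axis=1)
    if radius is None:
        radius = float(norms.mean())
    unit = coords / norms[:, None]
    cosang = np.clip(unit @ unit.T, -1.0, 1.0)
    d = radius * np.arccos(cosang)
    np.fill_diagonal(d, 0.0)
    return d


def cortical_distance_matrix(geometry: Geometry) -> np.ndarray:
    """Great-circle distance matrix between all cortical vertices (mm)."""
    coords = geometry.require_coordinates()[geometry.cortex_index]
    return great_circle_distances(coords)


def mesh_geodesic_distances(
    coords: np.ndarray, edges: np.ndarray, sources: np.ndarray | None = None
) -> np.ndarray:
    """Shortest-path distances along mesh edges (Dijkstra).

    This is the geodesic approximation used for real triangulated
    surfaces, where the exact polyhedral geodesic is not worth its
    cost.  ``edges`` is an ``(m, 2)`` integer array of undirected mesh
    edges; edge weights are Euclidean lengths.
    """
    coords = np.asarray(coords, dtype=float)
    edges = np.asarray(edges, dtype=np.intp)
    if edges.ndim != 2 or edges.shape[1] != 2:
        raise UsageError("edges must have shape (m, 2)")
    n = coords.shape[0]
    w = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    graph = sp.coo_matrix(
        (np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    ).tocsr()
    indices = None if sources is None else np.asarray(sources, dtype=np.intp)
    return dijkstra(graph, directed=False, indices=indices)


def exclusion_mask(
    geometry: Geometry,
    region_indices: np.ndarray,
    radius_mm: float,
    cortical_distances: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of grayordinates excluded around one region.

    The exclusion set is the region itself plus every grayordinate
    within ``radius_mm`` of any *cortical* vertex of the region:
    cortex-to-cortex neighbourhoods use the great-circle metric,
    subcortex-to-cortex neighbourhoods the Euclidean metric.

    Parameters
    ----------
    geometry :
        Geometry with coordinates.
    region_indices :
        Grayordinate indices of the region.
    radius_mm :
        Neighbourhood radius in millimetres.
    cortical_distances :
        Optional precomputed ``(n_cortex, n_cortex)`` great-circle
        matrix (saves recomputation when looping over regions).

    Returns
    -------
    numpy.ndarray
        Boolean array of length ``n_total``; ``True`` marks excluded
        grayordinates.
    """
    region_indices = np.asarray(region_indices, dtype=np.intp)
    mask = np.zeros(geometry.n_total, dtype=bool)
    mask[region_indices] = True

    # cortical vertices of the region, as positions within cortex_index
    pos_of = np.full(geometry.n_total, -1, dtype=np.intp)
    pos_of[geometry.cortex_index] = np.arange(geometry.n_cortex)
    region_ctx_pos = pos_of[region_indices]
    region_ctx_pos = region_ctx_pos[region_ctx_pos >= 0]
    if region_ctx_pos.size == 0:
        return mask

    coords = geometry.require_coordinates()
    if cortical_distances is None:
        cortical_distances = cortical_distance_matrix(geometry)
    near_ctx = (cortical_distances[region_ctx_pos] <= radius_mm).any(axis=0)
    mask[geometry.cortex_index[near_ctx]] = True

    sub_idx = geometry.subcortex_index
    if sub_idx.size:
        ctx_coords = coords[geometry.cortex_index[region_ctx_pos]]
        d = np.linalg.norm(coords[sub_idx][:, None, :] - ctx_coords[None, :, :], axis=2)
        mask[sub_idx[(d <= radius_mm).any(axis=1)]] = True
    return mask
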