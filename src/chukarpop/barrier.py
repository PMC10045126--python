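"""Monmonier maximum-difference barrier detection.

Populations are nodes of a Delaunay triangulation of their sampling
coordinates; each Delaunay edge carries the genetic distance between
its two populations.  A barrier is traced across the Voronoi dual:
starting from the edge with the largest genetic distance, it extends
through adjacent triangles, always crossing the remaining edge of
largest distance, until it exits at the convex hull or would
self-intersect.  Barrier robustness is scored by re-tracing on
bootstrap distance matrices and reporting, for each edge of the
point-estimate barrier, the percentage of matrices whose barrier
crosses it.

Coordinates are treated as planar after an equirectangular projection
about the centroid (adequate at the spatial extent of a single
country; it also makes edge sets reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from sklearn.base import BaseEstimator

from .io_formats import PopulationMap

__all__ = [
    "Triangulation",
    "BarrierResult",
    "delaunay_graph",
    "trace_barrier",
    "barrier_support",
    "MonmonierBarrier",
]


@dataclass
class Triangulation:
    """Planar Delaunay triangulation of population coordinates."""

    ids: list[str]
    points: np.ndarray          # (k, 2) projected coordinates
    simplices: np.ndarray       # (t, 3) vertex indices
    edges: list[tuple[int, int]]
    edge_tris: dict[tuple[int, int], list[int]] = field(default_factory=dict)

    def edge_on_hull(self, e: tuple[int, int]) -> bool:
        return len(self.edge_tris[e]) == 1


@dataclass
class BarrierResult:
    """Barriers as ordered lists of crossed Delaunay edges (pairs of
    population ids) plus optional bootstrap support per edge."""

    barriers: list[list[tuple[str, str]]]
    support: list[dict[tuple[str, str], float]] | None = None


def _project(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Equirectangular projection about the centroid (degrees -> km-ish)."""
    lat0 = float(np.mean(lat))
    x = (lon - np.mean(lon)) * np.cos(np.radians(lat0)) * 111.32
    y = (lat - np.mean(lat)) * 111.32
    return np.column_stack([x, y])


def delaunay_graph(popmap: PopulationMap, jitter_seed: int = 0) -> Triangulation:
    """Delaunay triangulation of the populations.

    Collinear or duplicate points are jittered by 1e-6 degrees
    (repeatedly, with increasing magnitude) until the triangulation is
    valid.
    """
    if len(popmap) < 3:
        raise ValueError("need >= 3 populations")
    lon, lat = popmap.lon.copy(), popmap.lat.copy()
    rng = np.random.default_rng(jitter_seed)
    eps = 1e-6
    for attempt in range(8):
        pts = _project(lon, lat)
        try:
            tri = Delaunay(pts)
            if tri.simplices.shape[0] > 0:
                break
        except Exception:
            pass
        lon = popmap.lon + rng.normal(0, eps, len(popmap))
        lat = popmap.lat + rng.normal(0, eps, len(popmap))
        eps *= 10
    else:
        raise ValueError("could not triangulate population coordinates")
    edge_tris: dict[tuple[int, int], list[int]] = {}
    for t, simplex in enumerate(tri.simplices):
        for a, b in ((0, 1), (1, 2), (0, 2)):
            e = tuple(sorted((int(simplex[a]), int(simplex[b]))))
            edge_tris.setdefault(e, []).append(t)
    return Triangulation(
        list(popmap.ids), pts, tri.simplices, sorted(edge_tris), edge_tris
    )


def _tri_edges(tri: Triangulation, t: int) -> list[tuple[int, int]]:
    s = tri.simplices[t]
    return [tuple(sorted((int(s[a]), int(s[b])))) for a, b in ((0, 1), (1, 2), (0, 2))]


def _trace_one(
    tri: Triangulation,
    dist: np.ndarray,
    banned: set[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Trace a single barrier; ``banned`` edges cannot be crossed."""
    candidates = [e for e in tri.edges if e not in banned]
    if not candidates:
        return []
    # seed edge: maximal distance, ties broken by lowest id pair
    start = min(candidates, key=lambda e: (-dist[e[0], e[1]], e))
    path = [start]
    crossed = {start}
    visited_tris: set[int] = set()
    # grow from both adjacent triangles of the seed edge
    ends = list(tri.edge_tris[start])
    for t0 in ends:
        t = t0
        entry = start
        while True:
            if t in visited_tris:
                break  # would self-intersect
            visited_tris.add(t)
            options = [
                e for e in _tri_edges(tri, t)
                if e != entry and e not in crossed and e not in banned
            ]
            if not options:
                break
            nxt = min(options, key=lambda e: (-dist[e[0], e[1]], e))
            crossed.add(nxt)
            if t0 == tri.edge_tris[start][0]:
                path.append(nxt)
            else:
                path.insert(0, nxt)
            if tri.edge_on_hull(nxt):
                break  # reached the study-area boundary
            nxt_tris = [x for x in tri.edge_tris[nxt] if x != t]
            if not nxt_tris:
                break
            t, entry = nxt_tris[0], nxt
    return path


def trace_barrier(
    tri: Triangulation,
    dist_matrix: np.ndarray,
    n_barriers: int = 1,
) -> BarrierResult:
    """Monmonier barrier(s) on a triangulation.

    ``dist_matrix`` must be symmetric and finite on triangulation
    edges, indexed like ``tri.ids``.  Successive barriers are
    edge-disjoint (already-crossed edges are excluded).
    """
    D = np.asarray(dist_matrix, float)
    k = len(tri.ids)
    if D.shape != (k, k):
        raise ValueError("distance matrix must match the population count")
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    for a, b in tri.edges:
        if not np.isfinite(D[a, b]):
            raise ValueError("non-finite distance on a triangulation edge")
    banned: set[tuple[int, int]] = set()
    barriers = []
    for _ in range(n_barriers):
        path = _trace_one(tri, D, banned)
        if not path:
            break
        banned.update(path)
        barriers.append([(tri.ids[a], tri.ids[b]) for a, b in path])
    return BarrierResult(barriers)


def barrier_support(
    popmap: PopulationMap,
    matrices: list[np.ndarray],
    point_estimate: np.ndarray | None = None,
    n_barriers: int = 1,
) -> BarrierResult:
    """Bootstrap support for barrier edges.

    The point-estimate barrier is traced from ``point_estimate`` (or
    the element-wise mean of ``matrices``); support for each of its
    edges is the percentage of bootstrap matrices whose barrier
    crosses that edge.
    """
    if len(matrices) < 2:
        raise ValueError("need >= 2 bootstrap matrices")
    tri = delaunay_graph(popmap)
    if point_estimate is None:
        point_estimate = np.mean(np.stack(matrices), axis=0)
    point = trace_barrier(tri, point_estimate, n_barriers)
    counts = [dict.fromkeys(b, 0) for b in point.barriers]
    for M in matrices:
        boot = trace_barrier(tri, M, n_barriers)
        crossed = {e for b in boot.barriers for e in b}
        for cb in counts:
            for e in cb:
                if e in crossed:
                    cb[e] += 1
    support = [
        {e: 100.0 * c / len(matrices) for e, c in cb.items()} for cb in counts
    ]
    return BarrierResult(point.barriers, support)


class MonmonierBarrier(BaseEstimator):
    """Estimator interface: fit(popmap, dist_matrix) stores the
    triangulation and traced barriers in ``triangulation_`` and
    ``barriers_``; ``support_`` is filled by :meth:`bootstrap`."""

    def __init__(self, n_barriers: int = 1):
        self.n_barriers = n_barriers

    def fit(self, popmap: PopulationMap, dist_matrix: np.ndarray) -> "MonmonierBarrier":
        self.triangulation_ = delaunay_graph(popmap)
        result = trace_barrier(self.triangulation_, dist_matrix, self.n_barriers)
        self.barriers_ = result.barriers
        self.popmap_ = popmap
        self.dist_matrix_ = np.asarray(dist_matrix, float)
        return self

    def bootstrap(self, matrices: list[np.ndarray]) -> BarrierResult:
        result = barrier_support(
            self.popmap_, matrices, self.dist_matrix_, self.n_barriers
        )
        self.support_ = result.support
        return result
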