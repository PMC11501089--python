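"""Core domain containers: surface time series, geometry, searchlights, masks.

Matrix orientation is time x vertex everywhere in this package: rows are
samples (TRs), columns are cortical vertices.  All model stages assume the
input time series have been cleaned upstream (motion/nuisance regression is
out of scope) and z-score each vertex to zero mean, unit variance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class SubjectTimeseries:
    """One participant's time x vertex response matrix.

    Attributes
    ----------
    subject_id : str
        Participant identifier.
    data : ndarray of shape (t_time, v_vertex)
        Response amplitudes (unitless after z-scoring).
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    run_boundaries : list of int
        Time indices at which acquisition runs start.  Strictly increasing,
        first entry 0, all < t_time.
    zero_variance : ndarray of bool, optional
        Per-vertex flag set by :func:`normalize_timeseries` for vertices with
        no temporal variance (e.g. medial wall); those columns are all-zero.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 1.0
    run_boundaries: list[int] = field(default_factory=lambda: [0])
    zero_variance: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("data must be a 2-D time x vertex matrix")
        if self.tr_seconds <= 0:
            raise InvalidInputError("tr_seconds must be positive")
        rb = list(self.run_boundaries)
        if not rb or rb[0] != 0:
            raise InvalidInputError("run_boundaries must start at 0")
        if any(b >= self.n_timepoints for b in rb):
            raise InvalidInputError("run boundaries must be < t_time")
        if any(b2 <= b1 for b1, b2 in zip(rb, rb[1:])):
            raise InvalidInputError("run boundaries must be strictly increasing")
        self.run_boundaries = rb

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    def replace(self, **kw) -> "SubjectTimeseries":
        return dataclasses.replace(self, **kw)


@dataclass
class SurfaceGeometry:
    """Vertex positions of a cortical surface patch.

    ``distance_mode`` selects euclidean distances on the 3-D coordinates
    (default, well defined without mesh topology) or geodesic distances along
    mesh edges, which requires ``edges``.
    """

    coordinates: np.ndarray  # (v, 3), mm
    distance_mode: str = "euclidean"
    edges: np.ndarray | None = None  # (n_edges, 2) vertex index pairs

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise InvalidInputError("coordinates must be (v, 3)")
        if self.coordinates.shape[0] < 1:
            raise InvalidInputError("geometry must contain at least one vertex")
        if not np.all(np.isfinite(self.coordinates)):
            raise InvalidInputError("coordinates must be finite")
        if self.distance_mode not in ("euclidean", "geodesic"):
            raise InvalidInputError(f"unknown distance_mode {self.distance_mode!r}")
        if self.distance_mode == "geodesic" and self.edges is None:
            raise InvalidInputError("geodesic distances require mesh edges")

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Searchlight:
    """All vertices within ``radius`` mm of a center vertex."""

    center_vertex: int
    members: np.ndarray  # vertex indices, unique
    distances: np.ndarray  # center-to-member distance, mm
    radius: float

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.members.size != np.unique(self.members).size:
            raise InvalidInputError("searchlight members must be unique")
        if self.center_vertex not in self.members:
            raise InvalidInputError("center must be a member of its searchlight")
        if np.any(self.distances > self.radius + 1e-9):
            raise InvalidInputError("member distance exceeds searchlight radius")

    @property
    def size(self) -> int:
        return self.members.size


@dataclass
class RegionMask:
    """A named set of vertex indices (e.g. early visual cortex)."""

    name: str
    members: np.ndarray

    def __post_init__(self):
        self.members = np.unique(np.asarray(self.members, dtype=int))
        if self.members.size and self.members.min() < 0:
            raise InvalidInputError("mask indices must be non-negative")


def normalize_timeseries(ts: SubjectTimeseries) -> SubjectTimeseries:
    """Z-score each vertex column to zero mean and unit (population) variance.

    Zero-variance columns are set to all-zeros and flagged in
    ``zero_variance`` rather than raising: medial-wall and masked vertices
    with constant signal are common in surface data.  Idempotent within 1e-9.
    """
    if ts.n_timepoints < 2:
        raise InvalidInputError("need at least 2 time points to z-score")
    data = ts.data
    mean = data.mean(axis=0)
    sd = data.std(axis=0)  # population SD (ddof=0)
    flat = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    safe_sd = np.where(flat, 1.0, sd)
    out = (data - mean) / safe_sd
    out[:, flat] = 0.0
    return ts.replace(data=out, zero_variance=flat)


def vertex_distances(geom: SurfaceGeometry, max_radius: float) -> csr_matrix:
    """Sparse pairwise vertex distances up to ``max_radius`` mm.

    Euclidean mode uses a KD-tree; geodesic mode runs Dijkstra on the
    edge-weighted mesh graph.  The diagonal (distance 0) is implicit.
    """
    coords = geom.coordinates
    if geom.distance_mode == "euclidean":
        tree = cKDTree(coords)
        return tree.sparse_distance_matrix(tree, max_radius, output_type="coo_matrix").tocsr()
    # geodesic: shortest path along mesh edges
    e = np.asarray(geom.edges, dtype=int)
    w = np.linalg.norm(coords[e[:, 0]] - coords[e[:, 1]], axis=1)
    v = geom.n_vertices
    graph = csr_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), shape=(v, v))
    dist = dijkstra(graph, directed=False, limit=max_radius)
    dist[~np.isfinite(dist)] = -1.0
    keep = dist >= 0
    rows, cols = np.nonzero(keep)
    return csr_matrix((dist[rows, cols], (rows, cols)), shape=(v, v))


def build_searchlights(geom: SurfaceGeometry, radius_mm: float) -> list[Searchlight]:
    """One searchlight per vertex: all vertices within ``radius_mm``.

    Every vertex is a member of its own searchlight (distance 0).  Under
    euclidean distances membership is symmetric: a in SL(b) iff b in SL(a).
    """
    if radius_mm <= 0:
        raise InvalidInputError("radius must be positive")
    if geom.n_vertices < 1:
        raise InvalidInputError("empty geometry")
    dist = vertex_distances(geom, radius_mm).tolil()
    out = []
    for center in range(geom.n_vertices):
        members = np.asarray(dist.rows[center], dtype=int)
        dists = np.asarray(dist.data[center], dtype=float)
        if center not in members:
            members = np.append(members, center)
            dists = np.append(dists, 0.0)
        order = np.argsort(members)
        out.append(Searchlight(center, members[order], dists[order], radius_mm))
    return out


def aggregation_weight(d_mm, r_mm: float):
    """Distance-based aggregation weight (r - d) / r.

    Linear and decreasing in d: 1 when the vertex is the searchlight center,
    0 at the searchlight boundary.  Accepts scalars or arrays of distances.
    """
    d = np.asarray(d_mm, dtype=float)
    if r_mm <= 0:
        raise InvalidInputError("radius must be positive")
    if np.any(d < 0) or np.any(d > r_mm + 1e-12):
        raise InvalidInputError("distances must satisfy 0 <= d <= r")
    w = (r_mm - d) / r_mm
    return float(w) if np.isscalar(d_mm) else w


def grid_geometry(n_x: int, n_y: int, spacing_mm: float = 3.0,
                  distance_mode: str = "euclidean") -> SurfaceGeometry:
    """Regular n_x x n_y grid in the z=0 plane, with 4-neighbor mesh edges."""
    xs, ys = np.meshgrid(np.arange(n_x), np.arange(n_y), indexing="ij")
    coords = np.column_stack([xs.ravel() * spacing_mm, ys.ravel() * spacing_mm,
                              np.zeros(n_x * n_y)])
    idx = np.arange(n_x * n_y).reshape(n_x, n_y)
    edges = np.concatenate([
        np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()]),
        np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()]),
    ])
    return SurfaceGeometry(coords, distance_mode=distance_mode, edges=edges)


def sphere_geometry(n_vertices: int, radius_mm: float = 100.0,
                    distance_mode: str = "euclidean") -> SurfaceGeometry:
    """Quasi-uniform Fibonacci lattice on a sphere (no mesh edges)."""
    i = np.arange(n_vertices)
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n_vertices
    r = np.sqrt(np.maximum(0.0, 1 - z ** 2))
    coords = radius_mm * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return SurfaceGeometry(coords, distance_mode=distance_mode)
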