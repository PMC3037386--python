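"""Unstructured triangular meshing of boundary shapes.

The mesher is intentionally simple and fully deterministic: the outline is
resampled at the target edge length (preserving sharp corners such as the
body-flank rectangle), the interior is filled with a hexagonal point lattice
kept clear of the boundary, the point set is Delaunay-triangulated and
triangles whose centroid falls outside the polygon are discarded.  A few
Laplacian smoothing passes on the interior points raise the worst angles.
The contract is the TriMesh invariant set (positive CCW triangles, area
partition, disc topology), not any particular generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .errors import GeometryError, MeshError, ConsistencyError, ParameterError
from .trajectory import BoundaryShape, Stage, shoelace_area

__all__ = [
    "TriMesh",
    "REFERENCE_EDGE_LENGTH",
    "triangulate",
    "triangulate_ring",
    "classify_boundary",
    "edge_neighbors",
    "EdgeNeighbors",
    "write_off",
    "read_off",
    "write_vtk",
    "read_vtk",
]

#: documented reference resolution: the edge length at which the standard
#: synthetic E9 frame discretizes into ~3.2k triangles, the mesh size used
#: by full-scale map evaluations at the youngest stage
REFERENCE_EDGE_LENGTH = 0.042


@dataclass
class TriMesh:
    """Triangular discretization of one boundary shape.

    points: (n, 2) vertex coordinates.  The first ``n_boundary`` points are
        the boundary vertices in counter-clockwise ring order.
    triangles: (m, 3) vertex indices, counter-clockwise.
    """

    points: np.ndarray
    triangles: np.ndarray
    n_boundary: int
    stage: Stage | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)

    # -- derived quantities (cached) --------------------------------------- #

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def areas(self) -> np.ndarray:
        """Signed triangle areas (positive for CCW triangles)."""
        if "areas" not in self._cache:
            self._cache["areas"] = triangle_areas(self.points, self.triangles)
        return self._cache["areas"]

    @property
    def centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.points[self.triangles].mean(axis=1)
        return self._cache["centroids"]

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted (i, j) index pairs."""
        if "edges" not in self._cache:
            e = np.vstack([
                self.triangles[:, [0, 1]],
                self.triangles[:, [1, 2]],
                self.triangles[:, [2, 0]],
            ])
            e.sort(axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    @property
    def boundary_nodes(self) -> np.ndarray:
        return np.arange(self.n_boundary)

    @property
    def boundary_ring(self) -> np.ndarray:
        """Boundary vertex coordinates in CCW ring order."""
        return self.points[: self.n_boundary]

    @property
    def flank_nodes(self) -> np.ndarray:
        if "flank" not in self._cache:
            bx = self.boundary_ring[:, 0]
            xmin = bx.min()
            scale = max(1.0, float(np.abs(self.points).max()))
            self._cache["flank"] = np.flatnonzero(bx <= xmin + 1e-7 * scale)
        return self._cache["flank"]

    @property
    def interior_nodes(self) -> np.ndarray:
        return np.arange(self.n_boundary, self.n_points)

    def boundary_polygon(self) -> Polygon:
        return Polygon(self.boundary_ring)

    def with_points(self, points: np.ndarray) -> "TriMesh":
        """Copy of the mesh with moved vertices (same connectivity)."""
        return TriMesh(points=np.asarray(points, float), triangles=self.triangles,
                       n_boundary=self.n_boundary, stage=self.stage)

    # -- validation -------------------------------------------------------- #

    def validate(self, rel_tol: float = 1e-6) -> None:
        a = self.areas
        if np.any(a <= 0):
            raise MeshError("mesh contains non-positive (inverted) triangles")
        poly_area = abs(shoelace_area(self.boundary_ring))
        if abs(a.sum() - poly_area) > rel_tol * poly_area:
            raise MeshError(
                f"triangle areas ({a.sum():.9g}) do not partition the boundary "
                f"polygon area ({poly_area:.9g})")
        # single connected component over the edge graph
        e = self.edges
        n = self.n_points
        g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        ncomp, _ = connected_components(g, directed=False)
        if ncomp != 1:
            raise MeshError(f"mesh has {ncomp} connected components")
        # disc topology: V - E + F = 1
        if n - len(e) + self.n_triangles != 1:
            raise MeshError("mesh does not have disc topology (V - E + F != 1)")


def triangle_areas(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = points[triangles]
    return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                  - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))


def min_angle_deg(points: np.ndarray, triangles: np.ndarray) -> float:
    """Smallest interior angle over all triangles, in degrees."""
    p = points[triangles]
    angles = []
    for k in range(3):
        a = p[:, (k + 1) % 3] - p[:, k]
        b = p[:, (k + 2) % 3] - p[:, k]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return float(np.min(angles))


# --------------------------------------------------------------------------- #
# boundary resampling that keeps sharp corners
# --------------------------------------------------------------------------- #


def _resample_ring(ring: np.ndarray, h: float, corner_deg: float = 25.0) -> np.ndarray:
    """Resample a closed ring to ~h spacing, pinning high-turn-angle vertices."""
    n = len(ring)
    prev = ring - np.roll(ring, 1, axis=0)
    nxt = np.roll(ring, -1, axis=0) - ring
    ang_in = np.arctan2(prev[:, 1], prev[:, 0])
    ang_out = np.arctan2(nxt[:, 1], nxt[:, 0])
    turn = np.degrees(np.abs(np.angle(np.exp(1j * (ang_out - ang_in)))))
    corners = np.flatnonzero(turn > corner_deg)
    if len(corners) == 0:
        corners = np.array([0])
    pieces = []
    for k in range(len(corners)):
        i0, i1 = corners[k], corners[(k + 1) % len(corners)]
        idx = np.arange(i0, i1 + 1) if i1 > i0 else np.concatenate(
            [np.arange(i0, n), np.arange(0, i1 + 1)])
        arc = ring[idx % n]
        seg = np.hypot(*np.diff(arc, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        m = max(1, int(round(total / h)))
        t = np.linspace(0, total, m + 1)[:-1]  # drop arc end: next piece starts there
        pieces.append(np.column_stack([np.interp(t, s, arc[:, 0]),
                                       np.interp(t, s, arc[:, 1])]))
    return np.vstack(pieces)


# --------------------------------------------------------------------------- #
# triangulation
# --------------------------------------------------------------------------- #


def triangulate(shape: BoundaryShape, target_edge_length: float,
                smooth_iters: int = 4, min_angle: float = 15.0) -> TriMesh:
    """Mesh the polygon of ``shape`` with triangles of ~target edge length.

    Raises MeshError if the resulting mesh violates the quality floor
    ``min_angle`` (degrees) or any TriMesh invariant.
    """
    shape.validate()
    pts = shape.outline
    diam = float(np.ptp(pts[:, 0]) + np.ptp(pts[:, 1]))
    h = float(target_edge_length)
    if not (0 < h < diam):
        raise ParameterError(f"target_edge_length must be in (0, {diam:.3g})")
    boundary = _resample_ring(pts, h)
    return _mesh_inside_ring(boundary, h, smooth_iters, min_angle, shape.stage)


def _split_long_segments(ring: np.ndarray, h: float) -> np.ndarray:
    """Insert collinear points so no ring segment exceeds ~1.5 h.

    The ring is unchanged as a geometric curve, which is what lets two meshes
    share an identical boundary polygon."""
    out = []
    n = len(ring)
    for i in range(n):
        a, b = ring[i], ring[(i + 1) % n]
        out.append(a)
        seg = float(np.hypot(*(b - a)))
        parts = int(np.ceil(seg / (1.5 * h)))
        if parts > 1:
            # nudge the collinear insertions a hair toward the interior
            # (left of the CCW direction) so the Delaunay step cannot emit
            # exactly degenerate boundary slivers; the area perturbation is
            # O(1e-8 h^2), far below the conservation tolerance
            normal = np.array([-(b - a)[1], (b - a)[0]]) / seg
            for k in range(1, parts):
                out.append(a + (b - a) * (k / parts) + 1e-8 * h * normal)
    return np.asarray(out)


def triangulate_ring(ring: np.ndarray, target_edge_length: float,
                     smooth_iters: int = 4, min_angle: float = 15.0,
                     stage: Stage | None = None) -> TriMesh:
    """Mesh the polygon whose boundary vertices are exactly ``ring``.

    Long boundary segments are split by collinear insertions (the polygon is
    geometrically unchanged), the interior is filled afresh.  Used to mesh
    frame t+1 on the deformed boundary of frame t so that consecutive meshes
    share an identical boundary polygon and the interpolation map partitions
    exactly."""
    h = float(target_edge_length)
    boundary = _split_long_segments(np.asarray(ring, dtype=float), h)
    return _mesh_inside_ring(boundary, h, smooth_iters, min_angle, stage)


def _mesh_inside_ring(boundary: np.ndarray, h: float, smooth_iters: int,
                      min_angle: float, stage: Stage | None) -> TriMesh:
    poly = Polygon(boundary)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("mesh boundary ring is degenerate")

    # hexagonal interior lattice, kept >= 0.7 h away from the boundary
    xmin, ymin, xmax, ymax = poly.bounds
    dy = h * np.sqrt(3) / 2
    rows = np.arange(ymin - h, ymax + h, dy)
    grid = []
    for r, y in enumerate(rows):
        xs = np.arange(xmin - h, xmax + h, h) + (h / 2 if r % 2 else 0.0)
        grid.append(np.column_stack([xs, np.full(len(xs), y)]))
    grid = np.vstack(grid)
    inner = poly.buffer(-0.7 * h)
    if inner.is_empty:
        interior = np.empty((0, 2))
    else:
        keep = shapely.contains_xy(inner, grid[:, 0], grid[:, 1])
        interior = grid[keep]

    points = np.vstack([boundary, interior])
    nb = len(boundary)

    def _delaunay(points):
        tri = Delaunay(points)
        simplices = tri.simplices
        cent = points[simplices].mean(axis=1)
        keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        return simplices[keep]

    simplices = _delaunay(points)
    # Laplacian smoothing of interior points (boundary stays put)
    for _ in range(smooth_iters):
        if len(interior) == 0:
            break
        e = np.vstack([simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        n = len(points)
        w = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        w = w + w.T
        deg = np.asarray(w.sum(axis=1)).ravel()
        avg = w.dot(points) / deg[:, None]
        points = points.copy()
        points[nb:] = avg[nb:]
        simplices = _delaunay(points)

    # orient CCW
    a = triangle_areas(points, simplices)
    flip = a < 0
    simplices[flip] = simplices[flip][:, ::-1]
    if np.any(triangle_areas(points, simplices) <= 0):
        raise MeshError("triangulation produced degenerate triangles")

    mesh = TriMesh(points=points, triangles=simplices, n_boundary=nb, stage=stage)
    mesh.validate()
    worst = min_angle_deg(points, simplices)
    if worst < min_angle:
        raise MeshError(
            f"mesh quality below floor: min angle {worst:.2f} deg < {min_angle} deg")
    return mesh


def classify_boundary(mesh: TriMesh, shape: BoundaryShape | None = None):
    """Partition node indices into (boundary, flank, interior) from topology.

    Boundary nodes are endpoints of edges incident to exactly one triangle;
    flank nodes are boundary nodes on the minimal-x edge.  If ``shape`` is
    given, the boundary nodes are checked to lie on its outline.
    """
    en = edge_neighbors(mesh)
    b_edges = en.boundary_edges
    boundary = np.unique(b_edges)
    expected = set(range(mesh.n_boundary))
    if set(boundary.tolist()) != expected:
        raise ConsistencyError("topological boundary does not match stored ring")
    if shape is not None:
        from shapely.geometry import LineString
        ring = LineString(np.vstack([shape.outline, shape.outline[:1]]))
        scale = max(1.0, float(np.abs(shape.outline).max()))
        for i in boundary:
            if ring.distance(shapely.points(mesh.points[i])) > 1e-6 * scale:
                raise ConsistencyError(f"boundary node {i} is not on the outline")
    flank = mesh.flank_nodes
    interior = np.setdiff1d(np.arange(mesh.n_points), boundary)
    return boundary, flank, interior


@dataclass
class EdgeNeighbors:
    """Triangle adjacency across shared edges (for the finite-volume solver).

    tri_a, tri_b: triangle index pairs sharing an interior edge.
    edge_length: length of the shared edge.
    centroid_distance: distance between the two triangle centroids.
    boundary_edges: (k, 2) vertex pairs of edges with a single triangle.
    """

    tri_a: np.ndarray
    tri_b: np.ndarray
    edge_length: np.ndarray
    centroid_distance: np.ndarray
    boundary_edges: np.ndarray


def edge_neighbors(mesh: TriMesh) -> EdgeNeighbors:
    tris = mesh.triangles
    m = len(tris)
    e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    owner = np.tile(np.arange(m), 3)
    e_sorted = np.sort(e, axis=1)
    order = np.lexsort((e_sorted[:, 1], e_sorted[:, 0]))
    e_sorted, owner = e_sorted[order], owner[order]
    uniq, start, counts = np.unique(e_sorted, axis=0, return_index=True, return_counts=True)
    if np.any(counts > 2):
        raise MeshError("non-manifold edge shared by more than two triangles")
    inter = counts == 2
    ta = owner[start[inter]]
    tb = owner[start[inter] + 1]
    edge_pts = mesh.points[uniq[inter]]
    elen = np.hypot(*(edge_pts[:, 0] - edge_pts[:, 1]).T)
    cent = mesh.centroids
    cdist = np.hypot(*(cent[ta] - cent[tb]).T)
    return EdgeNeighbors(
        tri_a=ta, tri_b=tb, edge_length=elen, centroid_distance=cdist,
        boundary_edges=uniq[~inter],
    )


# --------------------------------------------------------------------------- #
# ASCII mesh IO (OFF and legacy VTK)
# --------------------------------------------------------------------------- #


def write_off(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_points} {mesh.n_triangles} 0\n")
        fh.write(f"# n_boundary {mesh.n_boundary}\n")
        for x, y in mesh.points:
            fh.write(f"{float(x)!r} {float(y)!r} 0.0\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_off(path) -> TriMesh:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines[0] != "OFF":
        raise ConsistencyError("not an OFF file")
    nv, nf, _ = (int(v) for v in lines[1].split())
    nb = nv
    k = 2
    if lines[k].startswith("#"):
        parts = lines[k].split()
        if len(parts) >= 3 and parts[1] == "n_boundary":
            nb = int(parts[2])
        k += 1
    pts = np.array([[float(v) for v in lines[k + i].split()[:2]] for i in range(nv)])
    tris = np.array([[int(v) for v in lines[k + nv + i].split()[1:4]] for i in range(nf)])
    return TriMesh(points=pts, triangles=tris, n_boundary=nb)


def write_vtk(mesh: TriMesh, path, cell_data: dict | None = None) -> None:
    """Legacy-VTK ASCII UNSTRUCTURED_GRID writer with optional per-cell scalars."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmorphomovie mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_points} double\n")
        for x, y in mesh.points:
            fh.write(f"{float(x)!r} {float(y)!r} 0.0\n")
        fh.write(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {mesh.n_triangles}\n")
        fh.write("\n".join(["5"] * mesh.n_triangles) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {mesh.n_triangles}\n")
            for name, values in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(repr(float(v)) for v in values) + "\n")


def read_vtk(path) -> tuple[TriMesh, dict]:
    with open(path) as fh:
        tokens = fh.read().split()
    def _find(word):
        return tokens.index(word)
    i = _find("POINTS")
    nv = int(tokens[i + 1])
    pts = np.array(tokens[i + 3: i + 3 + 3 * nv], dtype=float).reshape(nv, 3)[:, :2]
    i = _find("CELLS")
    nf = int(tokens[i + 1])
    raw = np.array(tokens[i + 3: i + 3 + 4 * nf], dtype=int).reshape(nf, 4)
    tris = raw[:, 1:]
    cell_data = {}
    j = 0
    while "SCALARS" in tokens[j:]:
        j = tokens.index("SCALARS", j)
        name = tokens[j + 1]
        k = tokens.index("default", j) + 1
        cell_data[name] = np.array(tokens[k: k + nf], dtype=float)
        j = k + nf
    return TriMesh(points=pts, triangles=tris, n_boundary=nv), cell_data
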