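"""Conservative triangle-interpolation maps between consecutive meshes.

After the mesh of frame t is deformed to match the outline of frame t+1, each
deformed triangle is clipped against the fresh, independent mesh of frame t+1
and the overlap areas become the transfer weights w_ij.  Transfer of a
per-triangle field is the area-weighted convex combination

    v'_j = sum_i v_i w_ij / a_j ,   a_j = area of target triangle j,

which is linear, positivity- and constant-preserving and obeys the maximum
principle.  The two partition invariants (row sums = deformed source areas,
column sums = target areas) are enforced exactly: the raw clipped weights
carry O(h^2) boundary slivers because the deformed and the fresh boundary are
different chordal discretizations of the same outline, so the weights are
balanced to the exact area margins by iterative proportional fitting before
being stored.  Gross boundary mismatch still surfaces as empty rows/columns
or non-convergence of the balancing.

A MorphoMovie bundles the per-frame meshes, velocity fields and interpolation
maps for the whole developmental window and is the input to every downstream
simulation (virtual clones, progenitor maps, tensors, expression transport).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.sparse import coo_matrix, csr_matrix
from shapely import STRtree
from shapely.geometry import Polygon

from .boundary import ControlSpline, control_vectors, fit_gaussian_rbf, \
    boundary_velocity_field
from .errors import ConsistencyError, GeometryError, ParameterError
from .meshing import TriMesh, triangulate, triangulate_ring, triangle_areas
from .springs import StiffnessProfile, stiffness_field, propagate
from .trajectory import ShapeSequence

__all__ = [
    "TriangleInterpolationMap",
    "MorphoMovie",
    "triangle_overlap_area",
    "build_interpolation_map",
    "transfer",
    "reverse_transfer",
    "reverse_map",
    "build_morphomovie",
    "save_movie",
    "load_movie",
]


def triangle_overlap_area(tri_a: np.ndarray, tri_b: np.ndarray) -> float:
    """Area of the convex intersection of two triangles (>= 0)."""
    tri_a = np.asarray(tri_a, dtype=float)
    tri_b = np.asarray(tri_b, dtype=float)
    pa, pb = Polygon(tri_a), Polygon(tri_b)
    if pa.area <= 0 or pb.area <= 0:
        raise GeometryError("degenerate triangle in overlap computation")
    return float(pa.intersection(pb).area)


@dataclass
class TriangleInterpolationMap:
    """Sparse conservative transfer weights from source to target triangles.

    weights[i, j] is the overlap area between deformed source triangle i and
    target triangle j; row sums equal ``source_areas`` and column sums equal
    ``target_areas`` (to the balancing tolerance).
    """

    weights: csr_matrix
    source_areas: np.ndarray
    target_areas: np.ndarray
    raw_defect: float = 0.0
    balance_iterations: int = 0

    @property
    def n_source(self) -> int:
        return self.weights.shape[0]

    @property
    def n_target(self) -> int:
        return self.weights.shape[1]

    def partition_defect(self) -> float:
        """Max relative deviation of row sums from the source areas."""
        rows = np.asarray(self.weights.sum(axis=1)).ravel()
        return float(np.max(np.abs(rows - self.source_areas) / self.source_areas))

    def coverage_defect(self) -> float:
        """Max relative deviation of column sums from the target areas."""
        cols = np.asarray(self.weights.sum(axis=0)).ravel()
        return float(np.max(np.abs(cols - self.target_areas) / self.target_areas))


def _triangle_polygons(points: np.ndarray, triangles: np.ndarray):
    return shapely.polygons(points[triangles])


def build_interpolation_map(deformed_mesh: TriMesh, mesh_t1: TriMesh,
                            balance_tol: float = 1e-12,
                            max_balance_iter: int = 200,
                            defect_tol: float = 1e-4) -> TriangleInterpolationMap:
    """Clip every deformed source triangle against the target mesh.

    ``deformed_mesh`` is the frame-t mesh with its displacement field already
    applied (its boundary must lie on the frame-t+1 outline).  Candidate
    pairs come from an STR packed R-tree on bounding boxes; exact areas from
    polygon clipping; the weights are then balanced to the area margins.
    """
    # snap both meshes to a common precision grid: GEOS overlay is not
    # robust when nearly identical vertices differ in the last ulp
    grid = 1e-12
    src_polys = shapely.set_precision(
        _triangle_polygons(deformed_mesh.points, deformed_mesh.triangles), grid)
    tgt_polys = shapely.set_precision(
        _triangle_polygons(mesh_t1.points, mesh_t1.triangles), grid)
    src_areas = triangle_areas(deformed_mesh.points, deformed_mesh.triangles)
    tgt_areas = mesh_t1.areas.copy()
    if np.any(src_areas <= 0):
        raise GeometryError("deformed mesh contains inverted triangles")

    tree = STRtree(tgt_polys)
    si, ti = tree.query(src_polys)
    inter = shapely.intersection(src_polys[si], tgt_polys[ti])
    w = shapely.area(inter)
    keep = w > 1e-12 * float(np.mean(tgt_areas))
    si, ti, w = si[keep], ti[keep], w[keep]

    n_s, n_t = len(src_areas), len(tgt_areas)
    weights = coo_matrix((w, (si, ti)), shape=(n_s, n_t)).tocsr()

    rows = np.asarray(weights.sum(axis=1)).ravel()
    cols = np.asarray(weights.sum(axis=0)).ravel()
    if np.any(rows <= 0):
        raise ConsistencyError(
            f"{int(np.sum(rows <= 0))} source triangles overlap no target "
            "triangle (boundary mismatch between deformed and target mesh)")
    if np.any(cols <= 0):
        raise ConsistencyError(
            f"{int(np.sum(cols <= 0))} target triangles are not covered "
            "(boundary mismatch between deformed and target mesh)")
    raw_defect = max(
        float(np.max(np.abs(rows - src_areas) / src_areas)),
        float(np.max(np.abs(cols - tgt_areas) / tgt_areas)))

    # balance to exact margins; total source mass is rescaled onto the target
    # total so both margin sets are consistent
    s = src_areas * (tgt_areas.sum() / src_areas.sum())
    t = tgt_areas
    wb = weights.tocsr().astype(float)
    it = 0
    defect = np.inf
    for it in range(1, max_balance_iter + 1):
        rows = np.asarray(wb.sum(axis=1)).ravel()
        r = s / rows
        wb = wb.multiply(r[:, None]).tocsr()
        cols = np.asarray(wb.sum(axis=0)).ravel()
        c = t / cols
        wb = wb.multiply(c[None, :]).tocsr()
        rows = np.asarray(wb.sum(axis=1)).ravel()
        defect = float(np.max(np.abs(rows - s) / s))
        if defect <= balance_tol:
            break
    if defect > defect_tol:
        raise ConsistencyError(
            f"partition defect {defect:.3g} after balancing exceeds "
            f"{defect_tol:.3g} (boundary mismatch)")
    return TriangleInterpolationMap(
        weights=wb, source_areas=s, target_areas=t,
        raw_defect=raw_defect, balance_iterations=it)


def transfer(values: np.ndarray, imap: TriangleInterpolationMap) -> np.ndarray:
    """Forward transfer of a per-triangle field (or a stack of fields).

    ``values`` has shape (n_source,) or (n_source, k).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != imap.n_source:
        raise ConsistencyError(
            f"field length {values.shape[0]} != source triangle count "
            f"{imap.n_source}")
    out = imap.weights.T @ values
    if out.ndim == 1:
        return out / imap.target_areas
    return out / imap.target_areas[:, None]


def reverse_transfer(values: np.ndarray, imap: TriangleInterpolationMap) -> np.ndarray:
    """Adjoint (target -> source) transfer under the area-weighted inner
    product: <forward(u), v>_target == <u, reverse(v)>_source exactly."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != imap.n_target:
        raise ConsistencyError(
            f"field length {values.shape[0]} != target triangle count "
            f"{imap.n_target}")
    out = imap.weights @ values
    if out.ndim == 1:
        return out / imap.source_areas
    return out / imap.source_areas[:, None]


def reverse_map(imap: TriangleInterpolationMap) -> TriangleInterpolationMap:
    """Transposed map playing the movie backwards (roles of the invariants
    swapped); built by transposition so forward and reverse transport are
    exactly adjoint."""
    return TriangleInterpolationMap(
        weights=imap.weights.T.tocsr(),
        source_areas=imap.target_areas,
        target_areas=imap.source_areas,
        raw_defect=imap.raw_defect,
        balance_iterations=imap.balance_iterations)


# --------------------------------------------------------------------------- #
# MorphoMovie
# --------------------------------------------------------------------------- #


@dataclass
class MorphoMovie:
    """Meshes + hourly velocity fields + interpolation maps for all frames.

    displacements[t] is the per-node displacement of mesh t over one hour
    (so it doubles as the velocity field in model units per hour); maps[t]
    transfers per-triangle fields from frame t to frame t+1.
    """

    meshes: list[TriMesh]
    displacements: list[np.ndarray]
    maps: list[TriangleInterpolationMap]
    metadata: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(self.maps) != len(self.meshes) - 1:
            raise ConsistencyError("need exactly one map per consecutive mesh pair")
        if len(self.displacements) != len(self.meshes) - 1:
            raise ConsistencyError("need exactly one velocity field per mesh pair")

    @property
    def n_frames(self) -> int:
        return len(self.meshes)

    def deformed_mesh(self, t: int) -> TriMesh:
        """Mesh t with its hourly displacement applied (lies on outline t+1)."""
        return self.meshes[t].with_points(
            self.meshes[t].points + self.displacements[t])


def build_morphomovie(seq: ShapeSequence, splines: list[ControlSpline],
                      profile: StiffnessProfile, target_edge_length: float,
                      rbf_width: float | None = None, rbf_ridge: float = 1e-10,
                      solver_method: str = "direct",
                      mesh_min_angle: float = 15.0,
                      metadata: dict | None = None) -> MorphoMovie:
    """Run the full per-frame pipeline over the whole shape sequence.

    For each consecutive pair: spline/outline intersections -> control
    vectors -> Gaussian RBF boundary field (snapped onto the next outline) ->
    spring propagation into the interior -> conservative interpolation map
    between the deformed mesh and the fresh next mesh.  Deterministic given
    its inputs.
    """
    seq.validate()
    meshes = [triangulate(seq[0], target_edge_length, min_angle=mesh_min_angle)]
    displacements: list[np.ndarray] = []
    maps: list[TriangleInterpolationMap] = []
    log: list[dict] = []
    for t in range(len(seq) - 1):
        try:
            mesh_t = meshes[t]
            cv = control_vectors(splines, seq[t], seq[t + 1])
            rbf = fit_gaussian_rbf(cv, width=rbf_width, ridge=rbf_ridge)
            bdisp = boundary_velocity_field(rbf, mesh_t, seq[t + 1], snap=True)
            stiff = stiffness_field(mesh_t, profile)
            disp = propagate(mesh_t, bdisp, stiff, method=solver_method)
            deformed = mesh_t.with_points(mesh_t.points + disp.vectors)
            # the fresh mesh shares the deformed boundary polygon exactly, so
            # the overlap weights partition to clipping precision
            mesh_t1 = triangulate_ring(deformed.boundary_ring,
                                       target_edge_length,
                                       min_angle=mesh_min_angle,
                                       stage=seq[t + 1].stage)
            imap = build_interpolation_map(deformed, mesh_t1)
            meshes.append(mesh_t1)
            displacements.append(disp.vectors)
            maps.append(imap)
            log.append({
                "frame": t,
                "spring_residual": disp.residual,
                "spring_iterations": disp.iterations,
                "raw_overlap_defect": imap.raw_defect,
                "partition_defect": imap.partition_defect(),
                "coverage_defect": imap.coverage_defect(),
            })
        except Exception as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
    meta = dict(metadata or {})
    meta.setdefault("stiffness_profile", {
        "kind": profile.kind, "midpoint_frac": profile.midpoint_frac,
        "steepness_scale": profile.steepness_scale,
        "amplitude": profile.amplitude})
    meta["target_edge_length"] = target_edge_length
    meta["frame_log"] = log
    return MorphoMovie(meshes=meshes, displacements=displacements,
                       maps=maps, metadata=meta)


# --------------------------------------------------------------------------- #
# serialization: directory of OFF meshes + CSV velocities + sparse map text
# --------------------------------------------------------------------------- #


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_movie(movie: MorphoMovie, directory: str | Path) -> Path:
    from .meshing import write_off

    directory = Path(directory)
    (directory / "meshes").mkdir(parents=True, exist_ok=True)
    (directory / "velocities").mkdir(exist_ok=True)
    (directory / "maps").mkdir(exist_ok=True)
    for t, mesh in enumerate(movie.meshes):
        write_off(mesh, directory / "meshes" / f"frame_{t:03d}.off")
    for t, disp in enumerate(movie.displacements):
        with open(directory / "velocities" / f"frame_{t:03d}.csv", "w") as fh:
            fh.write("dx,dy\n")
            for dx, dy in disp:
                fh.write(f"{float(dx)!r},{float(dy)!r}\n")
    for t, imap in enumerate(movie.maps):
        coo = imap.weights.tocoo()
        with open(directory / "maps" / f"map_{t:03d}.txt", "w") as fh:
            fh.write(f"# {imap.n_source} {imap.n_target}\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i} {j} {float(w)!r}\n")
    meta = dict(movie.metadata)
    meta["n_frames"] = movie.n_frames
    meta["config_hash"] = config_hash(
        {k: v for k, v in meta.items() if k != "frame_log"})
    with open(directory / "manifest.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    return directory


def load_movie(directory: str | Path) -> MorphoMovie:
    from .meshing import read_off

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        meta = json.load(fh)
    n = meta["n_frames"]
    meshes = [read_off(directory / "meshes" / f"frame_{t:03d}.off")
              for t in range(n)]
    displacements = [
        np.loadtxt(directory / "velocities" / f"frame_{t:03d}.csv",
                   delimiter=",", skiprows=1).reshape(-1, 2)
        for t in range(n - 1)]
    maps = []
    for t in range(n - 1):
        path = directory / "maps" / f"map_{t:03d}.txt"
        with open(path) as fh:
            header = fh.readline().split()
            n_s, n_t = int(header[1]), int(header[2])
            data = np.loadtxt(fh).reshape(-1, 3)
        w = coo_matrix((data[:, 2], (data[:, 0].astype(int),
                                     data[:, 1].astype(int))),
                       shape=(n_s, n_t)).tocsr()
        src = triangle_areas(meshes[t].points + displacements[t],
                             meshes[t].triangles)
        tgt = meshes[t + 1].areas
        src = src * (tgt.sum() / src.sum())
        maps.append(TriangleInterpolationMap(
            weights=w, source_areas=src, target_areas=tgt))
    return MorphoMovie(meshes=meshes, displacements=displacements,
                       maps=maps, metadata=meta)
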