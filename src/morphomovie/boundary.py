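"""Boundary control splines -> boundary velocity vectors.

Consecutive outlines have no landmarks, so the correspondence between a point
on the younger outline and a point on the older one is user-defined through
*boundary control splines*: curves drawn across the whole shape sequence,
oriented roughly along the PD axis.  The intersections of a spline with two
consecutive outlines define a control vector; the set of control vectors is
interpolated onto all (non-flank) mesh boundary nodes with a Gaussian
radial-basis-function (RBF) least-squares fit, one scalar interpolant per
displacement component:

    s(p) = sum_k  c_k  exp(-|p - p_k|^2 / (2 sigma^2))

where p_k are the control-vector origins.  With zero ridge and a nonsingular
(square) system the fit interpolates the control vectors exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import LineString

from .errors import MappingError, ParameterError, MorphoMovieError
from .meshing import TriMesh
from .trajectory import BoundaryShape

__all__ = [
    "ControlSpline",
    "ControlVectorSet",
    "RBFInterpolant",
    "intersect_spline",
    "control_vectors",
    "fit_gaussian_rbf",
    "boundary_velocity_field",
    "save_splines",
    "load_splines",
]


@dataclass
class ControlSpline:
    """A named polyline crossing the shape sequence, oriented along PD."""

    name: str
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or len(self.points) < 2:
            raise ParameterError("a control spline needs >= 2 points")

    def linestring(self) -> LineString:
        return LineString(self.points)


def _closed_ring(shape: BoundaryShape) -> LineString:
    return LineString(np.vstack([shape.outline, shape.outline[:1]]))


def intersect_spline(spline: ControlSpline, shape: BoundaryShape,
                     exclude_flank: bool = True) -> np.ndarray:
    """Intersection points of the spline with the outline, ordered along the
    spline; intersections on the flank (minimal-x) edge are excluded."""
    line = spline.linestring()
    ring = _closed_ring(shape)
    inter = line.intersection(ring)
    if inter.is_empty:
        return np.empty((0, 2))
    pts = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.geom_type == "Point":
            pts.append([geom.x, geom.y])
        else:  # grazing overlap: take representative endpoints
            pts.extend(np.asarray(geom.coords))
    pts = np.asarray(pts)
    if exclude_flank:
        scale = max(1.0, float(np.abs(shape.outline).max()))
        keep = pts[:, 0] > shape.flank_x + 1e-7 * scale
        pts = pts[keep]
    if len(pts) == 0:
        return np.empty((0, 2))
    order = np.argsort(shapely.line_locate_point(line, shapely.points(pts)))
    return pts[order]


@dataclass
class ControlVectorSet:
    """Matched boundary points on two consecutive outlines."""

    origins: np.ndarray  # on outline t
    tips: np.ndarray     # on outline t+1

    @property
    def vectors(self) -> np.ndarray:
        return self.tips - self.origins

    def __len__(self) -> int:
        return len(self.origins)


def control_vectors(splines: list[ControlSpline], shape_t: BoundaryShape,
                    shape_t1: BoundaryShape) -> ControlVectorSet:
    """One control vector per spline per matched intersection (k-th with k-th)."""
    origins, tips = [], []
    for sp in splines:
        a = intersect_spline(sp, shape_t)
        b = intersect_spline(sp, shape_t1)
        if len(a) != len(b):
            raise MappingError(
                f"spline '{sp.name}' intersects the two outlines a different "
                f"number of times ({len(a)} vs {len(b)})")
        origins.append(a)
        tips.append(b)
    origins = np.vstack([o for o in origins if len(o)]) if any(len(o) for o in origins) \
        else np.empty((0, 2))
    tips = np.vstack([t for t in tips if len(t)]) if any(len(t) for t in tips) \
        else np.empty((0, 2))
    if len(origins) == 0:
        raise MappingError("no control vectors: no spline intersects both outlines")
    return ControlVectorSet(origins=origins, tips=tips)


@dataclass
class RBFInterpolant:
    """Gaussian-RBF displacement interpolant (x and y components)."""

    centers: np.ndarray
    coefficients: np.ndarray  # (n_centers, 2)
    width: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((points[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        basis = np.exp(-d2 / (2.0 * self.width**2))
        return basis @ self.coefficients


def _default_width(centers: np.ndarray) -> float:
    """Mean nearest-neighbor spacing between centers (1.0 for a single one)."""
    if len(centers) < 2:
        return 1.0
    d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    return float(np.mean(d.min(axis=1)))


def fit_gaussian_rbf(cv: ControlVectorSet, width: float | None = None,
                     ridge: float = 1e-10) -> RBFInterpolant:
    """Least-squares Gaussian RBF fit of the control vectors.

    With ridge=0 and a nonsingular square system the interpolant reproduces
    every control vector exactly at its origin.
    """
    if len(cv) < 1:
        raise ParameterError("need at least one control vector")
    if width is not None and width <= 0:
        raise ParameterError("width must be > 0")
    if ridge < 0:
        raise ParameterError("ridge must be >= 0")
    sigma = width if width is not None else _default_width(cv.origins)
    c = cv.origins
    d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    g = np.exp(-d2 / (2.0 * sigma**2))
    a = g + ridge * np.eye(len(c))
    try:
        coef = np.linalg.solve(a, cv.vectors)
    except np.linalg.LinAlgError as exc:
        raise MorphoMovieError(
            "singular RBF system; increase the ridge parameter") from exc
    return RBFInterpolant(centers=c.copy(), coefficients=coef, width=sigma)


def _snap_to_ring(positions: np.ndarray, ring_pts: np.ndarray) -> np.ndarray:
    ring = LineString(np.vstack([ring_pts, ring_pts[:1]]))
    pts = shapely.points(positions)
    s = shapely.line_locate_point(ring, pts)
    snapped = shapely.line_interpolate_point(ring, s)
    return shapely.get_coordinates(snapped)


def _weighted_pava(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted isotonic regression (pool-adjacent-violators)."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    # blocks as (value, weight, count)
    vals, wts, cnt = [], [], []
    for yi, wi in zip(y, w):
        vals.append(yi); wts.append(wi); cnt.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            c = cnt[-2] + cnt[-1]
            tw = wts[-2] + wts[-1]
            vals.pop(); wts.pop(); cnt.pop()
            vals[-1], wts[-1], cnt[-1] = v, tw, c
    out = np.empty_like(y)
    k = 0
    for v, c in zip(vals, cnt):
        out[k:k + c] = v
        k += c
    return out


def _monotone_ring_positions(s: np.ndarray, fixed: np.ndarray, length: float,
                             min_gap: float) -> np.ndarray:
    """Enforce cyclically increasing arc-length positions with a minimum gap.

    ``s`` are per-boundary-node positions on the target ring (ring order);
    ``fixed`` marks nodes whose positions must not move (flank).  The cycle is
    cut at the first fixed node, unwrapped modulo the ring length, and the
    moving positions are projected onto the monotone-with-gap constraint set
    by weighted isotonic regression.  Prevents boundary folding and node
    collapse under closest-point snapping.
    """
    n = len(s)
    start = int(np.flatnonzero(fixed)[0]) if fixed.any() else 0
    order = (np.arange(n) + start) % n
    su = s[order].copy()
    # unwrap: positions should increase along the ring from the cut point
    base = su[0]
    su = np.mod(su - base, length)
    su[0] = 0.0
    idx = np.arange(n)
    shifted = su - idx * min_gap
    w = np.where(fixed[order], 1e9, 1.0)
    fitted = _weighted_pava(shifted, w) + idx * min_gap
    out = np.empty(n)
    out[order] = np.mod(fitted + base, length)
    return out


def boundary_velocity_field(rbf: RBFInterpolant, mesh: TriMesh,
                            target, snap: bool = True) -> np.ndarray:
    """Displacement vectors for every boundary node of ``mesh``.

    Flank nodes get zero displacement (they represent deep body tissue).  If
    ``snap`` is on, displaced non-flank boundary nodes are projected onto the
    target outline so that the deformed boundary lies exactly on it.  The
    ``target`` may be a BoundaryShape, a TriMesh (its boundary ring is used)
    or an (n, 2) ring array.
    """
    if isinstance(target, BoundaryShape):
        ring_pts = target.outline
    elif isinstance(target, TriMesh):
        ring_pts = target.boundary_ring
    else:
        ring_pts = np.asarray(target, dtype=float)

    pos = mesh.boundary_ring
    disp = rbf(pos)
    flank = mesh.flank_nodes
    disp[flank] = 0.0
    if snap:
        nb = mesh.n_boundary
        ring = LineString(np.vstack([ring_pts, ring_pts[:1]]))
        length = float(ring.length)
        s = shapely.line_locate_point(ring, shapely.points(pos + disp))
        is_fixed = np.zeros(nb, dtype=bool)
        is_fixed[flank] = True
        min_gap = 0.25 * length / nb
        s = _monotone_ring_positions(np.asarray(s, float), is_fixed, length,
                                     min_gap)
        snapped = shapely.get_coordinates(
            shapely.line_interpolate_point(ring, s))
        moving = ~is_fixed
        disp[moving] = snapped[moving] - pos[moving]
    return disp


# --------------------------------------------------------------------------- #
# spline file IO (JSON list of named splines)
# --------------------------------------------------------------------------- #


def save_splines(sets: dict[str, list[ControlSpline]], path: str | Path) -> None:
    data = {
        set_name: [{"name": sp.name, "points": sp.points.tolist()} for sp in splines]
        for set_name, splines in sets.items()
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_splines(path: str | Path) -> dict[str, list[ControlSpline]]:
    with open(path) as fh:
        data = json.load(fh)
    return {
        set_name: [ControlSpline(name=d["name"], points=np.asarray(d["points"]))
                   for d in entries]
        for set_name, entries in data.items()
    }
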