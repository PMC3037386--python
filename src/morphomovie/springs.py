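"""Propagation of boundary displacements into the mesh interior.

Every mesh edge is modeled as a lineal tension spring; prescribing the
boundary displacements and relaxing the spring forces to equilibrium yields a
smooth interior displacement field.  The equilibrium of node i is the
stiffness-weighted average of its neighbors' displacements,

    d_i = sum_j k_ij d_j / sum_j k_ij ,

which is a convex combination, so interior displacement components always lie
within the range of the boundary values (discrete maximum principle).  The
spring analogy is a device for generating hypothetical movement maps, not a
mechanical model of the tissue.

The stiffness of an edge combines an inverse-length term (shorter edges are
stiffer, which preserves element quality) with a tunable PD profile

    k_e = f(x_e) / l_e ,

where x_e is the edge midpoint's PD coordinate.  A sigmoid profile stiffens
distal edges (restricting distal growth), an inverted sigmoid relaxes them
(allowing greater distal expansion), and a constant profile leaves the PD
distribution unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, eye as sparse_eye
from scipy.sparse.linalg import spsolve

from .errors import ConvergenceError, DeformationError, ParameterError
from .meshing import TriMesh, triangle_areas

__all__ = [
    "StiffnessProfile",
    "StiffnessField",
    "DisplacementField",
    "stiffness_field",
    "propagate",
]

PROFILE_KINDS = ("constant", "sigmoid", "inverted_sigmoid")


@dataclass(frozen=True)
class StiffnessProfile:
    """PD scaling profile f(x) of the edge stiffness.

    kind: constant | sigmoid | inverted_sigmoid.
    midpoint_frac: sigmoid midpoint as a fraction of the frame's PD extent.
    steepness_scale: sigmoid steepness in units of 1 / PD extent.
    amplitude: f ranges over [1, 1 + amplitude].
    """

    kind: str = "constant"
    midpoint_frac: float = 2.0 / 3.0
    steepness_scale: float = 10.0
    amplitude: float = 4.0

    def __post_init__(self):
        if self.kind not in PROFILE_KINDS:
            raise ParameterError(f"unknown profile kind {self.kind!r}")
        if self.amplitude < 0 or self.steepness_scale <= 0:
            raise ParameterError("amplitude must be >= 0 and steepness > 0")

    def evaluate(self, x: np.ndarray, x_min: float, x_max: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "constant":
            return np.ones_like(x)
        extent = max(x_max - x_min, 1e-12)
        mid = x_min + self.midpoint_frac * extent
        s = self.steepness_scale / extent
        sig = 1.0 / (1.0 + np.exp(-s * (x - mid)))
        if self.kind == "sigmoid":
            return 1.0 + self.amplitude * sig
        return 1.0 + self.amplitude * (1.0 - sig)


@dataclass
class StiffnessField:
    """Per-edge stiffness coefficients, aligned with ``mesh.edges``."""

    coefficients: np.ndarray
    profile: StiffnessProfile


def stiffness_field(mesh: TriMesh, profile: StiffnessProfile) -> StiffnessField:
    edges = mesh.edges
    p = mesh.points
    vec = p[edges[:, 1]] - p[edges[:, 0]]
    lengths = np.hypot(vec[:, 0], vec[:, 1])
    mid_x = 0.5 * (p[edges[:, 0], 0] + p[edges[:, 1], 0])
    f = profile.evaluate(mid_x, p[:, 0].min(), p[:, 0].max())
    k = f / lengths
    if np.any(~np.isfinite(k)) or np.any(k <= 0):
        raise ParameterError("stiffness coefficients must be positive and finite")
    return StiffnessField(coefficients=k, profile=profile)


@dataclass
class DisplacementField:
    """Full-mesh displacement vectors with solver diagnostics."""

    vectors: np.ndarray          # (n_points, 2)
    iterations: int
    residual: float


def _weighted_adjacency(mesh: TriMesh, stiffness: StiffnessField) -> csr_matrix:
    e = mesh.edges
    k = stiffness.coefficients
    n = mesh.n_points
    w = coo_matrix((k, (e[:, 0], e[:, 1])), shape=(n, n))
    return (w + w.T).tocsr()


def propagate(mesh: TriMesh, boundary_disp: np.ndarray, stiffness: StiffnessField,
              max_iter: int = 10_000, tol: float | None = None,
              relaxation: float = 1.0, method: str = "direct",
              check_inversion: bool = True, _depth: int = 0) -> DisplacementField:
    """Equilibrate the edge springs given prescribed boundary displacements.

    ``boundary_disp`` has one row per boundary node (any flank pinning is
    applied upstream by zeroing those rows).  ``method`` selects how the
    stiffness-weighted-average fixed point is computed: "direct" solves the
    sparse equilibrium system exactly, "jacobi" runs the damped fixed-point
    iteration until the update falls below ``tol`` (default: 1e-8 x mean edge
    length).  On element inversion the step is retried as two half steps.
    """
    boundary_disp = np.asarray(boundary_disp, dtype=float)
    nb = mesh.n_boundary
    if boundary_disp.shape != (nb, 2):
        raise ParameterError(f"boundary_disp must have shape ({nb}, 2)")
    if not 0 < relaxation <= 1:
        raise ParameterError("relaxation must be in (0, 1]")

    w = _weighted_adjacency(mesh, stiffness)
    deg = np.asarray(w.sum(axis=1)).ravel()
    n = mesh.n_points
    d = np.zeros((n, 2))
    d[:nb] = boundary_disp
    interior = np.arange(nb, n)

    if len(interior) == 0:
        iterations, residual = 0, 0.0
    elif method == "direct":
        # (D - W)_II d_I = W_IB d_B : the exact fixed point of the iteration
        lap = sparse_eye(n, format="csr").multiply(deg) - w
        a = lap[interior][:, interior].tocsc()
        rhs = w[interior][:, :nb] @ boundary_disp
        d[interior] = np.column_stack([spsolve(a, rhs[:, 0]), spsolve(a, rhs[:, 1])])
        iterations = 1
        upd = w.dot(d) / deg[:, None] - d
        residual = float(np.abs(upd[interior]).max()) if len(interior) else 0.0
    elif method == "jacobi":
        e = mesh.edges
        mean_len = float(np.mean(np.hypot(
            *(mesh.points[e[:, 1]] - mesh.points[e[:, 0]]).T)))
        eps = tol if tol is not None else 1e-8 * mean_len
        residual = np.inf
        iterations = 0
        for iterations in range(1, max_iter + 1):
            avg = w.dot(d) / deg[:, None]
            upd = avg[interior] - d[interior]
            residual = float(np.abs(upd).max())
            d[interior] += relaxation * upd
            if residual <= eps:
                break
        else:
            raise ConvergenceError(
                f"spring relaxation did not converge in {max_iter} iterations",
                residual=residual)
    else:
        raise ParameterError(f"unknown method {method!r}")

    if check_inversion:
        new_pts = mesh.points + d
        if np.any(triangle_areas(new_pts, mesh.triangles) <= 0):
            if _depth >= 3:
                raise DeformationError(
                    "element inversion persists after step halving")
            half = propagate(mesh, boundary_disp / 2.0, stiffness, max_iter, tol,
                             relaxation, method, check_inversion, _depth + 1)
            mid_mesh = mesh.with_points(mesh.points + half.vectors)
            # remaining boundary displacement measured from the midpoint
            rest = boundary_disp - half.vectors[:nb]
            second = propagate(mid_mesh, rest, stiffness, max_iter, tol,
                               relaxation, method, check_inversion, _depth + 1)
            total = half.vectors + second.vectors
            return DisplacementField(
                vectors=total,
                iterations=half.iterations + second.iterations,
                residual=max(half.residual, second.residual))

    return DisplacementField(vectors=d, iterations=iterations, residual=residual)
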