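"""Growth tensors: per-triangle velocity-gradient decomposition.

Assuming the velocity varies linearly inside a triangle, the 2x2 velocity
gradient L (units: per hour) is the unique matrix mapping the two edge
vectors to their velocity differences.  Its symmetric part S describes
deformation: trace(S) = lambda1 + lambda2 is the relative area expansion
rate, and the normalized eigenvalue gap (lambda1 - lambda2) / (lambda1 +
lambda2) measures anisotropy with the principal direction of lambda1.  The
antisymmetric part gives the local rigid rotation rate.  Expansion rate
translates into a cell-cycle time as the time needed to double the triangle
area: T = ln 2 / expansion_rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .meshing import TriMesh
from .remap import MorphoMovie

__all__ = [
    "GrowthTensor",
    "triangle_velocity_gradient",
    "decompose",
    "cell_cycle_time",
    "tensor_report",
    "regional_cell_cycle",
    "CELL_CYCLE_CLAMP",
]

#: display clamp for cell-cycle heat maps, hours (red = fast 10 h, blue = slow 42 h)
CELL_CYCLE_CLAMP = (10.0, 42.0)

#: fraction of the PD axis measured from the tip that counts as "distal"
DISTAL_FRACTION = 1.0 / 3.0


@dataclass
class GrowthTensor:
    """Velocity-gradient decomposition for one triangle.

    expansion_rate: trace of the symmetric part (per hour).
    anisotropy: (l1 - l2)/(l1 + l2) of the symmetric part, NaN when the
        expansion rate is ~0 (pure rotation/shear leaves it undefined).
    direction: principal strain direction (unit vector), NaN when flagged.
    rotation_rate: rigid rotation rate, radians per hour (positive = CCW).
    cell_cycle: ln2 / expansion_rate, np.inf for non-positive expansion.
    """

    L: np.ndarray
    expansion_rate: float
    anisotropy: float
    direction: np.ndarray
    rotation_rate: float
    cell_cycle: float


def triangle_velocity_gradient(mesh: TriMesh, node_velocities: np.ndarray,
                               tri: int) -> np.ndarray:
    """Velocity gradient L with L @ edge = velocity difference, exactly."""
    v = np.asarray(node_velocities, dtype=float)
    if v.shape != (mesh.n_points, 2):
        raise ParameterError("node_velocities must be (n_points, 2)")
    idx = mesh.triangles[tri]
    p = mesh.points[idx]
    edges = np.column_stack([p[1] - p[0], p[2] - p[0]])  # 2x2: columns e1, e2
    dv = np.column_stack([v[idx[1]] - v[idx[0]], v[idx[2]] - v[idx[0]]])
    det = np.linalg.det(edges)
    if abs(det) < 1e-300:
        raise GeometryError(f"triangle {tri} is degenerate")
    return dv @ np.linalg.inv(edges)


def decompose(L: np.ndarray) -> GrowthTensor:
    """Split L into expansion, anisotropy (+direction) and rotation."""
    L = np.asarray(L, dtype=float)
    s = 0.5 * (L + L.T)
    a = 0.5 * (L - L.T)
    expansion = float(np.trace(s))
    eigval, eigvec = np.linalg.eigh(s)  # ascending: l2, l1
    l2, l1 = float(eigval[0]), float(eigval[1])
    if abs(expansion) > 1e-12 * max(1.0, abs(l1), abs(l2)) and expansion > 0:
        aniso = (l1 - l2) / (l1 + l2)
        direction = eigvec[:, 1]
    else:
        aniso = np.nan
        direction = np.array([np.nan, np.nan])
    rotation = float(a[1, 0])
    return GrowthTensor(L=L, expansion_rate=expansion, anisotropy=aniso,
                        direction=direction, rotation_rate=rotation,
                        cell_cycle=cell_cycle_time(expansion))


def cell_cycle_time(expansion_rate: float) -> float:
    """Hours to double a triangle's area at the given expansion rate."""
    if expansion_rate <= 0:
        return np.inf
    return float(np.log(2.0) / expansion_rate)


def _all_gradients(mesh: TriMesh, node_velocities: np.ndarray) -> np.ndarray:
    """Vectorized per-triangle velocity gradients, shape (m, 2, 2)."""
    v = np.asarray(node_velocities, dtype=float)
    idx = mesh.triangles
    p = mesh.points[idx]
    e = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)
    dv = np.stack([v[idx[:, 1]] - v[idx[:, 0]], v[idx[:, 2]] - v[idx[:, 0]]], axis=2)
    return dv @ np.linalg.inv(e)


def tensor_report(movie: MorphoMovie, frame: int, dt: float = 1.0) -> pd.DataFrame:
    """Per-triangle tensor table for one frame of the movie.

    Columns include centroid position, expansion rate, cell-cycle time
    (clamped copy for heat maps per CELL_CYCLE_CLAMP), anisotropy, principal
    angle, rotation rate and the anisotropy-ellipse semi-axes exp(lambda*dt).
    """
    if not 0 <= frame < movie.n_frames - 1:
        raise ParameterError("frame must have a velocity field (not the last)")
    mesh = movie.meshes[frame]
    grads = _all_gradients(mesh, movie.displacements[frame])
    s = 0.5 * (grads + np.transpose(grads, (0, 2, 1)))
    a = 0.5 * (grads - np.transpose(grads, (0, 2, 1)))
    eigval, eigvec = np.linalg.eigh(s)
    l2, l1 = eigval[:, 0], eigval[:, 1]
    expansion = l1 + l2
    with np.errstate(divide="ignore", invalid="ignore"):
        aniso = np.where(expansion > 0, (l1 - l2) / (l1 + l2), np.nan)
        cycle = np.where(expansion > 0, np.log(2.0) / expansion, np.inf)
    angle = np.degrees(np.arctan2(eigvec[:, 1, 1], eigvec[:, 0, 1]))
    cent = mesh.centroids
    lo, hi = CELL_CYCLE_CLAMP
    return pd.DataFrame({
        "triangle": np.arange(mesh.n_triangles),
        "x": cent[:, 0], "y": cent[:, 1],
        "expansion_rate": expansion,
        "cell_cycle": cycle,
        "cell_cycle_clamped": np.clip(cycle, lo, hi),
        "anisotropy": aniso,
        "principal_angle_deg": angle,
        "rotation_rate": a[:, 1, 0],
        "ellipse_major": np.exp(l1 * dt),
        "ellipse_minor": np.exp(l2 * dt),
    })


def regional_cell_cycle(movie: MorphoMovie, frame: int) -> dict:
    """Average cell-cycle time of the distal third vs the proximal two-thirds.

    The PD axis is measured from the body wall (x = 0) to the tip; the
    distal region is the DISTAL_FRACTION of that extent nearest the tip.
    Only triangles with finite cell-cycle time (positive expansion) enter
    the averages.
    """
    table = tensor_report(movie, frame)
    mesh = movie.meshes[frame]
    tip = float(mesh.points[:, 0].max())
    split = tip - DISTAL_FRACTION * tip
    finite = np.isfinite(table["cell_cycle"])
    distal = finite & (table["x"] >= split)
    proximal = finite & (table["x"] < split) & (table["x"] >= 0)
    return {
        "distal_mean_cell_cycle": float(table.loc[distal, "cell_cycle"].mean()),
        "proximal_mean_cell_cycle": float(table.loc[proximal, "cell_cycle"].mean()),
        "split_x": split,
    }
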