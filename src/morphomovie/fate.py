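"""Virtual clonal fate maps: advection through the movie plus cell mixing.

A virtual clone is a per-triangle labeled-cell density in [0, 1] (value 1 =
every cell labeled).  Each simulated hour consists of (i) isotropic diffusion
on the current mesh, modeling mesenchymal cell mixing, and (ii) conservative
transfer to the next mesh through the frame's interpolation map, modeling the
tissue movement itself.  Experimental clones are stochastic realizations of
these densities.

Diffusion uses a finite-volume two-point flux scheme on the triangle
adjacency (flux across a shared edge proportional to D x edge length x value
difference / centroid distance) with zero-flux outer boundaries and explicit
Euler substeps, so the area integral of the density is conserved to rounding.

Progenitor maps run the movie backwards through the transposed (adjoint)
interpolation maps: they answer "which early regions can contribute to this
final region", and with mixing the progenitor region of a final segment is
always proportionally larger than the segment itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix

from .errors import ConsistencyError, ParameterError, StabilityError
from .meshing import TriMesh, edge_neighbors
from .remap import MorphoMovie, reverse_transfer, transfer

__all__ = [
    "ScalarField",
    "DiffusionConfig",
    "seed_clone",
    "diffuse",
    "simulate_fate",
    "simulate_matrix",
    "simulate_progenitors",
]


@dataclass
class ScalarField:
    """Per-triangle scalar values attached to one movie frame."""

    values: np.ndarray
    frame: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("field values must be finite")

    def integral(self, mesh: TriMesh) -> float:
        return float(self.values @ mesh.areas)


#: the two mixing constants explored by the published calibration, in the
#: original work's (unstated) units
PAPER_DIFFUSION_CONSTANTS = (0.03, 0.08)

#: conversion from those units to this model's area units: chosen once so
#: that the lower published constant gives an rms mixing displacement
#: sqrt(2 D t) of ~0.3 model units (~7% of the final PD length) over the
#: full 71-hour window — clones disperse visibly but stay within one or two
#: PD segments, as the real clones do
DIFFUSION_UNIT_SCALE = 0.02


def paper_diffusion(value: float) -> float:
    """Re-express a published mixing constant in model-area units per hour."""
    return value * DIFFUSION_UNIT_SCALE


@dataclass(frozen=True)
class DiffusionConfig:
    """Cell-mixing diffusion parameters.

    diffusion: D, in model-area units per hour.  The default is the lower
        published calibration constant converted to model units
        (paper_diffusion(0.03)); mixing acts on top of that inherent to the
        hourly re-meshing.
    substeps_per_hour: explicit Euler substeps; raised automatically when the
        stability bound demands it.
    safety: fraction of the explicit stability limit actually used.
    """

    diffusion: float = PAPER_DIFFUSION_CONSTANTS[0] * DIFFUSION_UNIT_SCALE
    substeps_per_hour: int = 10
    safety: float = 0.5

    def __post_init__(self):
        if self.diffusion < 0:
            raise ParameterError("diffusion constant must be >= 0")
        if self.substeps_per_hour < 1 or not 0 < self.safety < 1:
            raise ParameterError("substeps >= 1 and safety in (0, 1) required")


def seed_clone(mesh: TriMesh, triangle_id: int) -> ScalarField:
    """Label one triangle with density one (a virtual clonal dye)."""
    if not 0 <= triangle_id < mesh.n_triangles:
        raise ParameterError(
            f"triangle_id {triangle_id} out of range 0..{mesh.n_triangles - 1}")
    v = np.zeros(mesh.n_triangles)
    v[triangle_id] = 1.0
    return ScalarField(values=v, frame=0)


def _diffusion_operator(mesh: TriMesh) -> tuple[csr_matrix, float]:
    """Unit-D flux divergence matrix A with dv/dt = D * A v, plus the largest
    unit-D rate max_i sum_e (L/d) / area_i governing the stability bound."""
    key = "diffusion_op"
    if key not in mesh._cache:
        en = edge_neighbors(mesh)
        cond = en.edge_length / en.centroid_distance
        a, b = en.tri_a, en.tri_b
        m = mesh.n_triangles
        rows = np.concatenate([a, b, a, b])
        cols = np.concatenate([b, a, a, b])
        vals = np.concatenate([cond, cond, -cond, -cond])
        flux = coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsr()
        inv_area = 1.0 / mesh.areas
        op = flux.multiply(inv_area[:, None]).tocsr()
        rate = np.zeros(m)
        np.add.at(rate, a, cond)
        np.add.at(rate, b, cond)
        mesh._cache[key] = (op, float(np.max(rate * inv_area)))
    return mesh._cache[key]


def diffuse(field: ScalarField | np.ndarray, mesh: TriMesh, cfg: DiffusionConfig,
            hours: float = 1.0) -> ScalarField | np.ndarray:
    """Diffuse a field (or a stack of fields, shape (m, k)) for ``hours``.

    Zero-flux boundaries; the area integral is conserved exactly up to
    rounding.  Substeps are increased automatically to satisfy the explicit
    stability bound; a StabilityError is raised only if that is impossible.
    """
    is_field = isinstance(field, ScalarField)
    v = field.values.copy() if is_field else np.array(field, dtype=float)
    if v.shape[0] != mesh.n_triangles:
        raise ConsistencyError("field length does not match triangle count")
    if cfg.diffusion > 0 and hours > 0:
        op, max_rate = _diffusion_operator(mesh)
        dt_max = cfg.safety / (cfg.diffusion * max_rate)
        needed = max(cfg.substeps_per_hour, math.ceil(hours / dt_max))
        if needed > 10_000_000:
            raise StabilityError(
                "stability bound requires an impractical substep count",
                suggested_substeps=needed)
        dt = hours / needed
        scaled = (cfg.diffusion * dt) * op
        for _ in range(needed):
            v = v + scaled @ v
    if is_field:
        return ScalarField(values=v, frame=field.frame)
    return v


def simulate_fate(movie: MorphoMovie, seed: tuple[int, int] | ScalarField,
                  cfg: DiffusionConfig) -> list[ScalarField]:
    """Simulate a virtual clone from its seed frame to the end of the movie.

    Each hour: diffuse on the current mesh, then transfer through the
    frame's interpolation map.  Returns one ScalarField per frame from the
    seed frame to the last frame.
    """
    if isinstance(seed, ScalarField):
        frame, values = seed.frame, seed.values.copy()
    else:
        frame, tri = seed
        values = seed_clone(movie.meshes[frame], tri).values
    if not 0 <= frame < movie.n_frames - 1:
        raise ParameterError("seed frame must precede the last frame")
    out = [ScalarField(values=values.copy(), frame=frame)]
    v = values
    for t in range(frame, movie.n_frames - 1):
        v = diffuse(v, movie.meshes[t], cfg, hours=1.0)
        v = transfer(v, movie.maps[t])
        out.append(ScalarField(values=v.copy(), frame=t + 1))
    return out


def simulate_matrix(movie: MorphoMovie, fields: np.ndarray, start_frame: int,
                    cfg: DiffusionConfig) -> np.ndarray:
    """Propagate a stack of fields (columns) to the final frame in one pass.

    Advection and diffusion are linear, so propagating the identity matrix
    yields the final-frame density of every possible single-triangle seed at
    once; this is how exhaustive virtual-clone scans stay affordable.
    """
    v = np.asarray(fields, dtype=float)
    for t in range(start_frame, movie.n_frames - 1):
        v = diffuse(v, movie.meshes[t], cfg, hours=1.0)
        v = transfer(v, movie.maps[t])
    return v


def simulate_progenitors(movie: MorphoMovie, final_regions: list[np.ndarray],
                         cfg: DiffusionConfig) -> list[np.ndarray]:
    """Backward transport of final-frame regions through the reverse map.

    ``final_regions`` are disjoint triangle index sets on the last frame.
    Returns, per frame, an (n_triangles, n_regions) array of membership
    probabilities.  If the regions partition the last frame, the rows sum to
    one at every frame (the reverse transport of the all-ones field is the
    all-ones field, and diffusion fixes uniform fields).
    """
    last = movie.meshes[-1]
    taken = np.zeros(last.n_triangles, dtype=bool)
    for reg in final_regions:
        reg = np.asarray(reg, dtype=int)
        if reg.size and (reg.min() < 0 or reg.max() >= last.n_triangles):
            raise ParameterError("region triangle index out of range")
        if np.any(taken[reg]):
            raise ParameterError("final regions must be disjoint")
        taken[reg] = True

    k = len(final_regions)
    v = np.zeros((last.n_triangles, k))
    for j, reg in enumerate(final_regions):
        v[np.asarray(reg, dtype=int), j] = 1.0

    out = [None] * movie.n_frames
    out[-1] = v.copy()
    for t in range(movie.n_frames - 2, -1, -1):
        v = reverse_transfer(v, movie.maps[t])
        v = diffuse(v, movie.meshes[t], cfg, hours=1.0)
        out[t] = v.copy()
    return out
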