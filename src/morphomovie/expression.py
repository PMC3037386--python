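"""Growth-only transport of gene-expression domains and regulation calls.

A thresholded expression domain (e.g. a Hoxd13 in-situ at one stage) is an
indicator field on one frame's mesh.  Transporting it forward or backward
through the movie predicts how the domain would evolve if it were only
passively carried along by tissue movement.  Differencing that prediction
against the observed domain at the target stage separates active regulation
from growth: where the gene is observed ON but the growth-only prediction is
OFF the gene must have been up-regulated, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clones import AlignmentTransform, rasterize_mask_to_mesh
from .errors import ConsistencyError, ParameterError
from .fate import DiffusionConfig, diffuse
from .meshing import TriMesh
from .remap import MorphoMovie, reverse_transfer, transfer

__all__ = [
    "ExpressionDomain",
    "map_domain",
    "transport",
    "regulation_difference",
]


@dataclass
class ExpressionDomain:
    """Binary expression domain of one gene on one frame's mesh."""

    values: np.ndarray
    gene: str = ""
    frame: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        bad = ~np.isin(self.values, (0.0, 1.0))
        if np.any(bad):
            raise ParameterError("an input expression domain must be 0/1 valued")


def map_domain(mask: np.ndarray, mesh: TriMesh,
               alignment: AlignmentTransform | None = None,
               gene: str = "", frame: int = 0,
               coverage_threshold: float = 0.5) -> ExpressionDomain:
    """Rasterize a binary expression image onto the mesh (shared machinery
    with experimental-clone ingestion)."""
    clone = rasterize_mask_to_mesh(mask, mesh, alignment,
                                   coverage_threshold=coverage_threshold)
    v = np.zeros(mesh.n_triangles)
    v[clone.triangles] = 1.0
    return ExpressionDomain(values=v, gene=gene, frame=frame)


def transport(movie: MorphoMovie, domain: ExpressionDomain, to_frame: int,
              cfg: DiffusionConfig | None = None) -> np.ndarray:
    """Growth-only prediction of the domain at ``to_frame``.

    Forward transport uses the interpolation maps, backward transport the
    reverse (adjoint) maps; the direction is inferred from the frames.
    Mixing defaults to zero: expression domains are tissue marks, not
    dispersing labeled cells.  Values stay in [0, 1].
    """
    cfg = cfg or DiffusionConfig(diffusion=0.0)
    if not 0 <= domain.frame < movie.n_frames:
        raise ParameterError("domain frame outside the movie")
    if not 0 <= to_frame < movie.n_frames:
        raise ParameterError("target frame outside the movie")
    if len(domain.values) != movie.meshes[domain.frame].n_triangles:
        raise ConsistencyError("domain field does not match its frame's mesh")
    v = domain.values.copy()
    if to_frame >= domain.frame:
        for t in range(domain.frame, to_frame):
            v = diffuse(v, movie.meshes[t], cfg, hours=1.0)
            v = transfer(v, movie.maps[t])
    else:
        for t in range(domain.frame - 1, to_frame - 1, -1):
            v = reverse_transfer(v, movie.maps[t])
            v = diffuse(v, movie.meshes[t], cfg, hours=1.0)
    return v


def regulation_difference(predicted: np.ndarray, observed: ExpressionDomain,
                          threshold: float = 0.5) -> np.ndarray:
    """Per-triangle regulation class from prediction vs observation.

    Returns an array of strings: "up" where the gene is observed but the
    growth-only prediction is below the threshold, "down" where it is absent
    but predicted above the threshold, "consistent" elsewhere.
    """
    predicted = np.asarray(predicted, dtype=float)
    obs = observed.values
    if predicted.shape != obs.shape:
        raise ConsistencyError("predicted and observed fields differ in length")
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    out = np.full(len(obs), "consistent", dtype=object)
    out[(obs == 1.0) & (predicted < threshold)] = "up"
    out[(obs == 0.0) & (predicted > threshold)] = "down"
    return out
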