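"""Experimental clones: ingestion, scoring, mixing and shape statistics.

An experimental clone is the set of final-frame triangles covered by the
thresholded, aligned clone image.  A virtual clone (the simulated density of
one labeled seed triangle) is scored against it with a two-factor product:

    score = P(cell from the virtual distribution lies in the clone)
            x (fraction of clone triangles inside the virtual support)
          = [ sum_{i in E_c cap S} p_i a_i / sum_i p_i a_i ]
            x [ |E_c cap S| / n_c ] ,

where p_i is the virtual density, a_i the triangle area and the support S is
the set of triangles whose density exceeds a fraction of the field maximum
(continuous fields have no crisp support; an absolute cutoff is defeated by
the tiny numerical-diffusion tails that re-meshing spreads everywhere).  The
first factor treats the virtual clone as the probability distribution from
which labeled cells are drawn — it penalizes virtual mass outside the clone
and is invariant to the overall concentration of the field, so maps cannot
win just by keeping their densities peaked.  The second factor penalizes
clone cells found outside the virtual clone.  The score is in [0, 1], is 1
when the density is exactly the clone indicator, and is 0 exactly when the
supports are disjoint.  A movie's total score is the product over clones of
their best exhaustive-scan scores, so a map must match all clones at once to
score well.

Clone probability distributions are estimated from binary clones by an
iterated mean filter over edge-adjacent triangles; the overlap between two
such distributions is their Bhattacharyya coefficient sum_i sqrt(p_i q_i),
which is symmetric, zero for disjoint supports and 1 for identical
distributions — the statistic used to calibrate the mixing constant D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from .errors import ConsistencyError, ParameterError
from .fate import DiffusionConfig, simulate_matrix
from .meshing import TriMesh, edge_neighbors
from .remap import MorphoMovie

__all__ = [
    "ExperimentalClone",
    "CloneScore",
    "AlignmentTransform",
    "rasterize_mask_to_mesh",
    "clone_score",
    "best_match",
    "map_score",
    "full_scan_comparisons",
    "mean_filter",
    "overlap_score",
    "virtual_pair_overlap",
    "calibrate_mixing",
    "clone_extents",
    "SUPPORT_FRACTION",
]

#: a triangle belongs to a virtual clone's support when its density exceeds
#: this fraction of the field's maximum (continuous densities have no crisp
#: support, and an absolute cutoff is swamped by numerical-diffusion tails)
SUPPORT_FRACTION = 0.05


@dataclass
class ExperimentalClone:
    """Labeled triangle set on a stated frame's mesh."""

    triangles: np.ndarray
    frame: int = -1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.triangles = np.unique(np.asarray(self.triangles, dtype=int))

    @property
    def n(self) -> int:
        return len(self.triangles)


@dataclass(frozen=True)
class AlignmentTransform:
    """Similarity transform from image coordinates to model coordinates.

    Image coordinates are pixel centers with y up: (col + 0.5,
    n_rows - row - 0.5).  model = scale * R(rotation_deg) @ image + translation.
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def _rot(self) -> np.ndarray:
        a = np.radians(self.rotation_deg)
        return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])

    def image_to_model(self, pts: np.ndarray) -> np.ndarray:
        return self.scale * pts @ self._rot().T + np.asarray(self.translation)

    def model_to_image(self, pts: np.ndarray) -> np.ndarray:
        return ((pts - np.asarray(self.translation)) / self.scale) @ self._rot()

    def to_dict(self) -> dict:
        return {"scale": self.scale, "rotation_deg": self.rotation_deg,
                "translation": list(self.translation)}

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentTransform":
        return cls(scale=d.get("scale", 1.0),
                   rotation_deg=d.get("rotation_deg", 0.0),
                   translation=tuple(d.get("translation", (0.0, 0.0))))


def rasterize_mask_to_mesh(mask: np.ndarray, mesh: TriMesh,
                           alignment: AlignmentTransform | None = None,
                           coverage_threshold: float = 0.5,
                           frame: int = -1) -> ExperimentalClone:
    """Triangles whose labeled-pixel coverage reaches the threshold.

    ``mask`` is a binary image (rows x cols).  Each mesh triangle is projected
    into image coordinates; its coverage is the labeled fraction of the pixels
    it contains (sub-pixel triangles fall back to their centroid pixel).
    """
    mask = np.asarray(mask).astype(bool)
    alignment = alignment or AlignmentTransform()
    n_rows = mask.shape[0]
    included = []
    for t in range(mesh.n_triangles):
        img = alignment.model_to_image(mesh.points[mesh.triangles[t]])
        cols = img[:, 0] - 0.5
        rows = n_rows - img[:, 1] - 0.5
        rr, cc = draw_polygon(rows, cols, shape=mask.shape)
        if len(rr) == 0:
            r = int(round(rows.mean()))
            c = int(round(cols.mean()))
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
                continue
            rr, cc = np.array([r]), np.array([c])
        if mask[rr, cc].mean() >= coverage_threshold:
            included.append(t)
    return ExperimentalClone(triangles=np.asarray(included, dtype=int),
                             frame=frame)


# --------------------------------------------------------------------------- #
# scoring
# --------------------------------------------------------------------------- #


def clone_score(virtual: np.ndarray, clone: ExperimentalClone,
                areas: np.ndarray | None = None,
                support_fraction: float = SUPPORT_FRACTION) -> float:
    """Score a virtual density against an experimental triangle set.

    ``areas`` are the triangle areas of the clone's mesh (uniform if omitted),
    used to convert densities into the labeled-cell probability distribution.
    """
    if clone.n == 0:
        raise ParameterError("cannot score an empty experimental clone")
    v = np.asarray(virtual, dtype=float)
    if clone.triangles.max() >= len(v):
        raise ConsistencyError("clone triangle index exceeds field length")
    mass = v if areas is None else v * np.asarray(areas, dtype=float)
    total = mass.sum()
    if total <= 0:
        return 0.0
    inside = v[clone.triangles] > support_fraction * v.max()
    prob = mass[clone.triangles][inside].sum() / total
    return float(prob * inside.sum() / clone.n)


@dataclass
class CloneScore:
    """Per-clone best matches and the movie's total (product) score."""

    best_seeds: np.ndarray
    best_scores: np.ndarray
    total: float
    comparisons: int


def _final_fields(movie: MorphoMovie, cfg: DiffusionConfig,
                  seed_frame: int) -> np.ndarray:
    """Final-frame density of every single-triangle seed (cached, columns)."""
    key = ("final_fields", cfg.diffusion, cfg.substeps_per_hour, seed_frame)
    if key not in movie._cache:
        n0 = movie.meshes[seed_frame].n_triangles
        movie._cache[key] = simulate_matrix(
            movie, np.eye(n0), seed_frame, cfg)
    return movie._cache[key]


def _score_all_seeds(movie: MorphoMovie, clone: ExperimentalClone,
                     cfg: DiffusionConfig, seed_frame: int,
                     support_fraction: float) -> np.ndarray:
    """clone_score of every candidate seed, vectorized over the field stack."""
    fields = _final_fields(movie, cfg, seed_frame)
    areas = movie.meshes[-1].areas
    mass = fields * areas[:, None]
    total = mass.sum(axis=0)
    inside = fields[clone.triangles, :] > \
        support_fraction * fields.max(axis=0, keepdims=True)
    prob = (mass[clone.triangles, :] * inside).sum(axis=0) / total
    return prob * inside.sum(axis=0) / clone.n


def best_match(movie: MorphoMovie, clone: ExperimentalClone,
               cfg: DiffusionConfig, seed_frame: int = 0,
               support_fraction: float = SUPPORT_FRACTION) -> tuple[int, float]:
    """Exhaustive scan over every seed triangle of ``seed_frame``.

    Returns the argmax seed and its score; ties break to the lowest triangle
    index.  One comparison per (seed, clone) pair, i.e. a full-map evaluation
    performs n_seed_triangles x n_clones comparisons.
    """
    scores = _score_all_seeds(movie, clone, cfg, seed_frame, support_fraction)
    best = int(np.argmax(scores))  # argmax returns the first (lowest) index
    return best, float(scores[best])


def full_scan_comparisons(n_seed_triangles: int, n_clones: int) -> int:
    """Clonal comparisons performed by one full map evaluation."""
    return int(n_seed_triangles) * int(n_clones)


def map_score(movie: MorphoMovie, clones: list[ExperimentalClone],
              cfg: DiffusionConfig, seed_frame: int = 0) -> CloneScore:
    """Total movie score: the product of the per-clone best scores."""
    if len(clones) == 0:
        raise ParameterError("need at least one clone to score a movie")
    seeds, scores = [], []
    for clone in clones:
        s, sc = best_match(movie, clone, cfg, seed_frame)
        seeds.append(s)
        scores.append(sc)
    scores = np.asarray(scores)
    n_seeds = movie.meshes[seed_frame].n_triangles
    return CloneScore(
        best_seeds=np.asarray(seeds), best_scores=scores,
        total=float(np.prod(scores)),
        comparisons=full_scan_comparisons(n_seeds, len(clones)))


# --------------------------------------------------------------------------- #
# mixing estimation
# --------------------------------------------------------------------------- #


def mean_filter(clone: ExperimentalClone, mesh: TriMesh,
                iterations: int = 10) -> np.ndarray:
    """Estimated clone probability distribution (sums to one).

    Each iteration replaces every triangle value by the average over itself
    and its edge-adjacent neighbors, then renormalizes the distribution.
    """
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    v = np.zeros(mesh.n_triangles)
    v[clone.triangles] = 1.0
    en = edge_neighbors(mesh)
    for _ in range(iterations):
        total = v.copy()
        count = np.ones(mesh.n_triangles)
        np.add.at(total, en.tri_a, v[en.tri_b])
        np.add.at(total, en.tri_b, v[en.tri_a])
        np.add.at(count, en.tri_a, 1.0)
        np.add.at(count, en.tri_b, 1.0)
        v = total / count
        v = v / v.sum()
    return v / v.sum()


def virtual_pair_overlap(movie: MorphoMovie, seed_a: int, seed_b: int,
                         diffusion: float, seed_frame: int = 0) -> float:
    """Overlap of the final distributions of two single-triangle seeds."""
    from .fate import simulate_fate  # local import avoids a cycle

    areas = movie.meshes[-1].areas
    qs = []
    for s in (seed_a, seed_b):
        f = simulate_fate(movie, (seed_frame, s),
                          DiffusionConfig(diffusion=diffusion))[-1].values
        m = f * areas
        qs.append(m / m.sum())
    return overlap_score(qs[0], qs[1])


def calibrate_mixing(movie: MorphoMovie, seed_a: int, seed_b: int,
                     target_overlap: float, d_lo: float = 0.0,
                     d_hi: float = 2e-3, iterations: int = 12) -> float:
    """Best-fit mixing constant reproducing a target clone-pair overlap.

    The pairwise overlap grows monotonically with D (more mixing, more
    overlap), so the calibration is a bisection on the overlap-vs-D curve:
    the returned D makes the virtual pair's overlap match the experimentally
    estimated target.  Raises if the target is outside the bracket's overlap
    range.
    """
    o_lo = virtual_pair_overlap(movie, seed_a, seed_b, d_lo)
    o_hi = virtual_pair_overlap(movie, seed_a, seed_b, d_hi)
    if not o_lo <= target_overlap <= o_hi:
        raise ParameterError(
            f"target overlap {target_overlap:.3f} outside the bracket "
            f"[{o_lo:.3f}, {o_hi:.3f}]")
    for _ in range(iterations):
        mid = 0.5 * (d_lo + d_hi)
        if virtual_pair_overlap(movie, seed_a, seed_b, mid) < target_overlap:
            d_lo = mid
        else:
            d_hi = mid
    return 0.5 * (d_lo + d_hi)


def overlap_score(a: np.ndarray, b: np.ndarray) -> float:
    """Bhattacharyya overlap of two normalized clone distributions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConsistencyError("overlap_score needs fields on the same mesh")
    common = (a > 0) & (b > 0)
    return float(np.sqrt(a[common] * b[common]).sum())


# --------------------------------------------------------------------------- #
# clone shape statistics
# --------------------------------------------------------------------------- #


def clone_extents(clone: ExperimentalClone, mesh: TriMesh,
                  anisotropy_threshold: float = 1.5):
    """PD/AP extent fractions of the clone relative to the bud.

    The bud's PD extent runs from the body wall (x = 0 line, flank excluded)
    to the distal tip; its AP extent is the outline's y range.  Returns
    (pd_fraction, ap_fraction, ratio, label) with label "anisotropic" when
    the PD/AP ratio exceeds the threshold, else "isotropic".
    """
    if clone.n == 0:
        raise ParameterError("cannot measure an empty clone")
    pts = mesh.points
    body_wall = 0.0 if pts[:, 0].min() < 0 else float(pts[:, 0].min())
    limb_pd = float(pts[:, 0].max() - body_wall)
    limb_ap = float(np.ptp(pts[:, 1]))
    verts = pts[np.unique(mesh.triangles[clone.triangles])]
    pd = float(np.ptp(verts[:, 0])) / limb_pd
    ap = float(np.ptp(verts[:, 1])) / limb_ap
    ratio = pd / ap if ap > 0 else np.inf
    label = "anisotropic" if ratio > anisotropy_threshold else "isotropic"
    return pd, ap, ratio, label
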