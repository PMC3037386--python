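"""Synthetic hourly trajectories of 2D organ outlines and morphometric staging.

The limb bud is modeled in a dimensionless frame with the proximo-distal (PD)
axis along +x (distal = larger x) and the antero-posterior (AP) axis along y.
The bud protrudes from a flat "body" flank on the minimal-x side; the flank is
an artificial rectangular strip attached to the open bud curve so that the
deep internal tissue of the body can be held fixed by the deformation solver.

Stages use the morphometric notation mEdd:hh (morphometric embryonic day and
hour); hour index 0 of the default trajectory is mE9:00 and hour index 71 is
mE11:23, with "E12" conventionally aliased to the final frame.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import GeometryError, ParameterError

__all__ = [
    "Stage",
    "BoundaryShape",
    "ShapeSequence",
    "TrajectoryConfig",
    "stage_label",
    "generate_synthetic_trajectory",
    "attach_flank",
    "resample_outline",
    "shoelace_area",
    "save_sequence",
    "load_sequence",
]


# --------------------------------------------------------------------------- #
# staging
# --------------------------------------------------------------------------- #


@dataclass(frozen=True, order=True)
class Stage:
    """Morphometric stage mEdd:hh."""

    day: int
    hour: int

    def __post_init__(self):
        if not (0 <= self.hour < 24):
            raise ParameterError(f"hour must be in 0..23, got {self.hour}")

    @property
    def label(self) -> str:
        return f"mE{self.day}:{self.hour:02d}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def stage_label(hour_index: int, origin_day: int = 9) -> Stage:
    """Stage of the frame ``hour_index`` hours after mE<origin_day>:00."""
    if hour_index < 0:
        raise ParameterError(f"hour_index must be >= 0, got {hour_index}")
    return Stage(day=origin_day + hour_index // 24, hour=hour_index % 24)


# --------------------------------------------------------------------------- #
# shapes
# --------------------------------------------------------------------------- #


def shoelace_area(points: np.ndarray) -> float:
    """Signed area of a closed polygon given as an (n, 2) vertex ring."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class BoundaryShape:
    """One closed outline of the growing organ at one stage.

    ``outline`` is an (n, 2) array of vertices in counter-clockwise order with
    no repeated end point.  ``flank_span`` holds the indices of the vertices
    lying on the minimal-x (body) edge; those vertices are the ones pinned to
    zero displacement by the deformation solver.
    """

    outline: np.ndarray
    flank_span: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    stage: Stage | None = None

    def __post_init__(self):
        self.outline = np.asarray(self.outline, dtype=float)
        self.flank_span = np.asarray(self.flank_span, dtype=int)
        if self.outline.ndim != 2 or self.outline.shape[1] != 2:
            raise GeometryError("outline must be an (n, 2) array")
        if len(self.outline) < 3:
            raise GeometryError("outline needs at least 3 vertices")

    # -- geometry ---------------------------------------------------------- #

    @property
    def area(self) -> float:
        return abs(shoelace_area(self.outline))

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.outline, self.outline[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def polygon(self) -> Polygon:
        return Polygon(self.outline)

    @property
    def flank_x(self) -> float:
        return float(self.outline[:, 0].min())

    def validate(self) -> None:
        poly = self.polygon()
        if not poly.is_valid:
            raise GeometryError(f"outline is not a simple polygon: {shapely.is_valid_reason(poly)}")
        if shoelace_area(self.outline) <= 0:
            raise GeometryError("outline must be counter-clockwise with positive area")
        if self.flank_span.size:
            fx = self.outline[self.flank_span, 0]
            if np.any(np.abs(fx - self.flank_x) > 1e-7 * max(1.0, self.perimeter)):
                raise GeometryError("flank vertices must lie on the minimal-x edge")


@dataclass
class ShapeSequence:
    """Ordered hourly frames of the growing shape."""

    frames: list[BoundaryShape]

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> BoundaryShape:
        return self.frames[i]

    def validate(self) -> None:
        if len(self.frames) < 2:
            raise ParameterError("a shape sequence needs at least 2 frames")
        areas = [f.area for f in self.frames]
        for t in range(len(areas) - 1):
            if areas[t + 1] < areas[t] * (1 - 1e-9):
                raise GeometryError(f"enclosed area decreases between frames {t} and {t + 1}")
        fx = [f.flank_x for f in self.frames]
        if max(fx) - min(fx) > 1e-7:
            raise GeometryError("frames do not share the same flank baseline")


# --------------------------------------------------------------------------- #
# synthetic trajectory generator
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class TrajectoryConfig:
    """Growth parameters of the synthetic limb-like trajectory.

    Defaults emulate the published hourly window: 72 frames spanning mE9:00 to
    mE11:23, a bud of initial radius 1 (model units) on a flat flank, distal
    elongation of ~4x over the window, and a distal (autopod-like) widening
    switching on in the second half of the window.

    frames: number of hourly frames (the standard window is 72).
    bud_radius: initial bud radius; also the fixed half-width of the bud base.
    elongation_rate: PD tip advance per hour, in bud radii.
    widening_onset: hour at which the distal widening starts to ramp up.
    widening_ramp: hours over which the widening ramps from 0 to full.
    widening_strength: maximal relative AP widening of the distal paddle.
    flank_depth: depth of the artificial rectangular body flank.
    n_points: vertices per outline.
    noise: amplitude of a smooth, seed-controlled radial perturbation
        (default 0: the standard trajectory is deterministic and smooth).
    """

    frames: int = 72
    bud_radius: float = 1.0
    elongation_rate: float = 0.045
    widening_onset: float = 36.0
    widening_ramp: float = 24.0
    widening_strength: float = 0.5
    flank_depth: float = 0.5
    n_points: int = 240
    origin_day: int = 9
    noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.frames < 2:
            raise ParameterError("frames must be >= 2")
        for name in ("bud_radius", "flank_depth", "elongation_rate",
                     "widening_strength", "widening_ramp", "noise"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.bud_radius == 0:
            raise ParameterError("bud_radius must be > 0")
        if self.n_points < 32:
            raise ParameterError("n_points must be >= 32")


def _smoothstep(u: np.ndarray | float):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _bud_curve(cfg: TrajectoryConfig, t: float, rng_phase: float = 0.0) -> np.ndarray:
    """Open bud curve at hour ``t`` from (0, -r) around the tip to (0, +r).

    The profile is a stretched half-circle whose AP half-width is modulated by
    a Gaussian bump centered at ~70% of the PD extent, emulating the distal
    paddle.  The bump vanishes at the base so the flank junction is fixed.
    """
    r = cfg.bud_radius
    length = r + cfg.elongation_rate * t * r
    if cfg.widening_ramp > 0:
        w = cfg.widening_strength * float(_smoothstep((t - cfg.widening_onset) / cfg.widening_ramp))
    else:
        w = cfg.widening_strength if t >= cfg.widening_onset else 0.0

    n = cfg.n_points
    phi = np.linspace(-np.pi / 2, np.pi / 2, n)
    c = np.cos(phi)
    bump = (c**2) * np.exp(-((c - 0.7) ** 2) / (2 * 0.18**2))
    bump = bump / bump.max()
    radial = 1.0 + w * bump
    if cfg.noise > 0:
        radial = radial + cfg.noise * (c**2) * np.sin(3 * phi + rng_phase)
    x = length * c
    y = r * np.sin(phi) * radial
    return np.column_stack([x, y])


def attach_flank(curve: np.ndarray, depth: float) -> BoundaryShape:
    """Close an open bud curve with a rectangular body flank of given depth.

    The curve must run counter-clockwise from its lower to its upper end and
    both endpoints must share the same x coordinate (the body wall line).  A
    rectangle of the given depth is appended on the -x side; with depth 0 the
    curve is closed by a straight segment.
    """
    curve = np.asarray(curve, dtype=float)
    if depth < 0:
        raise ParameterError("flank depth must be >= 0")
    x0 = curve[0, 0]
    scale = max(1.0, float(np.abs(curve).max()))
    if abs(curve[-1, 0] - x0) > 1e-9 * scale:
        raise GeometryError("bud curve endpoints must share the same x coordinate")
    y_lo, y_hi = curve[0, 1], curve[-1, 1]
    if y_hi <= y_lo:
        raise GeometryError("bud curve must run from its lower to its upper endpoint")

    if depth == 0:
        ring = curve
        flank = np.array([0, len(curve) - 1], dtype=int)
    else:
        # sample the three rectangle edges at roughly the bud vertex spacing
        spacing = float(np.mean(np.hypot(*np.diff(curve, axis=0).T)))
        n_d = max(2, int(round(depth / spacing)) + 1)
        n_w = max(2, int(round((y_hi - y_lo) / spacing)) + 1)
        top = np.column_stack([np.linspace(x0, x0 - depth, n_d), np.full(n_d, y_hi)])
        left = np.column_stack([np.full(n_w, x0 - depth), np.linspace(y_hi, y_lo, n_w)])
        bottom = np.column_stack([np.linspace(x0 - depth, x0, n_d), np.full(n_d, y_lo)])
        extra = np.vstack([top[1:], left[1:], bottom[1:-1]])
        ring = np.vstack([curve, extra])
        flank = np.flatnonzero(np.abs(ring[:, 0] - (x0 - depth)) < 1e-12 * max(1.0, abs(x0 - depth) + 1))
    shape = BoundaryShape(outline=ring, flank_span=flank)
    shape.validate()
    return shape


def generate_synthetic_trajectory(cfg: TrajectoryConfig | None = None) -> ShapeSequence:
    """Generate the hourly sequence of outlines defined by ``cfg``.

    Deterministic given the config (including its seed); enclosed area is
    non-decreasing for any non-negative growth rates.
    """
    cfg = cfg or TrajectoryConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    phase = float(rng.uniform(0, 2 * math.pi))
    frames = []
    for t in range(cfg.frames):
        curve = _bud_curve(cfg, float(t), rng_phase=phase)
        shape = attach_flank(curve, cfg.flank_depth)
        shape.stage = stage_label(t, cfg.origin_day)
        frames.append(shape)
    seq = ShapeSequence(frames)
    seq.validate()
    return seq


# --------------------------------------------------------------------------- #
# resampling
# --------------------------------------------------------------------------- #


def resample_outline(shape: BoundaryShape, n: int) -> BoundaryShape:
    """Resample the closed outline to ``n`` arc-length-equidistant vertices.

    Resampling starts at vertex 0 so that a second resampling with the same n
    is (numerically) idempotent.  The flank span is re-derived from the
    minimal-x edge of the resampled ring.
    """
    if n < 8:
        raise ParameterError("resampling needs n >= 8")
    pts = shape.outline
    # iterate to the fixed point of arc-length resampling: one pass spaces
    # points equally on the OLD polygon's arc, which is not quite equal
    # spacing on the new one; a few passes make the operation idempotent
    for _ in range(4):
        ring = np.vstack([pts, pts[:1]])
        seg = np.hypot(*np.diff(ring, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        target = np.linspace(0.0, total, n, endpoint=False)
        pts = np.column_stack([np.interp(target, s, ring[:, 0]),
                               np.interp(target, s, ring[:, 1])])
    xmin = pts[:, 0].min()
    tol = 1e-7 * max(1.0, total)
    flank = np.flatnonzero(pts[:, 0] <= xmin + tol)
    out = BoundaryShape(outline=pts, flank_span=flank, stage=shape.stage)
    return out


# --------------------------------------------------------------------------- #
# file IO: per-frame CSV + JSON manifest
# --------------------------------------------------------------------------- #


def save_sequence(seq: ShapeSequence, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"frames": []}
    for i, shape in enumerate(seq.frames):
        fname = f"frame_{i:03d}.csv"
        with open(directory / fname, "w") as fh:
            fh.write("x,y\n")
            for px, py in shape.outline:
                fh.write(f"{float(px)!r},{float(py)!r}\n")
        entry = {
            "frame": i,
            "file": fname,
            "flank_span": [int(j) for j in shape.flank_span],
        }
        if shape.stage is not None:
            entry["stage"] = {"day": shape.stage.day, "hour": shape.stage.hour}
        manifest["frames"].append(entry)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return directory


def load_sequence(directory: str | Path) -> ShapeSequence:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    frames = []
    for entry in manifest["frames"]:
        pts = np.loadtxt(directory / entry["file"], delimiter=",", skiprows=1)
        stage = None
        if "stage" in entry:
            stage = Stage(day=entry["stage"]["day"], hour=entry["stage"]["hour"])
        frames.append(BoundaryShape(
            outline=pts,
            flank_span=np.asarray(entry["flank_span"], dtype=int),
            stage=stage,
        ))
    return ShapeSequence(frames)


def config_to_dict(cfg: TrajectoryConfig) -> dict:
    return dataclasses.asdict(cfg)
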