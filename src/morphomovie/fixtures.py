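"""Self-contained synthetic datasets exercising the whole pipeline.

Emulates, at configurable scale, the study layout: an hourly outline
trajectory, three boundary-control-spline sets (straight distal growth,
distal fanning-out, posterior-biased growth), three PD stiffness profiles
(their combinations span the nine canonical movement maps), simulated clone
masks with known seed triangles, and a toy two-phase expression time course.
Everything is generated deterministically from a seed; images are written as
plain-text PBM so fixture sets stay diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .boundary import ControlSpline, save_splines
from .clones import AlignmentTransform
from .fate import DiffusionConfig, simulate_fate
from .meshing import TriMesh
from .remap import MorphoMovie, build_morphomovie, config_hash, save_movie
from .springs import StiffnessProfile
from .trajectory import TrajectoryConfig, generate_synthetic_trajectory, \
    save_sequence

__all__ = [
    "default_spline_sets",
    "default_profiles",
    "render_triangles_to_mask",
    "write_pbm",
    "read_pbm",
    "fit_alignment",
    "make_fixtures",
]


def _rays(focus, angles_deg, length=9.0, name_prefix="ray"):
    out = []
    for k, ang in enumerate(angles_deg):
        a = np.radians(ang)
        tip = np.asarray(focus) + length * np.array([np.cos(a), np.sin(a)])
        out.append(ControlSpline(name=f"{name_prefix}{k}",
                                 points=np.vstack([focus, tip])))
    return out


def default_spline_sets() -> dict[str, list[ControlSpline]]:
    """Three control-spline sets spanning the plausible AP asymmetries.

    straight: rays from the bud-base center, defining straight distal growth.
    fanout: rays from a deeper focus, fanning tissue out along AP distally.
    posterior: rays from an anteriorly shifted focus, twisting growth into
        the posterior half.
    """
    angles = [-75, -45, -15, 15, 45, 75]
    return {
        "straight": _rays((0.0, 0.0), angles, name_prefix="s"),
        "fanout": _rays((-0.3, 0.0), angles, name_prefix="f"),
        "posterior": _rays((0.0, 0.4), [-85, -60, -35, -10, 15, 40],
                           name_prefix="p"),
    }


def default_profiles() -> dict[str, StiffnessProfile]:
    return {
        "inverted_sigmoid": StiffnessProfile(kind="inverted_sigmoid"),
        "constant": StiffnessProfile(kind="constant"),
        "sigmoid": StiffnessProfile(kind="sigmoid"),
    }


# --------------------------------------------------------------------------- #
# text images
# --------------------------------------------------------------------------- #


def write_pbm(mask: np.ndarray, path) -> None:
    """Plain-text (P1) portable bitmap."""
    mask = np.asarray(mask).astype(int)
    with open(path, "w") as fh:
        fh.write(f"P1\n{mask.shape[1]} {mask.shape[0]}\n")
        for row in mask:
            fh.write(" ".join(str(v) for v in row) + "\n")


def read_pbm(path) -> np.ndarray:
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "P1":
        raise ValueError("not a plain PBM (P1) file")
    w, h = int(tokens[1]), int(tokens[2])
    data = np.array(tokens[3:3 + w * h], dtype=int).reshape(h, w)
    return data.astype(bool)


def load_mask(path) -> np.ndarray:
    """Binary mask from a plain PBM or any Pillow-readable image."""
    path = Path(path)
    if path.suffix == ".pbm":
        return read_pbm(path)
    from PIL import Image
    return np.asarray(Image.open(path).convert("L")) > 127


def fit_alignment(mesh: TriMesh, size: int = 160, margin: int = 6) -> AlignmentTransform:
    """Axis-aligned similarity placing the mesh bbox inside a size x size image."""
    lo = mesh.points.min(axis=0)
    hi = mesh.points.max(axis=0)
    scale = float(max(hi - lo)) / (size - 2 * margin)
    translation = lo - margin * scale
    return AlignmentTransform(scale=scale, rotation_deg=0.0,
                              translation=tuple(translation))


def render_triangles_to_mask(mesh: TriMesh, triangle_ids: np.ndarray,
                             alignment: AlignmentTransform,
                             size: int = 160) -> np.ndarray:
    """Binary image with the given triangles filled (inverse of rasterize)."""
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros((size, size), dtype=bool)
    for t in np.asarray(triangle_ids, dtype=int):
        img = alignment.model_to_image(mesh.points[mesh.triangles[t]])
        cols = img[:, 0] - 0.5
        rows = size - img[:, 1] - 0.5
        rr, cc = draw_polygon(rows, cols, shape=mask.shape)
        mask[rr, cc] = True
    return mask


def threshold_virtual_clone(values: np.ndarray, fraction: float = 0.3) -> np.ndarray:
    """Triangle set of a simulated density: values above fraction x max."""
    return np.flatnonzero(values >= fraction * values.max())


def sample_clone_cells(values: np.ndarray, areas: np.ndarray, n_cells: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Triangle set of a stochastic clone realization.

    Draws ``n_cells`` labeled cells from the probability distribution
    proportional to density x area and returns the triangles containing at
    least one cell — the faithful emulation of an experimental clone as a
    random sample of the virtual density, tails included.
    """
    q = values * areas
    q = q / q.sum()
    counts = rng.multinomial(n_cells, q)
    return np.flatnonzero(counts)


# --------------------------------------------------------------------------- #
# the full fixture set
# --------------------------------------------------------------------------- #


def make_fixtures(out_dir, seed: int = 0, frames: int = 72,
                  edge_length: float = 0.3, n_clones: int = 6,
                  clone_diffusion: float = 1e-4, mask_size: int = 160,
                  movie_spline_set: str = "straight",
                  movie_profile: str = "sigmoid",
                  clone_window: int = 25) -> Path:
    """Write a self-contained synthetic dataset under ``out_dir``.

    Contains the outline trajectory, the three spline sets, the stiffness
    profile catalog, one built movie, simulated clone masks (with their
    generating seed triangles and seeding frame recorded) and a toy
    expression time course.  Clones are seeded ``clone_window`` hours before
    the final frame: over longer horizons the hourly re-meshing mixes the
    densities of adjacent seeds beyond exact identifiability at desk-scale
    mesh resolutions, so short-horizon clones are the regime in which the
    generating triangle can be pinned down.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    traj_cfg = TrajectoryConfig(frames=frames, seed=seed)
    seq = generate_synthetic_trajectory(traj_cfg)
    save_sequence(seq, out / "shapes")

    spline_sets = default_spline_sets()
    save_splines(spline_sets, out / "splines.json")
    profiles = default_profiles()
    with open(out / "profiles.json", "w") as fh:
        json.dump({name: {"kind": p.kind, "midpoint_frac": p.midpoint_frac,
                          "steepness_scale": p.steepness_scale,
                          "amplitude": p.amplitude}
                   for name, p in profiles.items()}, fh, indent=1)

    movie = build_morphomovie(
        seq, spline_sets[movie_spline_set], profiles[movie_profile],
        target_edge_length=edge_length,
        metadata={"spline_set": movie_spline_set, "profile": movie_profile})
    save_movie(movie, out / "movie")

    # simulated clones with known seeds, exported as aligned binary masks
    final = movie.meshes[-1]
    align = fit_alignment(final, size=mask_size)
    cfg = DiffusionConfig(diffusion=clone_diffusion)
    seed_frame = max(0, movie.n_frames - 1 - clone_window)
    n_seed = movie.meshes[seed_frame].n_triangles
    seeds = rng.choice(n_seed, size=min(n_clones, n_seed), replace=False)
    clones_dir = out / "clones"
    clones_dir.mkdir(exist_ok=True)
    truth = []
    for k, s in enumerate(sorted(int(v) for v in seeds)):
        fields = simulate_fate(movie, (seed_frame, s), cfg)
        tri = threshold_virtual_clone(fields[-1].values)
        mask = render_triangles_to_mask(final, tri, align, size=mask_size)
        write_pbm(mask, clones_dir / f"clone_{k:02d}.pbm")
        truth.append({"clone": k, "seed_triangle": s,
                      "seed_frame": int(seed_frame),
                      "n_triangles": int(len(tri))})
    with open(clones_dir / "alignment.json", "w") as fh:
        json.dump(align.to_dict(), fh, indent=1)
    with open(clones_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)

    # toy expression time course: a distal-posterior domain that jumps
    # anteriorly between the two stages (active regulation by construction)
    expr_dir = out / "expression"
    expr_dir.mkdir(exist_ok=True)
    fa = movie.n_frames * 2 // 3
    fb = min(fa + 6, movie.n_frames - 1)
    for label, f, sign in (("stage_a", fa, -1.0), ("stage_b", fb, +1.0)):
        mesh = movie.meshes[f]
        cent = mesh.centroids
        tip = mesh.points[:, 0].max()
        sel = np.flatnonzero((cent[:, 0] > 0.6 * tip) & (sign * cent[:, 1] > 0))
        al = fit_alignment(mesh, size=mask_size)
        mask = render_triangles_to_mask(mesh, sel, al, size=mask_size)
        write_pbm(mask, expr_dir / f"{label}.pbm")
        with open(expr_dir / f"{label}.json", "w") as fh:
            json.dump({"frame": int(f), "gene": "toy_distal",
                       "alignment": al.to_dict()}, fh, indent=1)

    manifest = {
        "seed": seed, "frames": frames, "edge_length": edge_length,
        "n_clones": n_clones, "clone_diffusion": clone_diffusion,
        "mask_size": mask_size, "movie_spline_set": movie_spline_set,
        "movie_profile": movie_profile, "clone_window": clone_window,
    }
    manifest["config_hash"] = config_hash(manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
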