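"""Shared fixtures: built once per session to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from morphomovie import (
    DiffusionConfig,
    ShapeSequence,
    build_morphomovie,
    generate_synthetic_trajectory,
)
from morphomovie.fixtures import default_profiles, default_spline_sets
from morphomovie.meshing import TriMesh, triangulate
from morphomovie.trajectory import TrajectoryConfig


@pytest.fixture(scope="session")
def trajectory72():
    return generate_synthetic_trajectory()


@pytest.fixture(scope="session")
def short_seq(trajectory72):
    return ShapeSequence(trajectory72.frames[:25])


@pytest.fixture(scope="session")
def splines():
    return default_spline_sets()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def movie_small(short_seq, splines, profiles):
    """25-frame movie at coarse resolution (the parameter-recovery scale)."""
    return build_morphomovie(short_seq, splines["fanout"], profiles["sigmoid"],
                             target_edge_length=0.3)


@pytest.fixture(scope="session")
def movie_distractor(short_seq, splines, profiles):
    """Same splines (hence same meshes) as movie_small, opposite PD profile."""
    return build_morphomovie(short_seq, splines["fanout"],
                             profiles["inverted_sigmoid"],
                             target_edge_length=0.3)


@pytest.fixture(scope="session")
def movie_full(trajectory72, splines, profiles):
    """Full 72-frame movie used for the conservation and progenitor suites."""
    return build_morphomovie(trajectory72, splines["straight"],
                             profiles["sigmoid"], target_edge_length=0.3)


@pytest.fixture(scope="session")
def mesh_coarse(trajectory72):
    return triangulate(trajectory72[0], 0.3)


@pytest.fixture()
def cfg_mixing():
    return DiffusionConfig(diffusion=6e-4)


def structured_strip_mesh(n_cols: int, n_rows: int = 3, h: float = 1.0) -> TriMesh:
    """Uniformly triangulated rectangular strip with boundary nodes first.

    All diagonals share one direction, so a linear displacement field is an
    exact fixed point of the stiffness-weighted neighbor average — the
    analytic spring-chain ramp oracle.
    """
    nx, ny = n_cols + 1, n_rows + 1
    idx = {}
    boundary = []
    # boundary ring, CCW from (0, 0)
    ring = (
        [(i, 0) for i in range(nx - 1)]
        + [(nx - 1, j) for j in range(ny - 1)]
        + [(i, ny - 1) for i in range(nx - 1, 0, -1)]
        + [(0, j) for j in range(ny - 1, 0, -1)]
    )
    pts = []
    for ij in ring:
        idx[ij] = len(pts)
        pts.append(ij)
    nb = len(pts)
    for j in range(1, ny - 1):
        for i in range(1, nx - 1):
            idx[(i, j)] = len(pts)
            pts.append((i, j))
    tris = []
    for j in range(n_rows):
        for i in range(n_cols):
            a, b = idx[(i, j)], idx[(i + 1, j)]
            c, d = idx[(i + 1, j + 1)], idx[(i, j + 1)]
            tris.append((a, b, c))
            tris.append((a, c, d))
    return TriMesh(points=h * np.asarray(pts, dtype=float),
                   triangles=np.asarray(tris), n_boundary=nb)


@pytest.fixture()
def strip_mesh():
    return structured_strip_mesh(8, 3)


@pytest.fixture()
def small_traj_cfg():
    return TrajectoryConfig(frames=8, n_points=120)
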