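"""Shared fixtures: synthetic geometries at test scale."""

import numpy as np
import pytest

from aorta_uq import GeometryParams, generate_aorta_surface


@pytest.fixture(scope="session")
def default_params() -> GeometryParams:
    return GeometryParams(seed=42)


@pytest.fixture(scope="session")
def default_mesh(default_params):
    return generate_aorta_surface(default_params)


@pytest.fixture(scope="session")
def coarse_params() -> GeometryParams:
    """Small, fast geometry for graph-oracle and study-loop tests."""
    return GeometryParams(seed=7,
                          n_circumferential=20,
                          desc_length=40.0,
                          branch_radii={"BCA": 4.5, "LCC": 3.5, "LSUB": 4.0},
                          branch_positions={"BCA": 50.0, "LCC": 90.0,
                                            "LSUB": 130.0})


@pytest.fixture(scope="session")
def coarse_mesh(coarse_params):
    return generate_aorta_surface(coarse_params)


def grid_patch_mesh(n: int = 9):
    """Flat triangulated unit-spacing grid in the z = 0 plane."""
    from aorta_uq import TriSurfaceMesh
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float),
                         indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    vid = np.arange(n * n).reshape(n, n)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = vid[i, j], vid[i + 1, j], vid[i + 1, j + 1], vid[i, j + 1]
            faces.append((a, b, c))
            faces.append((a, c, d))
    faces = np.asarray(faces)
    return TriSurfaceMesh(verts, faces, np.full(len(faces), "wall"))


def cylinder_mesh(radius: float = 10.0, length: float = 40.0,
                  n_circ: int = 24, n_axial: int = 20):
    """Open cylinder along z with labeled end rims (Ao at z=0, Desc at top)."""
    from aorta_uq import TriSurfaceMesh
    z = np.linspace(0.0, length, n_axial)
    phi = 2 * np.pi * np.arange(n_circ) / n_circ
    Z, PHI = np.meshgrid(z, phi, indexing="ij")
    verts = np.column_stack([radius * np.cos(PHI).ravel(),
                             radius * np.sin(PHI).ravel(), Z.ravel()])
    vid = np.arange(n_axial * n_circ).reshape(n_axial, n_circ)
    faces, labels = [], []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            jn = (j + 1) % n_circ
            a, b = vid[i, j], vid[i + 1, j]
            c, d = vid[i + 1, jn], vid[i, jn]
            faces.append((a, d, c))
            faces.append((a, c, b))
            tag = "Ao" if i == 0 else ("Desc" if i == n_axial - 2 else "wall")
            labels.extend([tag, tag])
    return TriSurfaceMesh(np.asarray(verts), np.asarray(faces),
                          np.asarray(labels),
                          rim_loops={"Ao": vid[0].copy(),
                                     "Desc": vid[-1].copy()})
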