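"""Surface smoothing: the cumulative S_L -> S_M -> S_H strategy.

The raw segmented surface is processed in three cumulative stages:

* ``S_L`` — one pass of the shape-preserving Taubin filter (w = 0.5, n = 15);
* ``S_M`` — local removal of the calcification-like artifact;
* ``S_H`` — a second global Taubin pass.

The Taubin filter alternates a positive (lambda) and a negative (mu) step of
the uniform umbrella Laplacian; with ``lambda < |mu|`` it acts as a low-pass
filter on surface detail without the volume shrinkage of plain Laplacian
smoothing.  Inlet/outlet rim vertices are always pinned so the outlet
cross-sections used for boundary-condition areas are preserved.

Artifact removal is this package's defined surrogate for the manual,
clinician-guided correction of the original workflow: boundary-fixed local
over-smoothing followed by a boundary-blended reconstruction from the
least-squares local cylinder fit of the surrounding wall.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.sparse as sp

from .mesh import TriSurfaceMesh, MeshError


class SmoothingLevel(str, Enum):
    """Cumulative smoothing levels, ordered by processing steps applied."""

    S_L = "S_L"
    S_M = "S_M"
    S_H = "S_H"


@dataclass
class TaubinConfig:
    """Taubin filter parameters.

    ``w`` is the positive step weight (the classic lambda); ``mu`` the
    negative step.  The default mu = -0.53 is the standard stable pairing for
    w = 0.5 (pass-band ~ 0.11).  ``n`` counts lambda/mu step pairs.
    """

    w: float = 0.5
    n: int = 15
    mu: float = -0.53

    def __post_init__(self) -> None:
        if not 0.0 < self.w < 1.0:
            raise ValueError("weighting factor w must lie in (0, 1)")
        if self.n < 0:
            raise ValueError("iteration count must be >= 0")
        if self.mu >= 0.0:
            raise ValueError("mu must be negative (use laplacian_smooth otherwise)")


def _umbrella_operator(mesh: TriSurfaceMesh) -> sp.csr_matrix:
    """Row-normalized vertex adjacency W; the umbrella vector is W p - p."""
    e = mesh.edges()
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    W = sp.csr_matrix((np.ones(len(i)), (i, j)),
                      shape=(mesh.n_vertices, mesh.n_vertices))
    deg = np.asarray(W.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sp.diags(1.0 / deg) @ W


def _check_manifold(mesh: TriSurfaceMesh) -> None:
    _, counts = mesh.edge_face_count()
    if np.any(counts > 2):
        raise MeshError("non-manifold input: edge shared by more than two faces")


def _movable_mask(mesh: TriSurfaceMesh, region_faces: np.ndarray | None) -> np.ndarray:
    """Vertices free to move: not on rims; inside the region with a one-ring
    transition band left fixed when a face subset is given."""
    free = np.ones(mesh.n_vertices, dtype=bool)
    rim = mesh.rim_vertices()
    free[rim] = False
    if region_faces is not None:
        region_faces = np.asarray(region_faces, dtype=np.int64)
        in_region = np.zeros(mesh.n_faces, dtype=bool)
        in_region[region_faces] = True
        region_v = np.unique(mesh.faces[in_region])
        outside_v = np.unique(mesh.faces[~in_region]) if (~in_region).any() \
            else np.array([], dtype=np.int64)
        allowed = np.zeros(mesh.n_vertices, dtype=bool)
        allowed[region_v] = True
        allowed[outside_v] = False          # fixed region boundary
        # one-ring transition band inside the region also held fixed
        e = mesh.edges()
        fixed = np.zeros(mesh.n_vertices, dtype=bool)
        fixed[outside_v] = True
        touches = fixed[e[:, 0]] | fixed[e[:, 1]]
        band = np.unique(e[touches])
        allowed[band] = False
        free &= allowed
    return free


def _iterate(mesh: TriSurfaceMesh, factors, free: np.ndarray) -> np.ndarray:
    W = _umbrella_operator(mesh)
    p = mesh.vertices.copy()
    for f in factors:
        if f == 0.0:
            continue
        p[free] += f * (W @ p - p)[free]
    return p


def taubin_smooth(mesh: TriSurfaceMesh, config: TaubinConfig | None = None,
                  region_faces: np.ndarray | None = None) -> TriSurfaceMesh:
    """Apply ``n`` lambda/mu Taubin pairs to the vertex positions.

    Connectivity is untouched; rim vertices and (when ``region_faces`` is
    given) everything outside the region plus a one-ring transition band stay
    fixed.
    """
    config = config or TaubinConfig()
    _check_manifold(mesh)
    free = _movable_mask(mesh, region_faces)
    factors = [config.w, config.mu] * config.n
    return mesh.with_vertices(_iterate(mesh, factors, free))


def laplacian_smooth(mesh: TriSurfaceMesh, w: float = 0.5, n: int = 15,
                     region_faces: np.ndarray | None = None) -> TriSurfaceMesh:
    """Plain (shrinking) Laplacian smoothing, for comparison with Taubin."""
    _check_manifold(mesh)
    free = _movable_mask(mesh, region_faces)
    return mesh.with_vertices(_iterate(mesh, [w] * n, free))


# ---------------------------------------------------------------------------
# artifact removal


def _fit_cylinder(points: np.ndarray, normals: np.ndarray):
    """Least-squares cylinder (axis point, axis direction, radius).

    The axis is the smallest-variance direction of the normal covariance
    (cylinder normals are orthogonal to the axis); the axis position is a
    linear (Kasa) circle fit of the points projected onto the orthogonal
    plane.  Deterministic and stable on near-cylindrical patches.
    """
    M = normals.T @ normals
    _, vecs = np.linalg.eigh(M)
    d = vecs[:, 0]
    # orthonormal plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = a - (a @ d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    x = points @ u
    y = points @ v
    # Kasa fit: x^2 + y^2 = 2 cx x + 2 cy y + k
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x * x + y * y, rcond=None)
    cx, cy, k = sol
    r = float(np.sqrt(max(k + cx * cx + cy * cy, 1e-30)))
    h0 = float((points @ d).mean())
    c = cx * u + cy * v + h0 * d
    return c, d, r


def _patch_connected(mesh: TriSurfaceMesh, patch: np.ndarray) -> bool:
    """Edge-connectivity of a face subset via shared vertices."""
    patch = set(int(f) for f in patch)
    if not patch:
        return True
    v2f: dict[int, list[int]] = {}
    for f in patch:
        for v in mesh.faces[f]:
            v2f.setdefault(int(v), []).append(f)
    seen = {next(iter(patch))}
    stack = [next(iter(patch))]
    while stack:
        f = stack.pop()
        for v in mesh.faces[f]:
            for g in v2f[int(v)]:
                if g not in seen:
                    seen.add(g)
                    stack.append(g)
    return seen == patch


def remove_artifact(mesh: TriSurfaceMesh,
                    artifact_faces: np.ndarray | None = None,
                    tolerance: float = 0.25,
                    oversmooth_iters: int = 60,
                    dilate: int = 1) -> TriSurfaceMesh:
    """Remove a localized wall artifact (calcification-like bump).

    The patch (dilated by ``dilate`` <= 1 face rings, so that nothing outside
    the patch and its one-ring ever moves) is referenced to a least-squares
    cylinder fitted to the surrounding wall.  The wall's smooth radial trend
    across the patch — including the arch curvature the straight cylinder
    cannot represent — is reconstructed by harmonic interpolation of the
    boundary radial deviations; the artifact is the interior *excess* over
    that trend.  If the excess is already below ``tolerance`` (mm) the mesh
    is returned unchanged; otherwise the interior is over-smoothed
    (boundary-fixed Laplacian, killing high-frequency noise) and its radial
    profile replaced by the harmonic trend.  Topology is never modified.
    """
    if artifact_faces is None:
        artifact_faces = mesh.faces_with_label("artifact_patch")
    artifact_faces = np.asarray(artifact_faces, dtype=np.int64)
    if len(artifact_faces) == 0:
        raise ValueError("artifact patch is empty")
    if not _patch_connected(mesh, artifact_faces):
        raise ValueError("artifact patch must be connected")
    if not 0 <= dilate <= 1:
        raise ValueError("dilate must be 0 or 1 (locality contract)")

    in_patch = np.zeros(mesh.n_faces, dtype=bool)
    in_patch[artifact_faces] = True
    for _ in range(dilate):
        pv = np.zeros(mesh.n_vertices, dtype=bool)
        pv[np.unique(mesh.faces[in_patch])] = True
        in_patch |= pv[mesh.faces].any(axis=1)

    patch_v = np.unique(mesh.faces[in_patch])
    rim = set(mesh.rim_vertices().tolist())
    if any(int(v) in rim for v in patch_v):
        raise ValueError("artifact patch touches an inlet/outlet rim")
    outside_v = np.unique(mesh.faces[~in_patch]) if (~in_patch).any() \
        else np.array([], dtype=np.int64)
    is_outside = np.zeros(mesh.n_vertices, dtype=bool)
    is_outside[outside_v] = True
    movable = np.zeros(mesh.n_vertices, dtype=bool)
    movable[patch_v] = True
    movable &= ~is_outside
    boundary_v = np.intersect1d(patch_v, outside_v)
    if not movable.any():
        return mesh.copy()

    # cylinder fit context: patch boundary plus its exterior one-ring
    e = mesh.edges()
    onb = np.zeros(mesh.n_vertices, dtype=bool)
    onb[boundary_v] = True
    touch = onb[e[:, 0]] | onb[e[:, 1]]
    context = np.unique(np.concatenate([boundary_v, e[touch].ravel()]))
    vn = mesh.vertex_normals()
    c, d, r_fit = _fit_cylinder(mesh.vertices[context], vn[context])

    def cyl_coords(p):
        """(axial h, unrolled circumferential w, radial deviation) about the fit."""
        rel = p - c
        h = rel @ d
        perp = rel - np.outer(h, d)
        pr = np.linalg.norm(perp, axis=1)
        return h, perp, pr

    # second-order radial trend: the straight cylinder cannot represent the
    # arch's curved wall, so the smooth trend of (radius - r_fit) is fitted
    # as a quadratic over the cylinder's parameter plane from the
    # artifact-free context ring
    h_ctx, perp_ctx, pr_ctx = cyl_coords(mesh.vertices[context])
    u_ref = perp_ctx.mean(axis=0)
    u_ref /= np.linalg.norm(u_ref)
    v_ref = np.cross(d, u_ref)

    def trend_basis(h, perp, pr):
        psi = np.arctan2(perp @ v_ref, perp @ u_ref)  # patch near psi = 0
        w = psi * r_fit
        return np.column_stack([np.ones_like(h), h, w, h * h, h * w, w * w])

    coef, *_ = np.linalg.lstsq(trend_basis(h_ctx, perp_ctx, pr_ctx),
                               pr_ctx - r_fit, rcond=None)

    patch_all = np.concatenate([np.flatnonzero(movable), boundary_v])
    h_p, perp_p, pr_p = cyl_coords(mesh.vertices[patch_all])
    trend = trend_basis(h_p, perp_p, pr_p) @ coef
    resid = (pr_p - r_fit) - trend

    # harmonic extension of the boundary residual over the patch interior
    local = {int(v): k for k, v in enumerate(patch_all)}
    n_loc = len(patch_all)
    in_set = np.zeros(mesh.n_vertices, dtype=bool)
    in_set[patch_all] = True
    pe = e[in_set[e[:, 0]] & in_set[e[:, 1]]]
    i = np.array([local[int(a)] for a in pe[:, 0]])
    j = np.array([local[int(b)] for b in pe[:, 1]])
    A = sp.csr_matrix((np.ones(2 * len(pe)),
                       (np.concatenate([i, j]), np.concatenate([j, i]))),
                      shape=(n_loc, n_loc))
    L = sp.diags(np.asarray(A.sum(axis=1)).ravel()) - A
    n_int = int(movable.sum())
    resid_hat = sp.linalg.spsolve(L[:n_int, :n_int].tocsc(),
                                  -L[:n_int, n_int:] @ resid[n_int:])

    if np.abs(resid[:n_int] - resid_hat).max() < tolerance:
        return mesh.copy()

    # over-smooth tangentially, then impose the reconstructed radial profile
    p = _iterate(mesh, [0.5] * oversmooth_iters, movable)
    mv = np.flatnonzero(movable)
    h_s, perp_s, pr_s = cyl_coords(p[mv])
    trend_s = trend_basis(h_s, perp_s, pr_s) @ coef
    radial_unit = perp_s / pr_s[:, None]
    p[mv] = c + np.outer(h_s, d) \
        + (r_fit + trend_s + resid_hat)[:, None] * radial_unit
    return mesh.with_vertices(p)


def apply_smoothing_strategy(raw: TriSurfaceMesh,
                             config: TaubinConfig | None = None,
                             tolerance: float = 0.25
                             ) -> dict[SmoothingLevel, TriSurfaceMesh]:
    """Run the cumulative smoothing chain on a raw segmented surface.

    Returns ``{S_L: taubin(raw), S_M: remove_artifact(S_L),
    S_H: taubin(S_M)}``; all outputs share the raw face table.
    """
    config = config or TaubinConfig()
    if len(raw.faces_with_label("artifact_patch")) == 0:
        raise ValueError("raw mesh carries no artifact_patch label")
    s_l = taubin_smooth(raw, config)
    s_m = remove_artifact(s_l, tolerance=tolerance)
    s_h = taubin_smooth(s_m, config)
    return {SmoothingLevel.S_L: s_l, SmoothingLevel.S_M: s_m,
            SmoothingLevel.S_H: s_h}
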