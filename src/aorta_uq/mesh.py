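"""Triangulated vascular surface meshes and cardiac phase series.

The geometric substrate of the whole pipeline is a labeled triangle surface
mesh of the aortic lumen wall: an open tube with one inlet rim (``Ao``), three
supra-aortic outlet rims (``BCA``, ``LCC``, ``LSUB``) and one descending
outlet rim (``Desc``).  Coordinates are millimetres throughout; physical
quantities (flow, pressure, shear) are SI and converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: region tags a face may carry
FACE_TAGS = ("wall", "Ao", "BCA", "LCC", "LSUB", "Desc",
             "ascending_patch", "artifact_patch")

#: rim (boundary loop) tags, inlet first
RIM_TAGS = ("Ao", "BCA", "LCC", "LSUB", "Desc")

OUTLET_TAGS = ("BCA", "LCC", "LSUB", "Desc")


class MeshError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class TriSurfaceMesh:
    """Labeled triangulated vascular surface.

    Parameters
    ----------
    vertices : (n_v, 3) float array, mm
    faces : (n_f, 3) int array of vertex indices, consistently oriented
        (outward normals).
    face_labels : (n_f,) array of region tags (see :data:`FACE_TAGS`).
    rim_loops : mapping of rim tag to an ordered array of vertex indices
        forming the boundary loop of that inlet/outlet.
    metadata : free-form dict; the synthetic generator stores the analytic
        parameterization here (centerline polyline, per-vertex radial
        directions, ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray
    rim_loops: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.face_labels = np.asarray(self.face_labels)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (n, 3)")
        if len(self.face_labels) != len(self.faces):
            raise MeshError("one label per face required")

    # -- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(n_f, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(c, axis=1)

    def face_normals(self) -> np.ndarray:
        t = self.triangles()
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        n = np.linalg.norm(c, axis=1, keepdims=True)
        return c / np.where(n == 0, 1.0, n)

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals."""
        t = self.triangles()
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # 2*area*n
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], c)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.where(norm == 0, 1.0, norm)

    # -- connectivity -----------------------------------------------------

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (n_e, 2) with v0 < v1."""
        e = np.vstack([self.faces[:, [0, 1]],
                       self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_face_count(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique undirected edges and the number of faces sharing each."""
        e = np.vstack([self.faces[:, [0, 1]],
                       self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def boundary_edges(self) -> np.ndarray:
        uniq, counts = self.edge_face_count()
        return uniq[counts == 1]

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def vertex_adjacency(self) -> "list[np.ndarray]":
        """Per-vertex neighbor index lists (umbrella stencil)."""
        e = self.edges()
        order = np.argsort(e[:, 0], kind="stable")
        nbr: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for a, b in e[order]:
            nbr[a].append(b)
            nbr[b].append(a)
        return [np.asarray(n, dtype=np.int64) for n in nbr]

    # -- labels -----------------------------------------------------------

    def faces_with_label(self, tag: str) -> np.ndarray:
        if tag not in FACE_TAGS:
            raise KeyError(f"unknown region tag {tag!r}")
        return np.flatnonzero(self.face_labels == tag)

    def wall_faces(self) -> np.ndarray:
        """Faces participating in the wall (everything that is not a rim ring)."""
        rimlike = np.isin(self.face_labels, RIM_TAGS)
        return np.flatnonzero(~rimlike)

    def rim_vertices(self) -> np.ndarray:
        """All vertices on inlet/outlet boundary loops."""
        if self.rim_loops:
            return np.unique(np.concatenate(list(self.rim_loops.values())))
        be = self.boundary_edges()
        return np.unique(be) if len(be) else np.array([], dtype=np.int64)

    def rim_area(self, tag: str) -> float:
        """Planar area (mm^2) of the polygon spanned by a rim loop."""
        loop = self.rim_loops[tag]
        pts = self.vertices[loop]
        c = pts.mean(axis=0)
        v = pts - c
        cross = np.cross(v, np.roll(v, -1, axis=0))
        return 0.5 * float(np.linalg.norm(cross.sum(axis=0)))

    def outlet_areas(self) -> dict[str, float]:
        return {tag: self.rim_area(tag) for tag in OUTLET_TAGS
                if tag in self.rim_loops}

    # -- convenience ------------------------------------------------------

    def with_vertices(self, vertices: np.ndarray) -> "TriSurfaceMesh":
        """Copy sharing faces/labels (topology) with new vertex positions."""
        return TriSurfaceMesh(np.asarray(vertices, dtype=np.float64),
                              self.faces, self.face_labels,
                              dict(self.rim_loops), dict(self.metadata))

    def copy(self) -> "TriSurfaceMesh":
        return self.with_vertices(self.vertices.copy())

    def validate(self, require_closed: bool = False) -> None:
        """Check the structural invariants; raise :class:`MeshError` on failure.

        Interior edges must be shared by exactly two faces; boundary edges
        (one face) may only lie on labeled rims.  Orientation consistency is
        checked by requiring every interior edge to be traversed once in each
        direction.
        """
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            raise MeshError("face references an invalid vertex")
        if np.any(self.face_areas() <= 0.0):
            raise MeshError("degenerate (zero-area) triangle present")
        uniq, counts = self.edge_face_count()
        if np.any(counts > 2):
            raise MeshError("non-manifold edge (shared by > 2 faces)")
        bd = uniq[counts == 1]
        if require_closed and len(bd):
            raise MeshError("mesh is not closed")
        if len(bd):
            rim = set(self.rim_vertices().tolist())
            off = [tuple(e) for e in bd if not (e[0] in rim and e[1] in rim)]
            if off:
                raise MeshError(f"boundary edges off the labeled rims: {off[:5]}")
        # orientation: directed edges of a consistently oriented surface are unique
        de = np.vstack([self.faces[:, [0, 1]],
                        self.faces[:, [1, 2]],
                        self.faces[:, [2, 0]]])
        if len(np.unique(de, axis=0)) != len(de):
            raise MeshError("inconsistent face orientation (repeated directed edge)")


def signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Signed volume of a closed oriented triangle mesh (divergence theorem).

    Positive for outward orientation.
    """
    t = np.asarray(vertices)[np.asarray(faces)]
    return float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2]))) / 6.0


@dataclass
class CardiacPhaseSeries:
    """Topology-identical wall snapshots at equally spaced cardiac times.

    ``phases[k].vertices`` gives the wall at ``phase_times[k]``; all phases
    share one face table (vertex correspondence holds), emulating ECG-gated
    reconstructions across the R-R interval.
    """

    phases: list[TriSurfaceMesh]
    phase_times: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.phase_times = np.asarray(self.phase_times, dtype=np.float64)
        if len(self.phases) != len(self.phase_times):
            raise ValueError("one time per phase required")
        if len(self.phases) >= 2:
            f0 = self.phases[0].faces
            for m in self.phases[1:]:
                if m.n_vertices != self.phases[0].n_vertices or not np.array_equal(m.faces, f0):
                    raise ValueError("phases must share vertex count and face table")
            dt = np.diff(self.phase_times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise ValueError("phase_times must be strictly increasing and equally spaced")
        if np.any(self.phase_times >= self.period):
            raise ValueError("phase_times must all be < period")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def phase_step(self) -> float:
        """Time step between consecutive phases, s."""
        return self.period / self.n_phases

    def positions(self) -> np.ndarray:
        """(n_phases, n_vertices, 3) stacked vertex positions."""
        return np.stack([m.vertices for m in self.phases])
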