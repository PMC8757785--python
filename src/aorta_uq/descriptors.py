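"""WSS descriptors: TAWSS, region statistics and unfolded maps.

TAWSS is the cycle average of the WSS magnitude,
``TAWSS = (1/T) int_0^T |WSS(t)| dt``, evaluated per face with the
trapezoidal rule.  Region statistics provide the box-plot numbers used to
compare configurations; unfolded maps project a tubular patch onto
circumferential-angle x longitudinal-arclength coordinates with a parallel-
transported reference direction fixing the angular origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .fields import SurfaceField, FieldSummary
from .mesh import TriSurfaceMesh


def tawss(wss_series: np.ndarray, times: np.ndarray,
          period: float | None = None) -> SurfaceField:
    """Time-averaged WSS magnitude per face.

    ``wss_series`` is (n_times, n_faces); ``times`` must span exactly one
    period with at least 3 samples.
    """
    wss_series = np.asarray(wss_series, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if wss_series.ndim != 2 or len(times) != len(wss_series):
        raise ValueError("need one row of per-face WSS per time sample")
    if len(times) < 3:
        raise ValueError("need at least 3 samples over the cycle")
    span = times[-1] - times[0]
    if period is not None and abs(span - period) > 1e-9 * max(1.0, period):
        raise ValueError("samples must span exactly one period")
    avg = np.trapezoid(np.abs(wss_series), times, axis=0) / span
    return SurfaceField(values=avg, association="face", units="Pa",
                        name="tawss_pa")


def extract_region(mesh: TriSurfaceMesh, field: SurfaceField | None,
                   region) -> tuple[TriSurfaceMesh, SurfaceField | None]:
    """Sub-mesh (and restricted field) of one or several region tags.

    Vertex indices are compacted; face areas are preserved exactly.
    """
    tags = [region] if isinstance(region, str) else list(region)
    sel = np.zeros(mesh.n_faces, dtype=bool)
    for tag in tags:
        idx = mesh.faces_with_label(tag)
        if len(idx) == 0:
            raise ValueError(f"no faces carry region tag {tag!r}")
        sel[idx] = True
    faces = mesh.faces[sel]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub_meta = {}
    for key, val in mesh.metadata.items():
        if isinstance(val, np.ndarray) and len(val) == mesh.n_vertices:
            sub_meta[key] = val[used]
        elif isinstance(val, np.ndarray) and len(val) == mesh.n_faces:
            sub_meta[key] = val[sel]
        else:
            sub_meta[key] = val
    sub = TriSurfaceMesh(vertices=mesh.vertices[used], faces=remap[faces],
                         face_labels=mesh.face_labels[sel], rim_loops={},
                         metadata=sub_meta)
    if field is None:
        return sub, None
    field.check_mesh(mesh)
    if field.association == "face":
        vals = field.values[sel]
    else:
        vals = field.values[used]
    return sub, SurfaceField(values=vals, association=field.association,
                             units=field.units, name=field.name)


def summarize_field(field: SurfaceField, mesh: TriSurfaceMesh) -> FieldSummary:
    """Box-plot summary: area-weighted mean, per-element order statistics,
    Tukey 1.5 IQR whiskers clamped to the data range."""
    field.check_mesh(mesh)
    v = field.values
    if v.ndim != 1:
        v = np.linalg.norm(v, axis=1)
    if len(v) == 0:
        raise ValueError("empty field")
    areas = mesh.face_areas()
    if field.association == "face":
        w = areas
    else:
        w = np.zeros(mesh.n_vertices)
        third = np.repeat(areas / 3.0, 3)
        np.add.at(w, mesh.faces.ravel(), third)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    return FieldSummary(
        min=float(v.min()), max=float(v.max()),
        mean=float(np.average(v, weights=w)),
        q1=float(q1), median=float(med), q3=float(q3),
        whisker_low=float(max(v.min(), q1 - 1.5 * iqr)),
        whisker_high=float(min(v.max(), q3 + 1.5 * iqr)),
        mean_unweighted=float(v.mean()), n_elements=int(len(v)))


# ---------------------------------------------------------------------------
# unfolded maps


@dataclass
class UnfoldedMap:
    """Field on circumferential-angle x longitudinal-arclength coordinates.

    ``samples`` holds the raw per-face triples (angle_deg, arclength_mm,
    value); ``grid`` the nearest-face resampling on the regular
    (angle x arclength) lattice.
    """

    samples: np.ndarray            # (n, 3)
    angle_deg: np.ndarray          # (n_circ,)
    arclength_mm: np.ndarray       # (n_long,)
    grid: np.ndarray               # (n_long, n_circ)

    def __post_init__(self) -> None:
        a = self.samples[:, 0]
        if np.any((a < 0) | (a >= 360.0)):
            raise ValueError("angles must lie in [0, 360)")
        if np.any(self.samples[:, 1] < -1e-9):
            raise ValueError("arclength must be non-negative")


def _transport_frames(centerline: np.ndarray, ref_direction: np.ndarray):
    """Tangents and a parallel-transported normal frame along a polyline."""
    c = np.asarray(centerline, dtype=np.float64)
    seg = np.diff(c, axis=0)
    t = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    tangents = np.vstack([t[:1], 0.5 * (t[1:] + t[:-1]), t[-1:]])
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    u = np.empty_like(c)
    u0 = np.asarray(ref_direction, dtype=np.float64)
    u0 = u0 - (u0 @ tangents[0]) * tangents[0]
    norm = np.linalg.norm(u0)
    if norm < 1e-12:
        raise ValueError("reference direction parallel to the centerline")
    u[0] = u0 / norm
    for i in range(1, len(c)):
        w = u[i - 1] - (u[i - 1] @ tangents[i]) * tangents[i]
        u[i] = w / np.linalg.norm(w)
    v = np.cross(tangents, u)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
    return tangents, u, v, s


def unfold(mesh: TriSurfaceMesh, field: SurfaceField,
           centerline: np.ndarray | None = None,
           ref_direction=(0.0, 0.0, 1.0),
           n_circ: int = 36, n_long: int = 24) -> UnfoldedMap:
    """Unfold a tubular patch into (angle, arclength) coordinates.

    Each face centroid is assigned the arclength of its nearest centerline
    point and the angle of its offset in the transported (u, v) frame; the
    map is then resampled onto a regular grid by nearest-face lookup, so
    values are relocated, never recomputed.  A patch covering less than 300
    degrees of angle is rejected as non-tubular.
    """
    field.check_mesh(mesh)
    if field.association != "face":
        raise ValueError("unfold expects a per-face field")
    if centerline is None:
        centerline = mesh.metadata.get("centerline")
        if centerline is None:
            raise ValueError("no centerline supplied and none in metadata")
    tangents, u, v, s = _transport_frames(np.asarray(centerline), ref_direction)

    cen = mesh.face_centroids()
    tree = cKDTree(np.asarray(centerline))
    _, idx = tree.query(cen)
    rel = cen - np.asarray(centerline)[idx]
    ang = np.degrees(np.arctan2(np.einsum("ij,ij->i", rel, v[idx]),
                                np.einsum("ij,ij->i", rel, u[idx])))
    ang = np.mod(ang, 360.0)
    arc = s[idx]
    arc = arc - arc.min()

    # tubularity: angular coverage of the patch
    occupied = np.unique((ang // 10).astype(int))
    if len(occupied) * 10 < 300:
        raise ValueError("patch is not tubular (angle coverage < 300 degrees)")

    samples = np.column_stack([ang, arc, field.values])
    ga = np.linspace(0.0, 360.0, n_circ, endpoint=False)
    gl = np.linspace(0.0, arc.max(), n_long)
    r_mean = np.linalg.norm(rel, axis=1).mean()
    # nearest-face lookup in an isometric embedding (circle x length)
    emb = np.column_stack([r_mean * np.cos(np.radians(ang)),
                           r_mean * np.sin(np.radians(ang)), arc])
    ftree = cKDTree(emb)
    AA, LL = np.meshgrid(ga, gl)
    q = np.column_stack([r_mean * np.cos(np.radians(AA.ravel())),
                         r_mean * np.sin(np.radians(AA.ravel())), LL.ravel()])
    _, nearest = ftree.query(q)
    grid = field.values[nearest].reshape(n_long, n_circ)
    return UnfoldedMap(samples=samples, angle_deg=ga, arclength_mm=gl,
                       grid=grid)
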