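"""Readers and writers for the exchange formats of the pipeline.

STL (binary or ASCII, via trimesh) is the geometry exchange format; since it
carries no attributes, region labels travel in a JSON sidecar keyed by face
index.  Fields and labeled meshes can also be written as ASCII VTK XML
PolyData (.vtp) with point/cell data arrays.  Waveforms are CSV with the
header ``time_s,flow_m3s``.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import trimesh

from .fields import SurfaceField
from .mesh import TriSurfaceMesh
from .waveform import FlowWaveform


# ---------------------------------------------------------------------------
# STL + labels sidecar


def write_stl(mesh: TriSurfaceMesh, path, ascii_stl: bool = False) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    path = Path(path)
    if ascii_stl:
        path.write_bytes(trimesh.exchange.stl.export_stl_ascii(tm).encode())
    else:
        path.write_bytes(trimesh.exchange.stl.export_stl(tm))


def write_labels(mesh: TriSurfaceMesh, path) -> None:
    """JSON sidecar: region tag per face index, plus the rim loops.

    Rim loops are stored as vertex coordinates, not indices: STL re-indexes
    vertices on load, so indices would not survive the round trip.
    """
    payload = {
        "face_labels": mesh.face_labels.tolist(),
        "rim_loops_xyz": {k: mesh.vertices[v].tolist()
                          for k, v in mesh.rim_loops.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_stl(path, labels_path=None) -> TriSurfaceMesh:
    """Load an STL surface, merging duplicated corner vertices.

    STL stores triangle soup; loading welds coincident vertices so the edge
    graph is usable.  Labels default to ``wall`` unless a sidecar is given.
    """
    tm = trimesh.load_mesh(str(path), process=True)
    vertices = np.asarray(tm.vertices, dtype=float)
    labels = np.full(len(tm.faces), "wall", dtype="<U16")
    rims: dict[str, np.ndarray] = {}
    if labels_path is not None:
        from scipy.spatial import cKDTree
        payload = json.loads(Path(labels_path).read_text())
        labels = np.asarray(payload["face_labels"], dtype="<U16")
        if len(labels) != len(tm.faces):
            raise ValueError("labels sidecar does not match the STL face count")
        tree = cKDTree(vertices)
        for tag, coords in payload["rim_loops_xyz"].items():
            dist, idx = tree.query(np.asarray(coords, dtype=float))
            if np.any(dist > 1e-3):
                raise ValueError(f"rim loop {tag!r} does not match the mesh")
            rims[tag] = np.asarray(idx, dtype=np.int64)
    return TriSurfaceMesh(vertices=vertices,
                          faces=np.asarray(tm.faces, dtype=np.int64),
                          face_labels=labels, rim_loops=rims)


# ---------------------------------------------------------------------------
# VTK XML PolyData (ASCII)


def write_vtp(mesh: TriSurfaceMesh, path,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None,
              include_labels: bool = True) -> None:
    """Write an ASCII .vtp with optional per-point / per-face data arrays.

    Region labels are embedded as an integer cell array ``region_id`` with
    the tag order recorded in the header comment of the array.
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    if include_labels:
        tags = sorted(set(mesh.face_labels.tolist()))
        ids = {t: i for i, t in enumerate(tags)}
        cell_data["region_id"] = np.asarray(
            [ids[t] for t in mesh.face_labels], dtype=np.int64)
        tag_comment = ",".join(tags)
    else:
        tag_comment = ""

    def arr(name, a, n_comp):
        a = np.asarray(a)
        txt = " ".join(repr(float(x)) if a.dtype.kind == "f" else str(int(x))
                       for x in a.ravel())
        dtype = "Float64" if a.dtype.kind == "f" else "Int64"
        return (f'<DataArray type="{dtype}" Name="{name}" '
                f'NumberOfComponents="{n_comp}" format="ascii">{txt}'
                f"</DataArray>")

    parts = ['<?xml version="1.0"?>',
             f"<!-- region tags: {tag_comment} -->",
             '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
             "<PolyData>",
             f'<Piece NumberOfPoints="{mesh.n_vertices}" '
             f'NumberOfPolys="{mesh.n_faces}">',
             "<Points>", arr("points", mesh.vertices, 3), "</Points>"]
    if point_data:
        parts.append("<PointData>")
        for k, v in point_data.items():
            parts.append(arr(k, v, 1 if np.asarray(v).ndim == 1 else 3))
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for k, v in cell_data.items():
            parts.append(arr(k, v, 1 if np.asarray(v).ndim == 1 else 3))
        parts.append("</CellData>")
    offsets = 3 * (np.arange(mesh.n_faces) + 1)
    parts += ["<Polys>",
              arr("connectivity", mesh.faces, 1),
              arr("offsets", offsets, 1),
              "</Polys>", "</Piece>", "</PolyData>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def read_vtp(path) -> tuple[TriSurfaceMesh, dict, dict]:
    """Read a .vtp written by :func:`write_vtp` (or any ASCII PolyData with
    triangle cells).  Returns (mesh, point_data, cell_data)."""
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")

    def parse(da):
        kind = float if da.get("type").startswith("Float") else int
        vals = np.asarray([kind(x) for x in (da.text or "").split()])
        nc = int(da.get("NumberOfComponents", "1"))
        return vals.reshape(-1, nc) if nc > 1 else vals

    pts = parse(piece.find("Points/DataArray"))
    polys = {da.get("Name"): parse(da)
             for da in piece.findall("Polys/DataArray")}
    offsets = polys["offsets"]
    if np.any(np.diff(np.concatenate([[0], offsets])) != 3):
        raise ValueError("only triangle PolyData is supported")
    faces = polys["connectivity"].reshape(-1, 3)
    pdata = {da.get("Name"): parse(da)
             for da in piece.findall("PointData/DataArray")}
    cdata = {da.get("Name"): parse(da)
             for da in piece.findall("CellData/DataArray")}
    labels = np.full(len(faces), "wall", dtype="<U16")
    mesh = TriSurfaceMesh(vertices=pts, faces=faces.astype(np.int64),
                          face_labels=labels)
    return mesh, pdata, cdata


def write_field_vtp(mesh: TriSurfaceMesh, field: SurfaceField, path) -> None:
    field.check_mesh(mesh)
    if field.association == "vertex":
        write_vtp(mesh, path, point_data={field.name: field.values})
    else:
        write_vtp(mesh, path, cell_data={field.name: field.values})


# ---------------------------------------------------------------------------
# waveform CSV


def write_waveform_csv(waveform: FlowWaveform, path) -> None:
    lines = ["time_s,flow_m3s"]
    lines += [f"{float(t)!r},{float(q)!r}"
              for t, q in zip(waveform.times, waveform.flow)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_waveform_csv(path, heart_rate_bpm: float | None = None) -> FlowWaveform:
    raw = np.loadtxt(str(path), delimiter=",", skiprows=1)
    times, flow = raw[:, 0], raw[:, 1]
    period = float(times[-1])
    hr = heart_rate_bpm if heart_rate_bpm is not None else 60.0 / period
    return FlowWaveform(times=times, flow=flow, period=period, heart_rate=hr)
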