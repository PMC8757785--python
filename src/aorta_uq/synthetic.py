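"""Synthetic aortic geometry, wall motion and inlet waveforms.

Generates an idealized thoracic aorta with the structure the downstream
pipeline expects from gated-CT segmentations: a torus-segment arch continuing
into a straight descending tube, three supra-aortic branch tubes on the arch
apex (BCA, LCC, LSUB), labeled inlet/outlet rims, a full-circumference
ascending analysis band, seeded high-frequency surface noise, and one
localized calcification-like indentation (the artifact the smoothing strategy
removes between its first and second stages).

The construction is fully parametric; with zero noise and zero bump amplitude
every main-tube vertex lies exactly on the analytic torus/cylinder surface,
which the tests exploit as ground truth.  Geometry is in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .mesh import TriSurfaceMesh, CardiacPhaseSeries, MeshError


class GeometryError(ValueError):
    """Raised for infeasible geometric parameter combinations."""


@dataclass
class GeometryParams:
    """Parameters of the idealized aortic arch.

    All lengths in mm; angles in degrees.  ``branch_positions`` are arc
    angles along the (semicircular) arch, measured from the ascending end.
    Defaults are literature-typical adult dimensions, not calibrated to any
    patient.
    """

    arch_radius: float = 30.0          # centerline radius of the arch
    lumen_radius: float = 12.5         # diastolic lumen radius
    desc_length: float = 60.0          # straight descending segment
    branch_radii: dict = field(default_factory=lambda:
                               {"BCA": 5.5, "LCC": 4.0, "LSUB": 4.5})
    branch_positions: dict = field(default_factory=lambda:
                                   {"BCA": 55.0, "LCC": 90.0, "LSUB": 125.0})
    branch_length: float = 18.0
    noise_amplitude: float = 0.2       # vertex-normal noise half-range
    bump_amplitude: float = 1.5        # inward calcification-like bump height
    bump_center_arc_deg: float = 30.0
    bump_center_circ_deg: float = 190.0
    bump_extent_s_mm: float = 7.0      # longitudinal half-extent
    bump_extent_circ_deg: float = 55.0  # circumferential half-extent
    ascending_span_arc_deg: tuple = (8.0, 52.0)
    pulsation: float = 0.1             # radial pulsation fraction of lumen radius
    n_circumferential: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("arch_radius", "lumen_radius", "desc_length",
                     "branch_length", "bump_extent_s_mm"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if any(r <= 0 for r in self.branch_radii.values()):
            raise GeometryError("branch radii must be positive")
        if not 0.0 <= self.pulsation <= 0.3:
            raise GeometryError("pulsation fraction must lie in [0, 0.3]")
        if self.n_circumferential < 12 or self.n_circumferential % 2:
            raise GeometryError("n_circumferential must be an even count >= 12")
        if self.lumen_radius >= self.arch_radius:
            raise GeometryError("lumen radius must be below arch radius")

    @property
    def arch_arc_length(self) -> float:
        return np.pi * self.arch_radius

    @property
    def total_length(self) -> float:
        return self.arch_arc_length + self.desc_length


# ---------------------------------------------------------------------------
# analytic centerline frame


def _centerline_point(params: GeometryParams, s: np.ndarray):
    """Centerline point, tangent and in-plane radial frame vector at arclength s.

    The arch is the upper semicircle of radius R in the x-z plane traversed
    from (R,0,0) to (-R,0,0); the descending segment continues straight along
    -z.  Returns (P, T, e1): e1 is the radial frame direction at circumference
    angle phi = 0 (pointing away from the arch center), e2 = +y everywhere.
    """
    s = np.atleast_1d(np.asarray(s, dtype=np.float64))
    R = params.arch_radius
    theta = np.minimum(s / R, np.pi)
    on_arch = s <= params.arch_arc_length + 1e-12
    P = np.empty((len(s), 3))
    T = np.empty_like(P)
    e1 = np.empty_like(P)
    ct, st = np.cos(theta), np.sin(theta)
    P[:, 0] = R * ct
    P[:, 1] = 0.0
    P[:, 2] = R * st
    T[:, 0], T[:, 1], T[:, 2] = -st, 0.0, ct
    e1[:, 0], e1[:, 1], e1[:, 2] = ct, 0.0, st
    over = ~on_arch
    if np.any(over):
        d = s[over] - params.arch_arc_length
        P[over, 0], P[over, 1], P[over, 2] = -R, 0.0, -d
        T[over] = (0.0, 0.0, -1.0)
        e1[over] = (-1.0, 0.0, 0.0)
    return P, T, e1


def _surface_point(params: GeometryParams, s, phi):
    """Analytic tube surface point at (arclength, circumferential angle)."""
    P, _, e1 = _centerline_point(params, np.asarray(s, dtype=float).ravel())
    phi = np.asarray(phi, dtype=float).ravel()
    e2 = np.array([0.0, 1.0, 0.0])
    rhat = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
    return P + params.lumen_radius * rhat, rhat


def centerline_polyline(params: GeometryParams, n: int = 400):
    """Densely sampled centerline as (points, arclengths)."""
    s = np.linspace(0.0, params.total_length, n)
    P, _, _ = _centerline_point(params, s)
    return P, s


def centerline_curvature(params: GeometryParams, s) -> np.ndarray:
    """Centerline curvature (1/mm): 1/R on the arch, 0 on the straight segment."""
    s = np.asarray(s, dtype=float)
    return np.where(s <= params.arch_arc_length, 1.0 / params.arch_radius, 0.0)


# ---------------------------------------------------------------------------
# bump profile


def _bump_weight(params: GeometryParams, s, phi) -> np.ndarray:
    """Compactly supported C1 bump profile in (arclength, angle) coordinates."""
    s = np.asarray(s, dtype=float)
    phi = np.asarray(phi, dtype=float)
    s_c = np.deg2rad(params.bump_center_arc_deg) * params.arch_radius
    phi_c = np.deg2rad(params.bump_center_circ_deg)
    dphi = np.angle(np.exp(1j * (phi - phi_c)))
    h_s = params.bump_extent_s_mm
    h_c = np.deg2rad(params.bump_extent_circ_deg) * params.lumen_radius
    rho2 = ((s - s_c) / h_s) ** 2 + (dphi * params.lumen_radius / h_c) ** 2
    w = np.clip(1.0 - rho2, 0.0, None) ** 2
    return w


# ---------------------------------------------------------------------------
# mesh assembly


def generate_aorta_surface(params: GeometryParams) -> TriSurfaceMesh:
    """Generate the labeled synthetic aortic surface.

    The main tube is a structured (ring x circumference) grid; each branch is
    attached by removing a rectangular patch of grid quads at the arch apex
    and lofting a tube from the hole perimeter to a circular outlet rim, so
    the result is edge-manifold with exactly five boundary loops (Euler
    characteristic V - E + F = -3).

    Raises
    ------
    GeometryError
        if branch openings would overlap or not fit on the grid
        (self-intersecting placement).
    """
    rng = np.random.default_rng(params.seed)
    R, r = params.arch_radius, params.lumen_radius
    n_phi = params.n_circumferential
    ds_target = 2.0 * np.pi * r / n_phi
    n_rings = int(round(params.total_length / ds_target)) + 1
    s_rings = np.linspace(0.0, params.total_length, n_rings)
    ds = s_rings[1] - s_rings[0]
    dphi = 2.0 * np.pi / n_phi
    phi_cols = dphi * np.arange(n_phi)

    # --- main tube vertices -------------------------------------------------
    S, PHI = np.meshgrid(s_rings, phi_cols, indexing="ij")
    pts, rhat = _surface_point(params, S.ravel(), PHI.ravel())
    vid = np.arange(n_rings * n_phi).reshape(n_rings, n_phi)

    # --- branch holes -------------------------------------------------------
    holes = {}
    for tag, theta_deg in params.branch_positions.items():
        rb = params.branch_radii[tag]
        s_b = np.deg2rad(theta_deg) * R
        i_c = int(round(s_b / ds))
        ks = max(2, int(np.ceil(rb / ds)))
        kx = max(2, int(np.ceil(rb / (r * dphi))))
        if kx >= n_phi // 4:
            raise GeometryError(f"branch {tag} too wide for the grid")
        if i_c - ks < 2 or i_c + ks > int(params.arch_arc_length / ds) - 2:
            raise GeometryError(f"branch {tag} does not fit on the arch")
        holes[tag] = (i_c, ks, kx, rb, s_b)
    order = sorted(holes.items(), key=lambda kv: kv[1][0])
    for (ta, a), (tb, b) in zip(order, order[1:]):
        if a[0] + a[1] >= b[0] - b[1]:
            raise GeometryError(
                f"branches {ta} and {tb} overlap (self-intersecting placement)")

    in_hole = np.zeros((n_rings - 1, n_phi), dtype=bool)  # quad (i, j)
    for i_c, ks, kx, _, _ in holes.values():
        cols = np.arange(-kx, kx) % n_phi
        in_hole[np.ix_(np.arange(i_c - ks, i_c + ks), cols)] = True

    # --- main tube faces ----------------------------------------------------
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_phi):
            if in_hole[i, j]:
                continue
            jn = (j + 1) % n_phi
            A, B = vid[i, j], vid[i + 1, j]
            C, D = vid[i + 1, jn], vid[i, jn]
            faces.append((A, D, C))
            faces.append((A, C, B))
    n_main_faces = len(faces)
    directed = {(a, b) for a, b, _ in faces} | {(b, c) for _, b, c in faces} \
        | {(c, a) for a, _, c in faces}

    vertices = [pts]
    v_s = [S.ravel()]
    v_phi = [PHI.ravel()]
    v_branch = [np.full(n_rings * n_phi, "", dtype="<U8")]
    next_id = n_rings * n_phi
    rim_loops: dict[str, np.ndarray] = {"Ao": vid[0].copy(), "Desc": vid[-1].copy()}
    branch_face_tag = []
    branch_axis_info = {}

    # --- branch tubes -------------------------------------------------------
    e2 = np.array([0.0, 1.0, 0.0])
    for tag, (i_c, ks, kx, rb, s_b) in holes.items():
        # ordered hole perimeter (ring index, column offset)
        per = []
        for d in range(-kx, kx):
            per.append((i_c - ks, d))
        for i in range(i_c - ks, i_c + ks):
            per.append((i, kx))
        for d in range(kx, -kx, -1):
            per.append((i_c + ks, d))
        for i in range(i_c + ks, i_c - ks, -1):
            per.append((i, -kx))
        loop = np.array([vid[i, d % n_phi] for i, d in per])
        nb = len(loop)

        Pc, Tc, e1c = _centerline_point(params, np.array([s_b]))
        axis = e1c[0]
        c_base = Pc[0] + r * axis
        u, v = Tc[0], np.cross(axis, Tc[0])
        base_pts = pts[loop]  # perimeter vertices live on the main-tube grid
        rel = base_pts - c_base
        psi = np.arctan2(rel @ v, rel @ u)
        top = (c_base + params.branch_length * axis
               + rb * (np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * v))
        m = max(4, int(round(params.branch_length / ds)))
        rings = [loop]
        for k in range(1, m + 1):
            t = k / m
            newp = (1.0 - t) * base_pts + t * top
            ids = np.arange(next_id, next_id + nb)
            next_id += nb
            vertices.append(newp)
            v_s.append(np.full(nb, np.nan))
            v_phi.append(np.full(nb, np.nan))
            v_branch.append(np.full(nb, tag, dtype="<U8"))
            rings.append(ids)
        rim_loops[tag] = rings[-1]
        branch_axis_info[tag] = {"axis": axis, "base": c_base,
                                 "length": params.branch_length, "radius": rb}

        # base edge direction used by the main tube decides branch winding
        reverse = (int(loop[0]), int(loop[1])) in directed
        for k in range(m):
            lo, hi = rings[k], rings[k + 1]
            for l in range(nb):
                ln = (l + 1) % nb
                A, B, C, D = lo[l], lo[ln], hi[ln], hi[l]
                if reverse:
                    faces.append((B, A, D))
                    faces.append((B, D, C))
                else:
                    faces.append((A, B, C))
                    faces.append((A, C, D))
                branch_face_tag.extend([tag, tag])

    vertices = np.vstack(vertices)
    faces = np.asarray(faces, dtype=np.int64)
    v_s = np.concatenate(v_s)
    v_phi = np.concatenate(v_phi)
    v_branch = np.concatenate(v_branch)

    # drop the unreferenced vertices left inside the carved branch holes
    used = np.zeros(len(vertices), dtype=bool)
    used[faces] = True
    remap = np.cumsum(used) - 1
    vertices, v_s, v_phi, v_branch = (a[used] for a in
                                      (vertices, v_s, v_phi, v_branch))
    faces = remap[faces]
    rim_loops = {k: remap[v] for k, v in rim_loops.items()}

    # --- per-vertex frame (foot point on the local centerline, radial dir) --
    v_foot = np.empty_like(vertices)
    main = v_branch == ""
    Pm, _, _ = _centerline_point(params, v_s[main])
    v_foot[main] = Pm
    for tag, info in branch_axis_info.items():
        sel = v_branch == tag
        rel = vertices[sel] - info["base"]
        h = rel @ info["axis"]
        v_foot[sel] = info["base"] + h[:, None] * info["axis"]
    v_rdir = vertices - v_foot
    v_radius = np.linalg.norm(v_rdir, axis=1)
    v_rdir = v_rdir / v_radius[:, None]

    # --- bump (inward, calcification-like) and seeded noise ------------------
    w_bump = np.zeros(len(vertices))
    w_bump[main] = _bump_weight(params, v_s[main], v_phi[main])
    vertices = vertices - (params.bump_amplitude * w_bump)[:, None] * v_rdir

    rim_set = np.zeros(len(vertices), dtype=bool)
    for lp in rim_loops.values():
        rim_set[lp] = True
    noise = rng.uniform(-params.noise_amplitude, params.noise_amplitude,
                        size=len(vertices))
    noise[rim_set] = 0.0
    vertices = vertices + noise[:, None] * v_rdir

    # --- face labels --------------------------------------------------------
    n_faces = len(faces)
    labels = np.full(n_faces, "wall", dtype="<U16")
    labels[n_main_faces:] = "wall"
    # rim face rings
    ring_of_face = np.full(n_faces, -1)
    fidx = 0
    for i in range(n_rings - 1):
        for j in range(n_phi):
            if in_hole[i, j]:
                continue
            ring_of_face[fidx:fidx + 2] = i
            fidx += 2
    labels[(ring_of_face == 0)] = "Ao"
    labels[(ring_of_face == n_rings - 2)] = "Desc"
    # ascending band and artifact patch from face-centroid parameters
    f_s = np.full(n_faces, np.nan)
    f_phi = np.full(n_faces, np.nan)
    fv_s = v_s[faces]
    fv_phi = v_phi[faces]
    main_face = ~np.isnan(fv_s).any(axis=1)
    f_s[main_face] = fv_s[main_face].mean(axis=1)
    # average angles on the unit circle to respect wrap-around
    z = np.exp(1j * fv_phi[main_face]).mean(axis=1)
    f_phi[main_face] = np.mod(np.angle(z), 2.0 * np.pi)
    lo, hi = (np.deg2rad(a) * R for a in params.ascending_span_arc_deg)
    asc = main_face & (f_s >= lo) & (f_s <= hi) & (ring_of_face > 0) \
        & (ring_of_face < n_rings - 2)
    labels[asc] = "ascending_patch"
    # every face materially displaced by the artifact (> 2% of its height)
    art = main_face & (_bump_weight(params, f_s, f_phi) > 0.02)
    labels[art] = "artifact_patch"
    # branch rim rings
    fb = np.full(n_faces, "", dtype="<U8")
    fb[n_main_faces:] = np.asarray(branch_face_tag, dtype="<U8")
    for tag, info in branch_axis_info.items():
        sel = np.flatnonzero(fb == tag)
        # outlet ring = the last loft row of quads, next to the branch rim
        cen = vertices[faces[sel]].mean(axis=1)
        h = (cen - info["base"]) @ info["axis"]
        m = max(4, int(round(info["length"] / ds)))
        labels[sel[h > info["length"] * (m - 1.01) / m]] = tag

    # face -> flow-branch assignment for the hemodynamic surrogate
    face_branch = np.full(n_faces, "Desc", dtype="<U8")
    face_branch[n_main_faces:] = np.asarray(branch_face_tag, dtype="<U8")
    s_split = max(info[4] for info in holes.values())  # past the last branch
    face_branch[main_face & (f_s <= s_split)] = "trunk"

    cl_pts, cl_s = centerline_polyline(params)
    mesh = TriSurfaceMesh(
        vertices=vertices, faces=faces, face_labels=labels,
        rim_loops=rim_loops,
        metadata={
            "params": asdict(params),
            "v_s": v_s, "v_phi": v_phi, "v_branch": v_branch,
            "v_foot": v_foot, "v_rdir": v_rdir,
            "v_radius": np.linalg.norm(vertices - v_foot, axis=1),
            "f_s": f_s, "f_phi": f_phi, "face_branch": face_branch,
            "centerline": cl_pts, "centerline_s": cl_s,
            "arch_arc_length": params.arch_arc_length,
            "lumen_radius": r,
        })
    mesh.validate()
    return mesh


def main_tube_surface_error(mesh: TriSurfaceMesh, params: GeometryParams) -> np.ndarray:
    """Distance (mm) of each main-tube vertex from the analytic surface.

    Measures ``| |p - foot| - lumen_radius |`` against the noise-free,
    bump-free torus/cylinder; used as the ground-truth geometric residual.
    """
    v_s = mesh.metadata["v_s"]
    main = mesh.metadata["v_branch"] == ""
    P, _, _ = _centerline_point(params, v_s[main])
    rad = np.linalg.norm(mesh.vertices[main] - P, axis=1)
    return np.abs(rad - params.lumen_radius)


# ---------------------------------------------------------------------------
# wall motion phases


def systolic_shape(t, period: float, peak_time: float) -> np.ndarray:
    """Smooth systolic modulation: 0 at cycle start/end, 1 at ``peak_time``.

    Piecewise raised cosine with zero slope at 0, the peak, and the period,
    mimicking systolic distension of the aortic wall.
    """
    t = np.mod(np.asarray(t, dtype=np.float64), period)
    up = 0.5 * (1.0 - np.cos(np.pi * t / peak_time))
    down = 0.5 * (1.0 + np.cos(np.pi * (t - peak_time) / (period - peak_time)))
    return np.where(t <= peak_time, up, down)


def generate_phase_series(base: TriSurfaceMesh, n_phases: int = 10,
                          heart_rate_bpm: float = 77.0,
                          pulsation: float | None = None,
                          peak_phase_index: int = 4) -> CardiacPhaseSeries:
    """Displace the wall radially to emulate gated phases over one R-R interval.

    Every vertex moves along its stored radial direction by
    ``lumen_radius * pulsation * s(t)`` where ``s`` is :func:`systolic_shape`
    peaking at phase ``peak_phase_index`` (the systolic phase, p4 of 10 by
    default).  Topology is shared across phases.
    """
    if n_phases < 2:
        raise ValueError("need at least 2 phases")
    if "v_rdir" not in base.metadata:
        raise ValueError("base mesh lacks the radial frame metadata "
                         "(generate it with generate_aorta_surface)")
    if pulsation is None:
        pulsation = base.metadata["params"]["pulsation"]
    lumen_radius = base.metadata["lumen_radius"]
    amp = lumen_radius * pulsation
    if amp >= base.metadata["v_radius"].min():
        raise GeometryError("pulsation would collapse the smallest local radius")
    period = 60.0 / heart_rate_bpm
    times = period * np.arange(n_phases) / n_phases
    peak_t = period * peak_phase_index / n_phases
    rdir = base.metadata["v_rdir"]
    phases = []
    for t in times:
        disp = amp * systolic_shape(t, period, peak_t)
        phases.append(base.with_vertices(base.vertices + disp * rdir))
    return CardiacPhaseSeries(phases=phases, phase_times=times, period=period)
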