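"""TAWSS quadrature, region statistics and unfolded maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aorta_uq import (SurfaceField, extract_region, summarize_field, tawss,
                      unfold)

from conftest import cylinder_mesh


class TestTawss:
    def test_constant_field_identity(self):
        t = np.linspace(0.0, 0.8, 41)
        series = np.full((41, 10), 3.7)
        out = tawss(series, t, period=0.8)
        assert np.all(out.values == pytest.approx(3.7, rel=1e-14))

    def test_abs_sine_average_two_over_pi(self):
        T = 0.779
        t = np.linspace(0.0, T, 1000)
        series = np.abs(np.sin(2 * np.pi * t / T))[:, None]
        out = tawss(series, t, period=T)
        assert out.values[0] == pytest.approx(2.0 / np.pi, abs=1e-3)

    def test_matches_rectangle_rule_oracle(self):
        """Trapezoid vs an independently coded midpoint rule: both converge,
        difference is O(dt^2)."""
        T = 1.0

        def f(t):
            # smooth but non-periodic: composite-rule errors are O(dt^2)
            return np.exp(2.0 * t / T) + 0.3 * np.sin(3.0 * np.pi * t / T)

        diffs = []
        for n in (51, 101, 201):
            t = np.linspace(0.0, T, n)
            trap = tawss(np.abs(f(t))[:, None], t, period=T).values[0]
            tm = 0.5 * (t[1:] + t[:-1])
            mid = np.sum(np.abs(f(tm)) * np.diff(t)) / T
            diffs.append(abs(trap - mid))
        assert diffs[0] / diffs[1] == pytest.approx(4.0, rel=0.2)
        assert diffs[1] / diffs[2] == pytest.approx(4.0, rel=0.2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(alpha=st.floats(0.1, 50.0))
    def test_homogeneity_and_max_bound(self, alpha):
        t = np.linspace(0.0, 0.8, 60)
        rng = np.random.default_rng(11)
        series = rng.uniform(0, 5, (60, 7))
        base = tawss(series, t, period=0.8).values
        scaled = tawss(alpha * series, t, period=0.8).values
        assert np.allclose(scaled, alpha * base, rtol=1e-12)
        assert np.all(base <= series.max(axis=0) + 1e-12)

    def test_bad_inputs(self):
        t = np.linspace(0, 0.8, 10)
        with pytest.raises(ValueError, match="one row"):
            tawss(np.zeros((9, 4)), t)
        with pytest.raises(ValueError, match="period"):
            tawss(np.zeros((10, 4)), t, period=1.0)
        with pytest.raises(ValueError, match="3 samples"):
            tawss(np.zeros((2, 4)), t[:2])


class TestExtractRegion:
    def test_whole_wall_identity(self, default_mesh):
        field = SurfaceField(np.arange(default_mesh.n_faces, dtype=float),
                             "face")
        tags = sorted(set(default_mesh.face_labels.tolist()))
        sub, fsub = extract_region(default_mesh, field, tags)
        assert sub.n_faces == default_mesh.n_faces
        assert sub.face_areas().sum() == pytest.approx(
            default_mesh.face_areas().sum(), rel=1e-12)
        assert np.array_equal(np.sort(fsub.values), field.values)

    def test_partition_conserves_area(self, default_mesh):
        total = 0.0
        for tag in sorted(set(default_mesh.face_labels.tolist())):
            sub, _ = extract_region(default_mesh, None, tag)
            total += sub.face_areas().sum()
        assert total == pytest.approx(default_mesh.face_areas().sum(),
                                      rel=1e-12)

    def test_ascending_band_area_matches_analytic(self):
        """The full-circumference ascending band on a noiseless torus has
        area 2 pi r R dtheta (strip between its bounding mesh rings)."""
        from aorta_uq import GeometryParams, generate_aorta_surface
        params = GeometryParams(seed=0, noise_amplitude=0.0,
                                bump_amplitude=0.0,
                                ascending_span_arc_deg=(8.0, 40.0),
                                bump_center_arc_deg=70.0)  # artifact elsewhere
        mesh = generate_aorta_surface(params)
        sub, _ = extract_region(mesh, None, "ascending_patch")
        sel = mesh.face_labels == "ascending_patch"
        # analytic torus strip area per full ring of faces is 2 pi r R dtheta;
        # the band holds n_faces / (2 n_circ) such rings
        rings = np.unique(mesh.metadata["v_s"][mesh.metadata["v_branch"] == ""])
        ds = float(np.diff(rings).mean())
        n_rings_covered = sel.sum() / (2.0 * params.n_circumferential)
        expected = n_rings_covered * 2 * np.pi * params.lumen_radius * ds
        assert sub.face_areas().sum() == pytest.approx(expected, rel=0.02)

    def test_unknown_tag_rejected(self, default_mesh):
        with pytest.raises(KeyError):
            extract_region(default_mesh, None, "no_such_region")


class TestSummarize:
    def test_uniform_field(self, coarse_mesh):
        f = SurfaceField(np.full(coarse_mesh.n_faces, 2.5), "face")
        s = summarize_field(f, coarse_mesh)
        assert s.min == s.max == 2.5
        assert s.mean == pytest.approx(2.5, rel=1e-12)
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max

    def test_area_weighted_mean_hand_case(self):
        """Two faces, areas 1 and 3, values 0 and 4: weighted mean 3."""
        from aorta_uq import TriSurfaceMesh
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [1, 2, 0],
                          [0, 8, 0]], dtype=float)
        faces = np.array([[0, 1, 2], [1, 4, 2]])  # areas 1 and 3
        mesh = TriSurfaceMesh(verts, faces, np.array(["wall", "wall"]))
        assert mesh.face_areas() == pytest.approx([1.0, 3.0])
        s = summarize_field(SurfaceField(np.array([0.0, 4.0]), "face"), mesh)
        assert s.mean == pytest.approx(3.0)
        assert s.mean_unweighted == pytest.approx(2.0)

    def test_permutation_invariance_and_linearity(self, coarse_mesh):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 10, coarse_mesh.n_faces)
        s1 = summarize_field(SurfaceField(vals, "face"), coarse_mesh)
        s3 = summarize_field(SurfaceField(3.0 * vals, "face"), coarse_mesh)
        for key in ("min", "max", "q1", "median", "q3"):
            assert getattr(s3, key) == pytest.approx(3 * getattr(s1, key))

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            SurfaceField(np.array([1.0, np.nan]), "face")


class TestUnfold:
    @staticmethod
    def _cylinder_and_centerline(field_kind):
        mesh = cylinder_mesh(radius=8.0, length=40.0, n_circ=36, n_axial=30)
        cen = mesh.face_centroids()
        angle = np.arctan2(cen[:, 1], cen[:, 0])
        # cos(angle) avoids the 0/360 wrap in the assertion arithmetic
        values = np.cos(angle) if field_kind == "angle" else cen[:, 2]
        field = SurfaceField(values, "face")
        centerline = np.column_stack([np.zeros(50), np.zeros(50),
                                      np.linspace(0, 40.0, 50)])
        return mesh, field, centerline

    def test_angular_field_tracks_map_angle(self):
        mesh, field, cl = self._cylinder_and_centerline("angle")
        um = unfold(mesh, field, centerline=cl, ref_direction=(1, 0, 0))
        # along the tube each column stays within one triangle of angular
        # quantization (the two triangles of a quad sit at different angles)
        quant = np.sin(np.radians(10.0))
        assert um.grid.std(axis=0).max() <= quant
        assert np.abs(um.grid[0] - np.cos(np.radians(um.angle_deg))).max() \
            <= quant + 1e-9

    def test_axial_field_constant_in_angle(self):
        mesh, field, cl = self._cylinder_and_centerline("axial")
        um = unfold(mesh, field, centerline=cl, ref_direction=(1, 0, 0))
        dz = 40.0 / 29  # ring spacing: triangle centroids sit dz/3 apart
        assert um.grid.std(axis=1).max() <= dz / 2
        row_means = um.grid.mean(axis=1)
        assert np.all(np.diff(row_means) >= -1e-9)

    def test_values_relocated_never_recomputed(self):
        mesh, field, cl = self._cylinder_and_centerline("angle")
        um = unfold(mesh, field, centerline=cl, ref_direction=(1, 0, 0))
        assert np.isin(um.grid.ravel(), field.values).all()

    def test_arch_inner_band_holds_row_maxima(self, default_mesh):
        """With the curvature-enhanced WSS surrogate, every longitudinal row
        of the unfolded ascending map peaks near the inner-curvature angle."""
        from aorta_uq import (OverallCirculation, allocate_outlet_params,
                              Branch, BranchNetwork, generate_inlet_waveform,
                              solve_flow_split, wall_wss_field)
        wf = generate_inlet_waveform(4.5, 77.0)
        areas = default_mesh.outlet_areas()
        outlets = allocate_outlet_params(OverallCirculation(
            1.65e7, 1.49e8, 1e-8, outlet_areas=areas))
        net = BranchNetwork([Branch(t, 18.0, float(np.sqrt(a / np.pi)))
                             for t, a in areas.items()])
        sol = solve_flow_split(net, outlets, wf, wf.period / 200)
        field = wall_wss_field(sol, default_mesh, wf.peak_time())
        sub, fsub = extract_region(default_mesh, field,
                                   ("ascending_patch", "artifact_patch"))
        cl = default_mesh.metadata["centerline"]
        cls = default_mesh.metadata["centerline_s"]
        f_s = sub.metadata["f_s"]
        clsub = cl[(cls >= f_s.min()) & (cls <= f_s.max())]
        um = unfold(sub, fsub, centerline=clsub, ref_direction=(0, 1, 0))
        # inner curvature faces point toward the arch center: for the arch in
        # the x-z plane with outward frame e1, that is angle ~180 deg in the
        # (u=y, v) frame... locate the peak column per row instead:
        peak_cols = um.angle_deg[np.argmax(um.grid, axis=1)]
        spread = np.ptp(np.mod(peak_cols - peak_cols[0] + 180, 360) - 180)
        assert spread <= 60.0

    def test_non_tubular_patch_rejected(self, default_mesh):
        """A narrow angular sliver cannot be unfolded."""
        md = default_mesh.metadata
        sel = np.flatnonzero(
            (np.nan_to_num(md["f_phi"], nan=99.0) < 0.6)
            & (md["face_branch"] == "trunk"))
        sliver = default_mesh.copy()
        labels = sliver.face_labels.copy()
        labels[sel] = "ascending_patch"
        labels[np.setdiff1d(np.arange(default_mesh.n_faces), sel)] = "wall"
        sliver.face_labels = labels
        sub, fsub = extract_region(
            sliver, SurfaceField(np.ones(default_mesh.n_faces), "face"),
            "ascending_patch")
        with pytest.raises(ValueError, match="tubular"):
            unfold(sub, fsub, centerline=md["centerline"],
                   ref_direction=(0, 1, 0))
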