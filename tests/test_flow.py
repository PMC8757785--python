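"""Resistance-network flow surrogate and Poiseuille wall shear stress."""

import numpy as np
import pytest

from aorta_uq import (Branch, BranchNetwork, FlowWaveform, WindkesselParams,
                      branch_wss, compute_reynolds, generate_inlet_waveform,
                      generate_phase_series, solve_flow_split, wall_wss_field,
                      OverallCirculation, allocate_outlet_params)


def constant_waveform(q0, period=0.8, n=200):
    t = np.linspace(0.0, period, n)
    return FlowWaveform(times=t, flow=np.full(n, q0), period=period,
                        heart_rate=60.0 / period)


WK = dict(Rp=2e7, Rd=2e8, C=5e-9)


class TestFlowSplit:
    def test_symmetric_branches_split_evenly(self):
        wf = generate_inlet_waveform(4.5, 77.0)
        net = BranchNetwork([Branch("L", 50.0, 5.0), Branch("R", 50.0, 5.0)])
        outlets = {t: WindkesselParams(**WK) for t in ("L", "R")}
        sol = solve_flow_split(net, outlets, wf, wf.period / 200)
        assert np.array_equal(sol.q_branch["L"], sol.q_branch["R"])

    def test_steady_nodal_balance(self):
        q0 = 8e-5
        wf = constant_waveform(q0)
        net = BranchNetwork([Branch("A", 60.0, 6.0), Branch("B", 40.0, 4.0)])
        outlets = {t: WindkesselParams(**WK) for t in ("A", "B")}
        sol = solve_flow_split(net, outlets, wf, dt=2e-3, n_cycles=40)
        res = net.resistances()
        for tag in ("A", "B"):
            qi = sol.q_branch[tag][-1]
            drop = sol.p_junction[-1] - sol.p_outlet[tag][-1]
            assert drop == pytest.approx(qi * res[tag], rel=1e-6)
        assert sol.q_branch["A"][-1] + sol.q_branch["B"][-1] == \
            pytest.approx(q0, rel=1e-12)

    def test_mass_conservation_every_step(self):
        wf = generate_inlet_waveform(4.5, 77.0)
        net = BranchNetwork([Branch("BCA", 18.0, 5.5), Branch("LCC", 18.0, 4.0),
                             Branch("LSUB", 18.0, 4.5), Branch("Desc", 60.0, 12.5)])
        outlets = {t: WindkesselParams(**WK) for t in net.tags()}
        sol = solve_flow_split(net, outlets, wf, wf.period / 250)
        scale = np.abs(sol.q_inlet).max()
        assert np.abs(sol.mass_residual()).max() < 1e-10 * scale

    def test_area_proportional_steady_split(self):
        """With area-allocated Windkessel outlets and equal Poiseuille
        resistances, the steady flow split follows the outlet areas."""
        areas = {"big": 200.0, "small": 100.0}
        overall = OverallCirculation(Rp_bar=1.65e7, Rd_bar=1.49e8, C_bar=1e-8,
                                     outlet_areas=areas)
        outlets = allocate_outlet_params(overall)
        # identical, negligible branch resistances
        net = BranchNetwork([Branch("big", 1.0, 20.0), Branch("small", 1.0, 20.0)])
        wf = constant_waveform(9e-5)
        sol = solve_flow_split(net, outlets, wf, dt=2e-3, n_cycles=60)
        ratio = sol.q_branch["big"][-1] / sol.q_branch["small"][-1]
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_mismatched_outlets_rejected(self):
        wf = constant_waveform(1e-4)
        net = BranchNetwork([Branch("A", 10.0, 5.0)])
        with pytest.raises(ValueError, match="match"):
            solve_flow_split(net, {"B": WindkesselParams(**WK)}, wf, 2e-3)


class TestBranchWss:
    def test_zero_flow(self):
        assert branch_wss(0.0, 0.01) == 0.0

    def test_hand_computed_value(self):
        # 4 * 0.0035 * 1e-4 / (pi * 1e-6) = 1.4e-6 / 3.14159e-6
        val = branch_wss(1e-4, 0.01, mu=0.0035)
        assert val == pytest.approx(4 * 0.0035 * 1e-4 / (np.pi * 1e-6),
                                    rel=1e-14)
        assert val == pytest.approx(0.4456, abs=2e-4)

    def test_inverse_cube_radius_scaling(self):
        assert branch_wss(1e-4, 0.005) == pytest.approx(
            8.0 * branch_wss(1e-4, 0.01), rel=1e-12)

    def test_positive_radius_required(self):
        with pytest.raises(ValueError):
            branch_wss(1e-4, 0.0)


class TestReynolds:
    def test_hand_computed_value(self):
        assert compute_reynolds(1060.0, 0.5, 0.025, 0.0035) == pytest.approx(
            1060 * 0.5 * 0.025 / 0.0035, rel=1e-14)

    def test_linear_in_velocity(self):
        assert compute_reynolds(1060, 1.0, 0.02, 0.0035) == pytest.approx(
            2 * compute_reynolds(1060, 0.5, 0.02, 0.0035))

    def test_velocity_diameter_symmetry(self):
        assert compute_reynolds(1060, 0.5, 0.025, 0.0035) == pytest.approx(
            compute_reynolds(1060, 0.025, 0.5, 0.0035))

    def test_turbulent_warning(self):
        with pytest.warns(UserWarning, match="laminar"):
            compute_reynolds(1060.0, 2.0, 0.03, 0.0035)


@pytest.fixture(scope="module")
def aorta_solution(default_mesh):
    wf = generate_inlet_waveform(4.5, 77.0)
    areas = default_mesh.outlet_areas()
    overall = OverallCirculation(Rp_bar=1.65e7, Rd_bar=1.49e8, C_bar=1e-8,
                                 outlet_areas=areas)
    outlets = allocate_outlet_params(overall)
    branches = [Branch(tag, 18.0, float(np.sqrt(a / np.pi)))
                for tag, a in areas.items()]
    net = BranchNetwork(branches)
    return solve_flow_split(net, outlets, wf, wf.period / 200)


class TestWallWssField:
    def test_moving_wall_scales_by_radius_cubed(self, default_mesh,
                                                aorta_solution):
        """At fixed flow, systolic wall motion (radius up) lowers WSS by
        (r0/r_t)^3 face by face."""
        from aorta_uq.synthetic import systolic_shape
        series = generate_phase_series(default_mesh, 10, 77.0, pulsation=0.1)
        # evaluate at a phase knot inside systole: interpolation is exact
        # there and both flow and wall excursion are nonzero
        t = float(series.phase_times[2])
        rigid = wall_wss_field(aorta_solution, default_mesh, t, motion=None)
        moving = wall_wss_field(aorta_solution, default_mesh, t, motion=series)
        md = default_mesh.metadata
        r0 = np.linalg.norm(default_mesh.vertices - md["v_foot"],
                            axis=1)[default_mesh.faces].mean(axis=1)
        amp = 0.1 * 12.5 * systolic_shape(t, series.period,
                                          series.period * 0.4)
        assert amp > 0.5
        expected = (r0 / (r0 + amp)) ** 3
        assert rigid.values.min() > 0.0
        # the pure cube law holds wherever the radius-dependent inner-
        # curvature factor is inactive (off-arch or outer-half faces)
        f_s = np.nan_to_num(md["f_s"], nan=np.inf)
        inner_arch = (f_s <= md["arch_arc_length"]) \
            & (np.clip(-np.cos(np.nan_to_num(md["f_phi"], nan=0.0)), 0, None) > 0)
        plain = ~inner_arch
        ratio = moving.values / rigid.values
        assert np.allclose(ratio[plain], expected[plain], rtol=1e-9)
        # on the inner arch the moving wall additionally raises the curvature
        # factor, so the ratio sits above the cube law there
        assert np.all(ratio[inner_arch] >= expected[inner_arch])

    def test_inner_curvature_exceeds_outer(self, default_mesh, aorta_solution):
        field = wall_wss_field(aorta_solution, default_mesh, 0.1)
        md = default_mesh.metadata
        f_s, f_phi = md["f_s"], md["f_phi"]
        arch = np.nan_to_num(f_s, nan=np.inf) <= md["arch_arc_length"]
        trunk = md["face_branch"] == "trunk"
        inner = arch & trunk & (np.abs(f_phi - np.pi) < 0.4)
        outer = arch & trunk & ((f_phi < 0.4) | (f_phi > 2 * np.pi - 0.4))
        # same band of s to compare like with like
        band = (f_s > 10.0) & (f_s < 20.0)
        assert field.values[inner & band].min() >= \
            field.values[outer & band].max() * 0.999

    def test_straight_tube_reduces_to_poiseuille(self, default_mesh,
                                                 aorta_solution):
        """Away from the arch (zero curvature) the rigid-wall field equals the
        plain Poiseuille value at each face's local radius."""
        t = 0.13
        field = wall_wss_field(aorta_solution, default_mesh, t)
        md = default_mesh.metadata
        desc = (md["face_branch"] == "Desc") & \
            (np.nan_to_num(md["f_s"], nan=-1.0) > md["arch_arc_length"])
        r_face = np.linalg.norm(default_mesh.vertices - md["v_foot"],
                                axis=1)[default_mesh.faces].mean(axis=1)
        q_desc = float(aorta_solution.branch_flow_at("Desc", t))
        expected = branch_wss(q_desc, r_face[desc] * 1e-3)
        assert np.allclose(field.values[desc], expected, rtol=1e-12)

    def test_unassignable_faces_rejected(self, default_mesh, aorta_solution):
        broken = default_mesh.copy()
        fb = broken.metadata["face_branch"].copy()
        fb[:5] = "nowhere"
        broken.metadata["face_branch"] = fb
        with pytest.raises(ValueError, match="assignable"):
            wall_wss_field(aorta_solution, broken, 0.1)
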