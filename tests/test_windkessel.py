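"""Three-element Windkessel model: allocation, units, 0D integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aorta_uq import (FlowWaveform, OverallCirculation, WindkesselParams,
                      WindkesselState, allocate_outlet_params,
                      check_allocation_consistency, convert_units,
                      generate_inlet_waveform, last_cycle,
                      params_from_table_units, params_to_table_units,
                      pressure_step, solve_3wkm, step_response_pressure,
                      total_resistance_from_pressure)

PHYSIO = WindkesselParams(Rp=1.65e7, Rd=1.49e8, C=1.0e-8)

#: tabulated outlet parameters (clinical units) used as conversion fixtures
TABLE_ROWS = {
    "BCA": (2.18e-9, 4.34e7, 6.80e8),
    "LCC": (7.74e-10, 1.22e7, 1.91e9),
    "LSUB": (1.56e-9, 6.08e7, 9.52e8),
    "Desc": (5.84e-9, 1.62e7, 2.53e8),
}


class TestAllocation:
    def test_two_equal_outlets(self):
        ov = OverallCirculation(Rp_bar=1.0, Rd_bar=3.0, C_bar=4.0,
                                outlet_areas={"a": 50.0, "b": 50.0})
        out = allocate_outlet_params(ov)
        assert out["a"].Rp == pytest.approx(2.0)
        assert out["b"].Rp == pytest.approx(2.0)
        assert out["a"].C == pytest.approx(2.0)

    def test_compliance_proportional_to_area(self):
        ov = OverallCirculation(Rp_bar=1.0, Rd_bar=1.0, C_bar=4.0,
                                outlet_areas={"big": 3.0, "small": 1.0})
        out = allocate_outlet_params(ov)
        assert out["big"].C == pytest.approx(3.0)
        assert out["small"].C == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(areas=st.lists(st.floats(1.0, 500.0), min_size=1, max_size=6))
    def test_conservation_properties(self, areas):
        ov = OverallCirculation(Rp_bar=1.65e7, Rd_bar=1.49e8, C_bar=1e-8,
                                outlet_areas={f"o{k}": a
                                              for k, a in enumerate(areas)})
        out = allocate_outlet_params(ov)
        rp_parallel = 1.0 / sum(1.0 / p.Rp for p in out.values())
        rd_parallel = 1.0 / sum(1.0 / p.Rd for p in out.values())
        c_sum = sum(p.C for p in out.values())
        assert rp_parallel == pytest.approx(ov.Rp_bar, rel=1e-12)
        assert rd_parallel == pytest.approx(ov.Rd_bar, rel=1e-12)
        assert c_sum == pytest.approx(ov.C_bar, rel=1e-12)
        ratios = [p.Rd / p.Rp for p in out.values()]
        assert np.ptp(ratios) <= 1e-9 * ratios[0]

    def test_invalid_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            OverallCirculation(1.0, 1.0, 1.0, {"a": -3.0})

    def test_tabulated_row_consistency_flags_lcc(self):
        """Three of the four tabulated outlet rows share C*Rp and Rd/Rp
        ratios to ~1%; the LCC row violates both and is flagged."""
        params = {tag: params_from_table_units(C=c, Rp=rp, Rd=rd)
                  for tag, (c, rp, rd) in TABLE_ROWS.items()}
        assert check_allocation_consistency(params) == ["LCC"]
        consistent = {t: p for t, p in params.items() if t != "LCC"}
        assert check_allocation_consistency(consistent) == []


class TestUnits:
    def test_dimensional_factor(self):
        # kg cm^-4 s^-1 -> (1e-2 m)^-4 factor 1e8 on Pa s/m^3 (= kg m^-4 s^-1)
        assert convert_units(1.0, "resistance", "table_to_si") == 1e8
        assert convert_units(1.0, "compliance", "table_to_si") == 1e-8

    def test_round_trip_desc_row(self):
        c, rp, rd = TABLE_ROWS["Desc"]
        back = params_to_table_units(params_from_table_units(C=c, Rp=rp, Rd=rd))
        assert back["C"] == pytest.approx(c, rel=1e-12)
        assert back["Rp"] == pytest.approx(rp, rel=1e-12)
        assert back["Rd"] == pytest.approx(rd, rel=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(v=st.floats(1e-12, 1e12))
    def test_round_trip_random(self, v):
        for q in ("resistance", "compliance"):
            si = convert_units(v, q, "table_to_si")
            assert convert_units(si, q, "si_to_table") == pytest.approx(
                v, rel=1e-12)

    def test_unknown_tags_rejected(self):
        with pytest.raises(ValueError):
            convert_units(1.0, "inductance", "table_to_si")
        with pytest.raises(ValueError):
            convert_units(1.0, "resistance", "sideways")


def constant_waveform(q0: float, period: float, n: int = 200) -> FlowWaveform:
    t = np.linspace(0.0, period, n)
    return FlowWaveform(times=t, flow=np.full(n, q0), period=period,
                        heart_rate=60.0 / period)


class TestSolver:
    def test_steady_state_resistive_sum(self):
        q0 = 7.5e-5
        wf = constant_waveform(q0, 0.8)
        n_cycles = int(np.ceil(10 * PHYSIO.tau / 0.8))
        state = solve_3wkm(PHYSIO, wf, dt=2e-3, n_cycles=n_cycles, p0=0.0)
        assert state.pressure == pytest.approx(q0 * (PHYSIO.Rp + PHYSIO.Rd),
                                               rel=1e-3)

    def test_resistive_limit_tracks_flow(self):
        params = WindkesselParams(Rp=1.65e7, Rd=1.49e8, C=1e-20)
        wf = generate_inlet_waveform(4.5, 77.0)
        state = solve_3wkm(params, wf, dt=wf.period / 400, n_cycles=1)
        t, q, p = state.arrays()
        expected = q * (params.Rp + params.Rd)
        scale = expected.max()
        assert np.abs(p - expected).max() / scale < 5e-3

    def test_step_response_first_order_convergence(self):
        """Against the closed-form step response (pressure initialized past
        the flow jump), the implicit-Euler error is O(dt): halving dt halves
        the error."""
        q0 = 1e-4
        errors = []
        for dt in (4e-3, 2e-3, 1e-3):
            state = WindkesselState(pressure=q0 * PHYSIO.Rp)
            n = int(round(2.0 / dt))
            for _ in range(n):
                pressure_step(state, PHYSIO, q0, dt, dq_dt=0.0)
            t, _, p = state.arrays()
            errors.append(np.abs(p - step_response_pressure(PHYSIO, q0, t)).max())
        assert errors[0] > errors[1] > errors[2]
        assert errors[0] / errors[1] == pytest.approx(2.0, rel=0.15)
        assert errors[1] / errors[2] == pytest.approx(2.0, rel=0.15)

    def test_pressure_step_reproduces_solver(self):
        wf = generate_inlet_waveform(4.5, 77.0)
        dt = wf.period / 200
        ref = solve_3wkm(PHYSIO, wf, dt, n_cycles=2, p0=1e4)
        t_ref, q_ref, p_ref = ref.arrays()
        state = WindkesselState(pressure=1e4)
        state.record(float(wf.at(0.0)))
        dq_grid = wf.derivative()
        for k, qk in enumerate(q_ref[1:]):
            tk = dt * (k + 1)
            dq = float(np.interp(np.mod(tk, wf.period), wf.times, dq_grid))
            pressure_step(state, PHYSIO, float(qk), dt, dq_dt=dq)
        _, _, p = state.arrays()
        assert np.array_equal(p, p_ref)

    def test_zero_flow_decay_rate(self):
        """With Q = 0 the pressure decays exponentially at 1/(Rd C)."""
        state = WindkesselState(pressure=1.2e4)
        dt = 1e-3
        for _ in range(1500):
            pressure_step(state, PHYSIO, 0.0, dt, dq_dt=0.0)
        t, _, p = state.arrays()
        rate = -np.polyfit(t[1:], np.log(p[1:]), 1)[0]
        assert rate == pytest.approx(1.0 / PHYSIO.tau, rel=1e-2)

    def test_monotone_approach_to_steady_state(self):
        q0 = 1e-4
        steady = q0 * (PHYSIO.Rp + PHYSIO.Rd)
        state = WindkesselState(pressure=0.0)
        prev = 0.0
        for _ in range(50):
            pressure_step(state, PHYSIO, q0, dt=5e-3, dq_dt=0.0)
            assert prev < state.pressure < steady
            prev = state.pressure

    def test_periodic_steady_state_by_cycle_three(self):
        """With the periodic initialization, the third cycle already equals
        later cycles (no start-up transient left)."""
        wf = generate_inlet_waveform(4.5, 77.0)
        dt = wf.period / 200
        s3 = solve_3wkm(PHYSIO, wf, dt, n_cycles=3)
        s4 = solve_3wkm(PHYSIO, wf, dt, n_cycles=4)
        _, _, p3 = last_cycle(s3, wf.period)
        _, _, p4 = last_cycle(s4, wf.period)
        n = min(len(p3), len(p4))
        assert np.abs(p3[:n] - p4[:n]).max() / p3.mean() < 1e-6
        # a cold start decays geometrically toward the periodic orbit:
        # cycle 3 retains well under a third of the cycle-1 deviation
        cold = solve_3wkm(PHYSIO, wf, dt, n_cycles=3,
                          p0=wf.cardiac_output() * (PHYSIO.Rp + PHYSIO.Rd))
        tc, _, pc = cold.arrays()
        tp, _, pp = solve_3wkm(PHYSIO, wf, dt, n_cycles=3).arrays()
        dev = np.abs(pc - pp)
        per_cycle = np.array_split(dev[1:], 3)
        ratio = per_cycle[2].max() / per_cycle[0].max()
        assert ratio == pytest.approx(np.exp(-2 * wf.period / PHYSIO.tau),
                                      rel=0.05)

    def test_dt_resolution_guard(self):
        wf = generate_inlet_waveform(4.5, 77.0)
        with pytest.raises(ValueError, match="dt"):
            solve_3wkm(PHYSIO, wf, dt=wf.period / 10)

    def test_total_resistance_helper(self):
        # 93 mmHg at 4.5 l/min
        r = total_resistance_from_pressure(93 * 133.322, 7.5e-5)
        assert r == pytest.approx(1.653e8, rel=1e-3)
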