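"""Three-element Windkessel (3WKM) outlet boundary model.

Each outlet is an RCR circuit analogue: a proximal resistance Rp in series
with the parallel pair of a distal resistance Rd and a compliance C.  The
outlet pressure P(t) and flow Q(t) obey

    (1 + Rp/Rd) Q + C Rp dQ/dt = C dP/dt + P/Rd.

The overall circulation parameters (Rp_bar, Rd_bar, C_bar) are distributed
over the outlets by cross-sectional area: resistances scale with
A_tot / A_i, compliances with A_i / A_tot, which conserves the parallel
combination exactly.

Internally everything is SI (Pa·s/m^3, m^3/Pa); converters are provided for
the tabulated clinical units kg·cm^-4·s^-1 (resistance) and kg^-1·cm^4·s^2
(compliance): 1 kg·cm^-4·s^-1 = 1e8 Pa·s/m^3 and 1 kg^-1·cm^4·s^2 =
1e-8 m^3/Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveform import FlowWaveform

#: 1 kg cm^-4 s^-1 expressed in Pa s / m^3 (= kg m^-4 s^-1): (1 cm)^-4 -> 1e8
RESISTANCE_TABLE_TO_SI = 1e8
#: 1 kg^-1 cm^4 s^2 expressed in m^3/Pa (= kg^-1 m^4 s^2): (1 cm)^4 -> 1e-8
COMPLIANCE_TABLE_TO_SI = 1e-8


@dataclass
class WindkesselParams:
    """Lumped parameters of one outlet, SI units."""

    Rp: float  # proximal resistance, Pa s/m^3
    Rd: float  # distal resistance, Pa s/m^3
    C: float   # compliance, m^3/Pa

    def __post_init__(self) -> None:
        if self.Rp <= 0 or self.Rd <= 0 or self.C <= 0:
            raise ValueError("Rp, Rd and C must all be positive")

    @property
    def tau(self) -> float:
        """Exponential relaxation time Rd*C, s."""
        return self.Rd * self.C


def params_from_table_units(C: float, Rp: float, Rd: float) -> WindkesselParams:
    """Build SI params from the tabulated units (kg cm^-4 s^-1, kg^-1 cm^4 s^2)."""
    return WindkesselParams(Rp=Rp * RESISTANCE_TABLE_TO_SI,
                            Rd=Rd * RESISTANCE_TABLE_TO_SI,
                            C=C * COMPLIANCE_TABLE_TO_SI)


def params_to_table_units(p: WindkesselParams) -> dict[str, float]:
    """Express SI params in the tabulated clinical units."""
    return {"C": p.C / COMPLIANCE_TABLE_TO_SI,
            "Rp": p.Rp / RESISTANCE_TABLE_TO_SI,
            "Rd": p.Rd / RESISTANCE_TABLE_TO_SI}


def convert_units(value: float, quantity: str, direction: str) -> float:
    """Convert a single resistance/compliance value between unit systems.

    ``quantity`` is ``"resistance"`` or ``"compliance"``; ``direction``
    ``"table_to_si"`` or ``"si_to_table"``.
    """
    factors = {"resistance": RESISTANCE_TABLE_TO_SI,
               "compliance": COMPLIANCE_TABLE_TO_SI}
    if quantity not in factors:
        raise ValueError(f"unknown quantity {quantity!r}")
    if direction == "table_to_si":
        return value * factors[quantity]
    if direction == "si_to_table":
        return value / factors[quantity]
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class OverallCirculation:
    """Overall lumped parameters plus the outlet areas used to split them."""

    Rp_bar: float
    Rd_bar: float
    C_bar: float
    outlet_areas: dict[str, float] = field(default_factory=dict)  # mm^2

    def __post_init__(self) -> None:
        if self.Rp_bar <= 0 or self.Rd_bar <= 0 or self.C_bar <= 0:
            raise ValueError("overall parameters must be positive")
        if len(set(self.outlet_areas)) != len(self.outlet_areas):
            raise ValueError("outlet tags must be unique")
        for tag, a in self.outlet_areas.items():
            if a <= 0:
                raise ValueError(f"outlet {tag} has non-positive area")


def total_resistance_from_pressure(mean_pressure_pa: float,
                                   cardiac_output_m3s: float) -> float:
    """Systemic total resistance Rp_bar + Rd_bar from mean pressure / CO."""
    if mean_pressure_pa <= 0 or cardiac_output_m3s <= 0:
        raise ValueError("pressure and cardiac output must be positive")
    return mean_pressure_pa / cardiac_output_m3s


def allocate_outlet_params(overall: OverallCirculation
                           ) -> dict[str, WindkesselParams]:
    """Distribute the overall parameters over the outlets by area.

    Rp_i = Rp_bar * A_tot / A_i (same for Rd); C_i = C_bar * A_i / A_tot.
    The parallel combination of the allocated resistances recovers the
    overall resistance and the compliances sum to C_bar.
    """
    if not overall.outlet_areas:
        raise ValueError("at least one outlet required")
    a_tot = sum(overall.outlet_areas.values())
    out = {}
    for tag, a in overall.outlet_areas.items():
        out[tag] = WindkesselParams(Rp=overall.Rp_bar * a_tot / a,
                                    Rd=overall.Rd_bar * a_tot / a,
                                    C=overall.C_bar * a / a_tot)
    return out


def check_allocation_consistency(params: dict[str, WindkesselParams],
                                 rtol: float = 0.01) -> list[str]:
    """Flag outlets whose parameters violate the area-allocation ratios.

    Under the allocation rule both Rd_i/Rp_i and C_i*Rp_i are constant across
    outlets.  Returns the tags inconsistent with the majority (median) ratios
    beyond ``rtol``; an empty list means the set is internally consistent.
    """
    tags = list(params)
    ratio = np.array([params[t].Rd / params[t].Rp for t in tags])
    crp = np.array([params[t].C * params[t].Rp for t in tags])
    bad = set()
    for values in (ratio, crp):
        ref = np.median(values)
        rel = np.abs(values - ref) / ref
        bad.update(np.asarray(tags)[rel > rtol].tolist())
    return sorted(bad)


# ---------------------------------------------------------------------------
# 0D time stepping


@dataclass
class WindkesselState:
    """Pressure state and (t, Q, P) history of one outlet's 0D solve."""

    pressure: float = 0.0
    time: float = 0.0
    history_t: list = field(default_factory=list)
    history_q: list = field(default_factory=list)
    history_p: list = field(default_factory=list)

    def record(self, q: float) -> None:
        if self.history_t and self.time <= self.history_t[-1]:
            raise ValueError("history times must be strictly increasing")
        self.history_t.append(self.time)
        self.history_q.append(q)
        self.history_p.append(self.pressure)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (np.asarray(self.history_t), np.asarray(self.history_q),
                np.asarray(self.history_p))


def pressure_step(state: WindkesselState, params: WindkesselParams,
                  q_new: float, dt: float,
                  dq_dt: float | None = None) -> WindkesselState:
    """Advance the outlet pressure by one implicit (backward) Euler step.

    This is the single-call contract a flow solver uses once per time step
    per outlet.  ``dq_dt`` defaults to the backward difference against the
    last recorded flow; passing an explicit value (e.g. periodic central
    differences) reproduces :func:`solve_3wkm` exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dq_dt is None:
        q_prev = state.history_q[-1] if state.history_q else q_new
        dq_dt = (q_new - q_prev) / dt
    if not state.history_t:
        state.record(q_new)  # initial condition at state.time
    rp, rd, c = params.Rp, params.Rd, params.C
    source = (1.0 + rp / rd) * q_new + c * rp * dq_dt
    state.pressure = (c / dt * state.pressure + source) / (c / dt + 1.0 / rd)
    state.time += dt
    state.record(q_new)
    return state


def solve_3wkm(params: WindkesselParams, waveform: FlowWaveform,
               dt: float, n_cycles: int = 3,
               p0: float | None = None) -> WindkesselState:
    """Integrate the outlet pressure over ``n_cycles`` of a periodic waveform.

    Implicit Euler in P with dQ/dt from periodic central differences of the
    waveform.  With ``p0=None`` the exact periodic initial pressure of the
    discrete scheme is computed first (the linear one-cycle map P(T) =
    a^N P(0) + G is solved for its fixed point), so the returned cycles are
    free of start-up transients; pass an explicit ``p0`` to study the
    transient itself.  Use :func:`last_cycle` for the solution cycle.
    """
    if dt >= waveform.period / 50.0:
        raise ValueError("dt must resolve the cycle (dt < period/50)")
    steps_per_cycle = int(round(waveform.period / dt))
    n_steps = steps_per_cycle * n_cycles
    times = dt * np.arange(1, n_steps + 1)
    q = waveform.at(times)
    dq_grid = waveform.derivative()
    dq = np.interp(np.mod(times, waveform.period), waveform.times, dq_grid)

    def run(p_init: float, n: int) -> WindkesselState:
        st = WindkesselState(pressure=p_init, time=0.0)
        st.record(float(waveform.at(0.0)))
        for qi, dqi in zip(q[:n], dq[:n]):
            pressure_step(st, params, float(qi), dt, dq_dt=float(dqi))
        return st

    if p0 is None:
        # fixed point of the one-cycle affine map of the discrete scheme
        alpha = (params.C / dt) / (params.C / dt + 1.0 / params.Rd)
        g = run(0.0, steps_per_cycle).pressure
        p0 = g / (1.0 - alpha ** steps_per_cycle)
    return run(float(p0), n_steps)


def last_cycle(state: WindkesselState, period: float
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (t, Q, P) restricted to the final cycle of the history."""
    t, q, p = state.arrays()
    sel = t >= t[-1] - period + 1e-12
    return t[sel], q[sel], p[sel]


def step_response_pressure(params: WindkesselParams, q0: float,
                           t: np.ndarray) -> np.ndarray:
    """Closed-form P(t) for a flow step Q0*H(t) from rest (P(0-) = 0).

    The compliance transmits the flow jump instantaneously through Rp, so
    P(0+) = Q0*Rp, relaxing to the resistive steady state Q0*(Rp+Rd) with
    time constant Rd*C.
    """
    t = np.asarray(t, dtype=np.float64)
    decay = np.exp(-t / params.tau)
    return q0 * (params.Rp + params.Rd) * (1.0 - decay) + q0 * params.Rp * decay
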