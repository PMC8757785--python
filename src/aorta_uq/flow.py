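"""Quasi-static resistance-network flow surrogate and wall shear stress.

This module supplies the quantities a 3D CFD solver would provide — the
per-branch flow split, outlet pressures and wall shear stress over the cycle
— from a one-junction Poiseuille network coupled to the three-element
Windkessel outlets.  It is openly a surrogate: no Navier-Stokes equations
are solved; it exists so the WSS descriptor machinery and the uncertainty
study run end-to-end, and so that an externally computed per-face WSS series
can be dropped in through the same interfaces.

At every implicit time step the junction pressure is the solution of the
nodal balance ``sum_i (P_J - P_i)/R_i = Q_inlet`` with each outlet pressure
eliminated through its backward-Euler Windkessel update, so mass is
conserved to machine precision by construction.

Wall shear stress uses the Poiseuille wall value ``4 mu Q / (pi r^3)`` with
the instantaneous local radius (moving wall lowers systolic WSS by
``(r0/r_t)^3``), enhanced on the inner curvature of the arch by a factor
``1 + kappa * r`` (kappa the centerline curvature) to reproduce the
inner-bend WSS hot spot qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import SurfaceField
from .mesh import TriSurfaceMesh, CardiacPhaseSeries
from .morphing import phase_positions
from .waveform import FlowWaveform
from .windkessel import WindkesselParams, WindkesselState, pressure_step

BLOOD_DENSITY = 1060.0      # kg/m^3
BLOOD_VISCOSITY = 0.0035    # Pa s


@dataclass
class Branch:
    tag: str
    length_mm: float
    radius_mm: float

    def poiseuille_resistance(self, mu: float) -> float:
        """8 mu L / (pi r^4), SI (Pa s / m^3)."""
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise ValueError("branch dimensions must be positive")
        L = self.length_mm * 1e-3
        r = self.radius_mm * 1e-3
        return 8.0 * mu * L / (np.pi * r ** 4)


@dataclass
class BranchNetwork:
    """One inlet junction feeding each outlet through a Poiseuille branch."""

    branches: list
    density: float = BLOOD_DENSITY
    viscosity: float = BLOOD_VISCOSITY

    def __post_init__(self) -> None:
        tags = [b.tag for b in self.branches]
        if len(set(tags)) != len(tags):
            raise ValueError("one branch per outlet tag required")

    def tags(self) -> list:
        return [b.tag for b in self.branches]

    def resistances(self) -> dict[str, float]:
        return {b.tag: b.poiseuille_resistance(self.viscosity)
                for b in self.branches}


@dataclass
class FlowSolution:
    """Time histories of the coupled 0D solve (SI units)."""

    times: np.ndarray
    q_inlet: np.ndarray
    q_branch: dict[str, np.ndarray]
    p_outlet: dict[str, np.ndarray]
    p_junction: np.ndarray
    period: float
    network: BranchNetwork
    waveform: FlowWaveform = None

    def mass_residual(self) -> np.ndarray:
        total = np.sum([q for q in self.q_branch.values()], axis=0)
        return total - self.q_inlet

    def last_cycle(self) -> "FlowSolution":
        sel = self.times >= self.times[-1] - self.period + 1e-12
        return FlowSolution(
            times=self.times[sel], q_inlet=self.q_inlet[sel],
            q_branch={k: v[sel] for k, v in self.q_branch.items()},
            p_outlet={k: v[sel] for k, v in self.p_outlet.items()},
            p_junction=self.p_junction[sel], period=self.period,
            network=self.network, waveform=self.waveform)

    def branch_flow_at(self, tag: str, t) -> np.ndarray:
        """Branch flow at cycle time(s) t, periodic interpolation of the
        last cycle."""
        lc = self.last_cycle()
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        tl = lc.times - lc.times[0]
        return np.interp(tt, tl, lc.q_branch[tag])


def solve_flow_split(network: BranchNetwork,
                     outlets: dict[str, WindkesselParams],
                     waveform: FlowWaveform, dt: float,
                     n_cycles: int = 3) -> FlowSolution:
    """Couple the junction network to the Windkessel outlets over n_cycles.

    Outlet pressures start from their resistive steady state, so the usual
    three-cycle convention suffices for periodic convergence;
    each step solves the junction balance exactly and advances every outlet
    through :func:`pressure_step`.
    """
    tags = network.tags()
    if set(tags) != set(outlets):
        raise ValueError("network outlets must match Windkessel outlet tags")
    res = network.resistances()
    q_mean = waveform.cardiac_output()
    # conductance-based steady split for the warm start
    g = {t: 1.0 / (res[t] + outlets[t].Rp + outlets[t].Rd) for t in tags}
    g_tot = sum(g.values())
    states = {}
    q_start = float(waveform.at(0.0))
    for t in tags:
        q0 = q_mean * g[t] / g_tot
        st = WindkesselState(pressure=q0 * (outlets[t].Rp + outlets[t].Rd))
        st.record(q_start * g[t] / g_tot)  # t=0 record splits the actual inlet flow
        states[t] = st

    n_steps = int(round(waveform.period / dt * n_cycles))
    times = dt * np.arange(1, n_steps + 1)
    q_in = waveform.at(times)
    q_hist = {t: [states[t].history_q[0]] for t in tags}
    p_hist = {t: [states[t].pressure] for t in tags}
    pj_hist = [np.nan]

    for k, qk in enumerate(q_in):
        alpha, beta = {}, {}
        for t in tags:
            p = outlets[t]
            denom = p.C / dt + 1.0 / p.Rd
            q_prev = q_hist[t][-1]
            p_prev = p_hist[t][-1]
            alpha[t] = (p.C / dt * p_prev - p.C * p.Rp / dt * q_prev) / denom
            beta[t] = ((1.0 + p.Rp / p.Rd) + p.C * p.Rp / dt) / denom
        inv = {t: 1.0 / (res[t] + beta[t]) for t in tags}
        p_j = (qk + sum(alpha[t] * inv[t] for t in tags)) / sum(inv.values())
        q_new = {t: (p_j - alpha[t]) * inv[t] for t in tags}
        residual = abs(sum(q_new.values()) - qk)
        if residual > 1e-9 * max(1e-12, abs(qk), q_mean):
            raise RuntimeError(
                f"junction balance failed at step {k}: residual {residual:.3e}")
        for t in tags:
            pressure_step(states[t], outlets[t], q_new[t], dt)
            q_hist[t].append(q_new[t])
            p_hist[t].append(states[t].pressure)
        pj_hist.append(p_j)

    all_t = np.concatenate([[0.0], times])
    return FlowSolution(
        times=all_t,
        q_inlet=np.concatenate([[float(waveform.at(0.0))], q_in]),
        q_branch={t: np.asarray(q_hist[t]) for t in tags},
        p_outlet={t: np.asarray(p_hist[t]) for t in tags},
        p_junction=np.asarray(pj_hist),
        period=waveform.period, network=network, waveform=waveform)


def branch_wss(q_m3s, radius_m, mu: float = BLOOD_VISCOSITY):
    """Poiseuille wall shear stress 4 mu Q / (pi r^3), Pa."""
    radius_m = np.asarray(radius_m, dtype=float)
    if np.any(radius_m <= 0):
        raise ValueError("radius must be positive")
    return 4.0 * mu * np.asarray(q_m3s, dtype=float) / (np.pi * radius_m ** 3)


def compute_reynolds(density: float, velocity: float, diameter: float,
                     mu: float) -> float:
    """Reynolds number rho v D / mu (laminar-regime check; warn above 4000)."""
    if min(density, velocity, diameter, mu) <= 0:
        raise ValueError("all inputs must be positive")
    re = density * velocity * diameter / mu
    if re > 4000.0:
        import warnings
        warnings.warn(f"Re = {re:.0f} exceeds the laminar regime", stacklevel=2)
    return re


def wall_wss_field(solution: FlowSolution, mesh: TriSurfaceMesh, t: float,
                   motion: CardiacPhaseSeries | None = None,
                   curvature_coeff: float = 1.0) -> SurfaceField:
    """Per-face WSS (Pa) at cycle time ``t``.

    Faces are assigned to network branches through the generator's
    ``face_branch`` metadata ("trunk" faces carry the full inlet flow).  The
    instantaneous local radius comes from ``motion`` when given (the
    moving-wall mode), else from the mesh as-is (rigid mode).  Arch faces get
    the inner-curvature enhancement ``1 + c * kappa * r`` on their inner
    half.
    """
    md = mesh.metadata
    if "face_branch" not in md:
        raise ValueError("mesh lacks face_branch metadata")
    fb = md["face_branch"]
    known = set(solution.q_branch) | {"trunk"}
    bad = np.flatnonzero(~np.isin(fb, sorted(known)))
    if len(bad):
        raise ValueError(f"faces not assignable to a branch: {bad[:10].tolist()}")

    verts = phase_positions(motion, t) if motion is not None else mesh.vertices
    r_vert_mm = np.linalg.norm(verts - md["v_foot"], axis=1)
    r_face_mm = r_vert_mm[mesh.faces].mean(axis=1)

    mu = solution.network.viscosity
    q_face = np.empty(mesh.n_faces)
    for tag in np.unique(fb):
        sel = fb == tag
        if tag == "trunk":
            q = float(solution.waveform.at(t)) if solution.waveform is not None \
                else float(np.interp(np.mod(t, solution.period),
                                     solution.times, solution.q_inlet))
        else:
            q = float(solution.branch_flow_at(tag, t))
        q_face[sel] = q
    wss = branch_wss(q_face, r_face_mm * 1e-3, mu)

    f_s = md.get("f_s")
    if f_s is not None:
        arch_len = md["arch_arc_length"]
        kappa = np.where(np.nan_to_num(f_s, nan=np.inf) <= arch_len,
                         1.0 / md["params"]["arch_radius"], 0.0)
        f_phi = md["f_phi"]
        inner = np.clip(-np.cos(np.nan_to_num(f_phi, nan=0.0)), 0.0, None)
        factor = 1.0 + curvature_coeff * kappa * r_face_mm * inner
        wss = wss * factor
    return SurfaceField(values=wss, association="face", units="Pa",
                        name="wss_pa")
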