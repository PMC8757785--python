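"""Surrogate flow split and WSS/TAWSS descriptors on the ascending aorta.

Couples the Poiseuille branch network to the Windkessel outlets, samples the
wall shear stress over the last cycle, and writes the systolic-peak WSS and
TAWSS summaries plus the unfolded ascending-aorta map.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import aorta_uq as aq

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = aq.GeometryParams(seed=42)
    mesh = aq.generate_aorta_surface(params)
    wf = aq.generate_inlet_waveform(4.5, 77.0)
    areas = mesh.outlet_areas()
    outlets = aq.allocate_outlet_params(aq.OverallCirculation(
        Rp_bar=1.65e7, Rd_bar=1.49e8, C_bar=1e-8, outlet_areas=areas))
    net = aq.BranchNetwork([
        aq.Branch(tag, params.branch_length if tag in params.branch_radii
                  else params.desc_length, float(np.sqrt(a / np.pi)))
        for tag, a in areas.items()])
    sol = aq.solve_flow_split(net, outlets, wf, wf.period / 200)

    lc = sol.last_cycle()
    split = {tag: np.trapezoid(lc.q_branch[tag], lc.times)
             / np.trapezoid(lc.q_inlet, lc.times) for tag in lc.q_branch}
    print("Cycle-mean flow split:",
          {k: f"{100 * v:.1f}%" for k, v in split.items()},
          f"(mass residual {np.abs(sol.mass_residual()).max():.2e} m^3/s)")

    t_eval = np.linspace(0.0, wf.period, 33)
    wss_rows = np.vstack([aq.wall_wss_field(sol, mesh, float(t)).values
                          for t in t_eval])
    tawss_field = aq.tawss(wss_rows, t_eval, period=wf.period)
    sys_field = aq.wall_wss_field(sol, mesh, wf.peak_time())

    region = ("ascending_patch", "artifact_patch")
    sub, sys_sub = aq.extract_region(mesh, sys_field, region)
    _, tawss_sub = aq.extract_region(mesh, tawss_field, region)
    rows = []
    for kind, field in (("wss_systolic", sys_sub), ("tawss", tawss_sub)):
        s = aq.summarize_field(field, sub)
        rows.append({"descriptor": kind, **s.as_dict()})
        print(f"{kind:13s} ascending wall: min {s.min:.2f} / "
              f"avg {s.mean:.2f} / max {s.max:.2f} Pa")
    pd.DataFrame(rows).to_csv(RESULTS / "wss_descriptors.csv", index=False)

    cl = mesh.metadata["centerline"]
    cls = mesh.metadata["centerline_s"]
    f_s = sub.metadata["f_s"]
    clsub = cl[(cls >= np.nanmin(f_s)) & (cls <= np.nanmax(f_s))]
    um = aq.unfold(sub, sys_sub, centerline=clsub, ref_direction=(0, 1, 0))
    grid = pd.DataFrame(um.grid, index=np.round(um.arclength_mm, 2),
                        columns=np.round(um.angle_deg, 1))
    grid.to_csv(RESULTS / "unfolded_ascending_wss.csv")
    peak_angle = um.angle_deg[np.argmax(um.grid.max(axis=0))]
    print(f"Unfolded map: systolic WSS peaks at circumferential angle "
          f"{peak_angle:.0f} deg (inner curvature of the arch).")


if __name__ == "__main__":
    main()
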