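"""Run the cumulative smoothing strategy and quantify what it moved.

Produces the S_L / S_M / S_H chain, the between-level correspondence
distances, and the on-mesh geodesic distance from the inlet, mirroring the
surface-distance stage of the study.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import aorta_uq as aq
from aorta_uq.io import write_field_vtp

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "smoothing"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    params = aq.GeometryParams(seed=42)
    raw = aq.generate_aorta_surface(params)
    chain = aq.apply_smoothing_strategy(raw)
    levels = list(chain)

    rows = []
    art_verts = set(np.unique(
        raw.faces[raw.faces_with_label("artifact_patch")]).tolist())
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            d = aq.correspondence_distance(chain[a], chain[b])
            rows.append({
                "pair": f"{a.value} vs {b.value}",
                "max_mm": d.values.max(),
                "mean_mm": d.values.mean(),
                "p95_mm": np.percentile(d.values, 95),
                "argmax_on_artifact": int(np.argmax(d.values)) in art_verts,
            })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "smoothing_distances.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    worst = df.loc[df.max_mm.idxmax()]
    print(f"\nLargest displacement {worst.max_mm:.2f} mm ({worst['pair']}) "
          f"sits on the removed calcification artifact: "
          f"{bool(worst.argmax_on_artifact)}.")

    d_lh = aq.correspondence_distance(chain[aq.SmoothingLevel.S_L],
                                      chain[aq.SmoothingLevel.S_H])
    write_field_vtp(chain[aq.SmoothingLevel.S_H], d_lh,
                    SCRATCH / "distance_SL_SH.vtp")
    geo = aq.dijkstra_geodesic(chain[aq.SmoothingLevel.S_H],
                               raw.rim_loops["Ao"])
    write_field_vtp(chain[aq.SmoothingLevel.S_H], geo,
                    SCRATCH / "geodesic_from_inlet.vtp")
    print(f"Geodesic distance from the inlet rim spans 0 to "
          f"{geo.values.max():.1f} mm along the wall.")


if __name__ == "__main__":
    main()
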