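"""The full uncertainty study: smoothing level, phase, wall treatment.

Runs the five-configuration matrix (S_L/S_M/S_H at diastole, systolic-phase
geometry, moving wall), writes the box-plot summaries and pairwise
contrasts, and states the qualitative findings.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import aorta_uq as aq

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "figures"


def boxplot(report, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    labels, stats = [], []
    for label, kinds in report.summaries.items():
        s = kinds["wss_sys"]
        labels.append(label)
        stats.append({"med": s.median, "q1": s.q1, "q3": s.q3,
                      "whislo": s.whisker_low, "whishi": s.whisker_high,
                      "label": label})
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel("systolic WSS (Pa)")
    ax.set_title("Ascending-aorta WSS across study configurations")
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg = aq.StudyConfig(geometry=aq.GeometryParams(seed=42))
    report = aq.run_uncertainty_study(cfg)
    boxplot(report, SCRATCH / "wss_boxplots.png")
    (RESULTS / "study_report.json").write_text(
        json.dumps(report.as_dict(), indent=2))

    rows = []
    for label, kinds in report.summaries.items():
        for kind, s in kinds.items():
            rows.append({"configuration": label, "descriptor": kind,
                         **s.as_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "study_summaries.csv", index=False)
    show = df[df.descriptor == "wss_sys"][
        ["configuration", "min", "q1", "median", "q3", "max", "mean"]]
    print("Systolic-peak WSS on the ascending wall (Pa):")
    print(show.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    iqr = {lbl.split("/")[0]: k["wss_sys"].iqr
           for lbl, k in report.summaries.items() if lbl.endswith("p0/rigid")}
    print(f"\nSmoothing: S_L IQR {iqr['S_L']:.3f} Pa exceeds "
          f"S_M {iqr['S_M']:.3f} and S_H {iqr['S_H']:.3f} — the light level "
          f"keeps the calcification bump and residual noise.")
    p0 = report.summaries["S_M/p0/rigid"]["wss_sys"].mean
    p4 = report.summaries["S_M/p4/rigid"]["wss_sys"].mean
    print(f"Phase: systolic geometry (dilated lumen) lowers mean systolic "
          f"WSS from {p0:.2f} to {p4:.2f} Pa.")
    rigid = report.summaries["S_M/p0/rigid"]["tawss"].mean
    moving = report.summaries["S_M/p0/moving"]["tawss"].mean
    oracle = aq.expected_moving_rigid_ratio(cfg)
    print(f"Wall treatment: moving wall shifts cycle-mean WSS by "
          f"{100 * (moving / rigid - 1):+.1f}% "
          f"(radius-law oracle {100 * (oracle - 1):+.1f}%).")


if __name__ == "__main__":
    main()
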