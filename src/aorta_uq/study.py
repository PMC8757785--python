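"""The uncertainty study driver.

Contrasts, on the synthetic aorta, the three uncertainty sources the
pipeline quantifies:

* surface smoothing level (S_L / S_M / S_H, cumulative chain);
* segmentation phase (diastolic p0 vs systolic p4 geometry);
* numerical treatment of the wall (rigid vs moving wall).

Each configuration runs the full chain — smooth the raw geometry, compute
outlet areas, allocate the Windkessel parameters, couple the flow surrogate
over three cycles, and evaluate systolic-peak WSS and TAWSS on the ascending
analysis region — and is condensed to box-plot summaries plus pairwise
contrasts of means and interquartile ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .descriptors import tawss, extract_region, summarize_field
from .fields import FieldSummary
from .flow import Branch, BranchNetwork, solve_flow_split, wall_wss_field
from .mesh import TriSurfaceMesh
from .morphing import phase_positions
from .smoothing import SmoothingLevel, TaubinConfig, apply_smoothing_strategy
from .synthetic import (GeometryParams, generate_aorta_surface,
                        generate_phase_series, systolic_shape)
from .waveform import generate_inlet_waveform
from .windkessel import OverallCirculation, allocate_outlet_params

#: the run matrix of the study: (smoothing level, phase, wall method)
DEFAULT_CONFIGURATIONS = (
    ("S_L", "p0", "rigid"),
    ("S_M", "p0", "rigid"),
    ("S_H", "p0", "rigid"),
    ("S_M", "p4", "rigid"),
    ("S_M", "p0", "moving"),
)


@dataclass
class StudyConfig:
    """Inputs of one study run; defaults are the package's study conditions."""

    geometry: GeometryParams = dc_field(default_factory=GeometryParams)
    cardiac_output_l_min: float = 4.5
    heart_rate_bpm: float = 77.0
    n_phases: int = 10
    peak_phase_index: int = 4
    # overall circulation (SI): total resistance from a 93 mmHg mean pressure
    # at 4.5 l/min, split 10% proximal / 90% distal; compliance ~1e-8 m^3/Pa
    Rp_bar: float = 1.65e7
    Rd_bar: float = 1.49e8
    C_bar: float = 1.0e-8
    taubin: TaubinConfig = dc_field(default_factory=TaubinConfig)
    configurations: tuple = DEFAULT_CONFIGURATIONS
    region_tags: tuple = ("ascending_patch", "artifact_patch")
    n_cycles: int = 3
    steps_per_cycle: int = 200
    n_wss_samples: int = 33
    curvature_coeff: float = 1.0


@dataclass
class StudyReport:
    """Per-configuration summaries and pairwise contrasts."""

    summaries: dict            # label -> {"wss_sys": FieldSummary, "tawss": ...}
    contrasts: dict            # (label_a, label_b) -> contrast dict
    meta: dict

    def as_dict(self) -> dict:
        return {
            "meta": self.meta,
            "summaries": {k: {kind: s.as_dict() for kind, s in v.items()}
                          for k, v in self.summaries.items()},
            "contrasts": {f"{a} vs {b}": c
                          for (a, b), c in self.contrasts.items()},
        }


def _config_label(level: str, phase: str, method: str) -> str:
    return f"{level}/{phase}/{method}"


def run_uncertainty_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the full study matrix and summarize it.

    Deterministic for a fixed config (the geometry seed is part of
    :class:`~aorta_uq.synthetic.GeometryParams`).
    """
    config = config or StudyConfig()
    raw = generate_aorta_surface(config.geometry)
    smoothed = apply_smoothing_strategy(raw, config.taubin)
    waveform = generate_inlet_waveform(config.cardiac_output_l_min,
                                       config.heart_rate_bpm)
    dt = waveform.period / config.steps_per_cycle
    t_eval = np.linspace(0.0, waveform.period, config.n_wss_samples)
    t_sys = waveform.peak_time()
    params = config.geometry

    summaries: dict = {}
    for level, phase, method in config.configurations:
        mesh0 = smoothed[SmoothingLevel(level)]
        series = generate_phase_series(mesh0, config.n_phases,
                                       config.heart_rate_bpm,
                                       peak_phase_index=config.peak_phase_index)
        if phase == "p0":
            static = mesh0
        elif phase == "p4":
            static = series.phases[config.peak_phase_index]
        else:
            raise ValueError(f"unknown phase {phase!r}")

        overall = OverallCirculation(Rp_bar=config.Rp_bar, Rd_bar=config.Rd_bar,
                                     C_bar=config.C_bar,
                                     outlet_areas=static.outlet_areas())
        outlets = allocate_outlet_params(overall)
        branches = []
        for tag, area in static.outlet_areas().items():
            r_mm = np.sqrt(area / np.pi)
            length = (params.branch_length if tag in params.branch_radii
                      else params.desc_length)
            branches.append(Branch(tag=tag, length_mm=length, radius_mm=r_mm))
        network = BranchNetwork(branches=branches)
        solution = solve_flow_split(network, outlets, waveform, dt,
                                    n_cycles=config.n_cycles)

        motion = series if method == "moving" else None
        if method not in ("rigid", "moving"):
            raise ValueError(f"unknown wall method {method!r}")
        try:
            wss_rows = [wall_wss_field(solution, static, t, motion=motion,
                                       curvature_coeff=config.curvature_coeff
                                       ).values
                        for t in t_eval]
        except Exception as exc:
            raise RuntimeError(
                f"configuration {_config_label(level, phase, method)} failed"
            ) from exc
        wss_series = np.vstack(wss_rows)
        tawss_field = tawss(wss_series, t_eval, period=waveform.period)
        sys_field = wall_wss_field(solution, static, t_sys, motion=motion,
                                   curvature_coeff=config.curvature_coeff)

        sub, sys_sub = extract_region(static, sys_field, config.region_tags)
        _, tawss_sub = extract_region(static, tawss_field, config.region_tags)
        label = _config_label(level, phase, method)
        summaries[label] = {"wss_sys": summarize_field(sys_sub, sub),
                            "tawss": summarize_field(tawss_sub, sub)}

    contrasts = {}
    labels = list(summaries)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            c = {}
            for kind in ("wss_sys", "tawss"):
                sa: FieldSummary = summaries[a][kind]
                sb: FieldSummary = summaries[b][kind]
                c[f"{kind}_mean_diff"] = sa.mean - sb.mean
                c[f"{kind}_iqr_diff"] = sa.iqr - sb.iqr
            contrasts[(a, b)] = c

    meta = {"heart_rate_bpm": config.heart_rate_bpm,
            "cardiac_output_l_min": config.cardiac_output_l_min,
            "period_s": waveform.period,
            "systolic_peak_s": t_sys,
            "n_faces": raw.n_faces,
            "seed": config.geometry.seed,
            "configurations": [list(c) for c in config.configurations]}
    return StudyReport(summaries=summaries, contrasts=contrasts, meta=meta)


def expected_moving_rigid_ratio(config: StudyConfig | None = None,
                                n_samples: int = 400) -> float:
    """Radius-law oracle for the moving-vs-rigid cycle-mean WSS shift.

    With WSS ~ Q(t)/r(t)^3 and the wall radius following the systolic shape,
    the expected ratio of moving to rigid cycle-mean WSS is
    ``mean[ Q(t) (r0 / r(t))^3 ] / mean[ Q(t) ]`` — below 1, because the
    radius is largest exactly when the flow peaks.
    """
    config = config or StudyConfig()
    waveform = generate_inlet_waveform(config.cardiac_output_l_min,
                                       config.heart_rate_bpm)
    t = np.linspace(0.0, waveform.period, n_samples)
    q = waveform.at(t)
    r0 = config.geometry.lumen_radius
    peak_t = waveform.period * config.peak_phase_index / config.n_phases
    r_t = r0 + r0 * config.geometry.pulsation * systolic_shape(
        t, waveform.period, peak_t)
    num = np.trapezoid(q * (r0 / r_t) ** 3, t)
    den = np.trapezoid(q, t)
    return float(num / den)
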