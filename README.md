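# aorta-uq

Uncertainty assessment for aortic hemodynamics at desk scale: how much do
surface smoothing, the choice of segmentation phase, and the rigid-wall
assumption change wall-shear-stress (WSS) predictions on the ascending
aorta?

Patient-specific CFD pipelines start from gated-CT segmentations that are
noisy, carry calcification artifacts, and freeze the wall at one cardiac
phase. This package re-implements the geometry-processing and
boundary-condition machinery of such a pipeline as tested, reusable
components, and exercises them end-to-end on synthetic gated-CT-like
geometry, so every stage is verifiable without patient data. It is written
for people building or auditing vascular simulation workflows.

## What is implemented

- **Synthetic anatomy** — a parametric aortic arch (torus segment plus
  descending tube) with three supra-aortic branches (BCA, LCC, LSUB),
  labeled inlet/outlet rims, 10 gated wall-motion phases over the R-R
  interval (78 ms step at 77 bpm), seeded surface noise, a localized
  calcification-like bump, and a pulsatile inlet waveform calibrated to a
  cardiac output of 4.5 l/min.
- **Cumulative smoothing strategy** — shape-preserving Taubin filtering
  (w = 0.5, n = 15; λ/μ pairs with μ = −0.53) applied as
  raw → S_L → S_M → S_H, where S_L→S_M is local removal of the
  calcification artifact; plus per-vertex correspondence distances between
  levels and Dijkstra geodesic distances on the mesh edge graph.
- **Three-element Windkessel outlets (3WKM)** — the RCR relation
  `(1 + Rp/Rd) Q + C Rp dQ/dt = C dP/dt + P/Rd` integrated with implicit
  Euler, with area-based allocation of the overall parameters over the
  outlets: `Rp_i = R̄p·A_tot/A_i`, `Rd_i = R̄d·A_tot/A_i`,
  `C_i = C̄·A_i/A_tot`, and converters for the clinical units
  kg·cm⁻⁴·s⁻¹ / kg⁻¹·cm⁴·s².
- **Wall motion** — RBF mesh morphing (augmented interpolation system with
  affine reproduction; Wendland C2 / polyharmonic / Gaussian kernels),
  periodic cubic-spline interpolation between gated phases, and a
  Laplace-law estimate of the effective wall Young's modulus from diameter
  pulsation.
- **Flow surrogate** — a quasi-static Poiseuille branch network coupled to
  the Windkessel outlets (mass-conserving junction solve each time step),
  providing per-branch flows, outlet pressures, and Poiseuille WSS
  `τ_w = 4 μ Q / (π r³)` with an inner-curvature enhancement on the arch.
  This stands in for a 3D Navier–Stokes solver — it exists to drive the
  descriptor machinery, and externally computed per-face WSS series can be
  loaded through the same interfaces.
- **WSS descriptors** — `TAWSS = (1/T)∫₀ᵀ |WSS(t)| dt` by trapezoidal
  quadrature, area-weighted region statistics (box-plot summaries),
  unfolded circumferential × longitudinal maps of the ascending aorta, and
  the study driver contrasting smoothing levels, phases p0/p4, and
  rigid vs moving wall.

## Worked example

```sh
python analysis/05_uncertainty_study.py
```

prints (seed 42, default study conditions):

```
Systolic-peak WSS on the ascending wall (Pa):
configuration   min    q1  median    q3   max  mean
 S_L/p0/rigid 0.958 1.019   1.049 1.347 1.978 1.132
 S_M/p0/rigid 0.958 1.019   1.049 1.340 1.446 1.115
 S_H/p0/rigid 0.946 1.010   1.043 1.332 1.443 1.107
 S_M/p4/rigid 0.724 0.766   0.789 1.031 1.119 0.841
S_M/p0/moving 0.862 0.915   0.941 1.213 1.312 1.004

Smoothing: S_L IQR 0.328 Pa exceeds S_M 0.321 and S_H 0.322 — the light level
keeps the calcification bump and residual noise.
Phase: systolic geometry (dilated lumen) lowers mean systolic WSS from 1.11 to 0.84 Pa.
Wall treatment: moving wall shifts cycle-mean WSS by -10.2% (radius-law oracle -10.5%).
```

Reading this: the lightly smoothed surface (S_L) retains the calcification
bump, which shows up as a higher WSS maximum (1.98 vs 1.45 Pa) and a wider
interquartile range; after artifact removal (S_M) a further smoothing pass
(S_H) changes little. Segmenting at systole (p4) dilates the lumen and
lowers WSS across the board. Letting the wall move redistributes WSS over
the cycle exactly as the Poiseuille radius law predicts, since the radius
is largest when the flow peaks.

The other drivers (`analysis/01…04`) generate the geometry, quantify the
smoothing distances (the S_L→S_H maximum localizes on the removed
artifact), allocate and integrate the Windkessel outlets, and write the
flow split, descriptor tables and the unfolded ascending-aorta map. All
tables land in `results/`.

A CLI mirrors the pipeline stages for shell use:

```sh
aorta-uq synth --config cfg.yaml --out dir/     # phase meshes + waveform
aorta-uq smooth --in raw.stl --labels labels.json --level SH --out sh.stl
aorta-uq distance --a a.stl --b b.stl --mode correspondence --out d.vtp
aorta-uq wk --config cfg.yaml --waveform w.csv --out wk/
aorta-uq morph --phases dir/ --t 0.25 --out mesh_t.stl
aorta-uq study --out report/
```

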