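# Methods

This note records the models, the numerical choices, and the reasoning
behind the parameters this package ships with. Geometry is in millimetres;
physical quantities are SI internally (m³/s, Pa, s), converted at the I/O
boundary. Clinical units (mmHg; kg·cm⁻⁴·s⁻¹ and kg⁻¹·cm⁴·s² for Windkessel
parameters) are accepted through explicit converters
(1 mmHg = 133.322 Pa; 1 kg·cm⁻⁴·s⁻¹ = 10⁸ Pa·s/m³;
1 kg⁻¹·cm⁴·s² = 10⁻⁸ m³/Pa).

## Synthetic anatomy

The generator emulates the *structure* of a gated-CT aortic dataset, not any
patient: a semicircular arch (centerline radius R = 30 mm, lumen radius
r = 12.5 mm) continuing into a straight descending tube (60 mm), with three
branch tubes on the arch apex (BCA 5.5, LCC 4.0, LSUB 4.5 mm radius at arc
angles 55°/90°/125°). These are literature-typical adult dimensions and are
configurable; they are not calibrated to any dataset. The main tube is a
structured ring×circumference grid; each branch is attached by carving a
rectangular patch of grid quads and lofting a tube from the hole perimeter
to a circular outlet rim, which keeps the surface edge-manifold with exactly
five boundary loops (Euler characteristic −3). With zero noise and zero
bump the main-tube vertices lie exactly on the analytic torus/cylinder
surface, which the tests use as ground truth.

Imaging imperfections are modeled as (i) seeded uniform noise of ±0.2 mm
applied along the analytic surface normals (CT voxel-scale roughness; rim
vertices are excluded so outlet cross-sections stay planar), and (ii) one
smooth, compactly supported indentation of 1.5 mm depth on the inner
ascending wall, standing in for a calcification artifact. The bump's
longitudinal half-extent is 7 mm — a realistic focal calcification size,
chosen also so that a straight-cylinder fit remains a valid local reference
on the curved arch (the chord-sagitta error of a cylinder against a torus
grows with the square of the patch length). Faces displaced by more than 2%
of the bump height carry the `artifact_patch` label; a full-circumference
band over arch angles 8°–52° carries `ascending_patch` and is the analysis
region (the WSS statistics of the study are taken over the union of the
two, i.e. the whole ascending luminal wall, artifact area included).

Wall motion: ten phases over the R-R interval at 77 bpm (inter-phase step
77.9 ms, rounding to 78 ms). Every vertex moves along its stored radial
direction by `r·p·s(t)` with pulsation fraction p = 0.1 (physiological
aortic distension) and `s(t)` a piecewise raised cosine that is 0 at the
cycle ends and 1 at phase 4 of 10 — the systolic phase. The inlet waveform
is a raised-cosine systole occupying one third of the period with zero-flow
diastole, rescaled so the trapezoidal cycle integral reproduces the cardiac
output (4.5 l/min → 58.44 ml/beat) exactly up to rounding. The real
ECHO-derived waveform shape is unpublished; only its integral constraints
are stated, so the shape is a modeling choice.

## Smoothing strategy

The Taubin filter alternates a positive (λ) and a negative (μ) step of the
uniform umbrella Laplacian. The classic parameterization needs (λ, μ); the
workflow this mirrors reports a single weighting factor w = 0.5 and n = 15
iterations, so we set λ = w and pair it with the standard stable μ = −0.53
(pass-band ≈ 0.11), counting n as λ/μ pairs; both are exposed in
`TaubinConfig`. The uniform (combinatorial) umbrella is used rather than
cotangent weights: it matches common vascular-toolkit practice and is robust
on noisy meshes. Rim vertices are always pinned; region-restricted smoothing
additionally freezes everything outside the region plus a one-ring
transition band. On an icosphere the pairing demonstrably removes radial
noise while shrinking volume by an order of magnitude less than an
equal-iteration pure Laplacian — the "shape-preserving" property the tests
assert.

**Artifact removal** is this package's defined surrogate for a manual,
clinician-guided correction whose exact procedure is unrecoverable. The
labeled patch (dilated by one face ring, so nothing outside the patch and
its one-ring ever moves) is referenced to a least-squares cylinder fitted to
its surrounding wall: the axis from the smallest-variance direction of the
normal covariance, the position and radius from a linear Kasa circle fit in
the orthogonal plane (a nonlinear refinement proved less stable on partial
arcs and is unnecessary here). Because a straight cylinder cannot represent
the arch's curved wall, the smooth radial trend of (radius − r_fit) is
fitted as a quadratic over the cylinder's parameter plane from the
artifact-free context ring; the *artifact* is the interior excess over the
harmonic extension of the boundary residuals. If that excess is below the
tolerance (0.25 mm, about the residual-noise scale after one Taubin pass)
the mesh is returned unchanged — so an artifact-free wall is a fixed point
of the operation. Otherwise the patch interior is over-smoothed with
boundary-fixed Laplacian iterations (killing high-frequency noise; a
Taubin pass-band filter cannot remove the bump, whose patch-scale mode lies
below the pass-band) and the radial profile is replaced by trend + harmonic
residual. On the default geometry this flattens the 1.5 mm bump to within
0.22 mm of the analytically known bump-free wall.

Two distance notions are shipped because "distance between geometries along
the surface" is ambiguous: the between-mesh per-vertex correspondence
distance (meshes share topology through the whole chain), and the on-mesh
Dijkstra geodesic distance on the edge graph (edge weight = Euclidean
length; computed with `scipy.sparse.csgraph`, cross-checked against a
brute-force relaxation solver in the tests). The S_L→S_H correspondence
maximum localizes on the artifact patch; away from the branch ostia (where
smoothing legitimately rounds corners) the clean-geometry chain drifts by
less than 1% of the lumen radius.

## Windkessel outlets

Each outlet follows the RCR relation
`(1 + Rp/Rd) Q + C Rp dQ/dt = C dP/dt + P/Rd`. Time integration is implicit
(backward) Euler — unconditionally stable for the stiff Rd·C time constants
that arise when the model is stepped once per time step by an external flow
solver — with dQ/dt from periodic central differences of the waveform.
First-order convergence is verified against the closed-form step response
`P(t) = Q₀(Rp+Rd)(1−e^{−t/RdC}) + Q₀Rp e^{−t/RdC}`. `pressure_step` is the
single-call contract a flow solver uses; `solve_3wkm` wraps it and, by
default, first solves the one-cycle affine map of the discrete scheme for
its fixed point, so the returned cycles carry no start-up transient (the
three-cycle convention then trivially suffices; a cold start decays
geometrically at e^{−T/RdC} per cycle, which the tests measure).

The overall parameters (R̄p, R̄d, C̄) are config inputs; the defaults place
the total resistance at a 93 mmHg mean pressure for 4.5 l/min, split 10%
proximal / 90% distal, with C̄ = 10⁻⁸ m³/Pa (≈1.3 ml/mmHg systemic
compliance, Rd·C ≈ 1.5 s). Allocation over outlets is by rim area
(`Rp_i = R̄p·A_tot/A_i`, `C_i = C̄·A_i/A_tot`), with areas computed from the
labeled rim polygons of the mesh so the split is mesh-consistent. The rule
implies outlet-independent Rd/Rp and C·Rp ratios; a validator flags
parameter sets violating them (the shipped clinical-unit fixture set
contains one such row, LCC, which is flagged rather than corrected).

## Wall motion and material

RBF morphing solves the augmented interpolation system (kernel matrix plus
full affine block) so every control displacement is reproduced exactly and
any affine — in particular rigid — field is reproduced globally. The default
kernel is compact Wendland C2 with support 0.75 of the control-cloud
bounding-box diagonal (large enough for robust conditioning, finite so
distant points see only the affine part); polyharmonic r³ and Gaussian
kernels are alternatives. Duplicate control points are rejected by name.
Control points default to all wall vertices at desk scale. Temporal
interpolation across phases is a periodic cubic spline per vertex
coordinate — exact at the knots, local, and with no Gibbs artifacts; the
alternative of a single space-time RBF solve over all phases is noted but
not taken. Morphing the synthetic case at pulsation ≤ 0.2 inverts no
triangles.

The effective Young's modulus uses the incremental thin-wall Laplace form:
Δσ = (P_sys·D_sys − P_dia·D_dia)/(2t), ε = (D_sys − D_dia)/D_dia,
E = Δσ/ε, with t = 2 mm by default. With 120/80 mmHg and the synthetic 10%
diameter pulsation this gives E ≈ 0.43 MPa — a physiological magnitude.
The exact algebra behind published estimates of this kind is usually
unstated; the incremental form is the one a gated diameter pair plus cuff
pressures supports.

## Flow surrogate and WSS

No Navier–Stokes equations are solved. The surrogate is a one-junction
resistance network: each outlet branch has Poiseuille resistance
8μL/(πr⁴) (blood: ρ = 1060 kg/m³, μ = 0.0035 Pa·s, laminar — a Reynolds
helper warns above 4000), and at every implicit step the junction pressure
solves the nodal balance with each outlet eliminated through its
backward-Euler Windkessel update, making mass conservation exact to machine
precision. Wall shear stress is the Poiseuille wall value 4μQ/(πr³)
evaluated per face with the *instantaneous local radius* (from the phase
interpolant in moving-wall mode), so wall motion rescales WSS by
(r₀/r_t)³ by construction. Main-tube faces up to the last branch carry the
full inlet flow; beyond it, the descending-branch flow. On the arch, faces
on the inner half are enhanced by (1 + κ·r_local), κ = 1/R the centerline
curvature — a deliberately simple stand-in for the inner-curvature WSS
hot spot of curved-pipe flow; the coefficient is configurable. The
surrogate's absolute WSS level (~1 Pa at systole) is below patient-scale
CFD values, as expected for fully developed Poiseuille flow; the study's
conclusions are orderings and ratios, which is what the surrogate is for.
A reader for externally supplied per-face WSS series (VTP) provides the
seam where a real CFD solution would enter.

## Descriptors and the study

TAWSS is the per-face trapezoidal cycle average of |WSS| (33 samples over
the cycle in the study — the integrand is smooth, and doubling the sampling
changes the study numbers in the fourth digit). "Systolic WSS" is the field
at the time of peak inlet flow. Box statistics are computed per element,
unweighted (quartiles by linear interpolation of order statistics, Tukey
1.5·IQR whiskers clamped to the data range), while the reported "avg" is
area-weighted; both conventions are emitted because published figure
captions rarely state the weighting. Unfolded maps assign each face
centroid the arclength of its nearest centerline point and the angle of its
offset in a parallel-transported frame (double-projection transport; the
angular zero is the transported reference direction), then resample by
nearest face onto a regular grid — values are relocated, never recomputed.
Patches covering under 300° of angle are rejected as non-tubular. For the
synthetic case the analytic centerline is used; for imported meshes a
user-supplied centerline polyline is required (a full centerline extractor
is out of scope).

The study matrix is five configurations: S_L/S_M/S_H at the diastolic
geometry (rigid), the systolic-phase geometry at S_M (rigid), and S_M with
the moving wall. Each runs geometry → areas → allocation → three flow
cycles (200 steps/cycle, last cycle kept) → descriptors on the ascending
region → summaries and pairwise contrasts of means and IQRs. A fixed
config and seed reproduce the report bit-for-bit.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* of gated-CT data —
topology-identical phases, rim-labeled outlets, noise and a focal artifact —
but not its failure modes: no segmentation topology errors, no
through-plane resolution anisotropy, no real calcification geometry, and
wall motion that is purely radial and spatially uniform. The flow surrogate
omits inertia, secondary flow and entrance effects entirely. Green tests
therefore certify the pipeline machinery (filters, solvers, allocators,
descriptors and their contracts) and the direction of the studied effects
under Poiseuille scaling — not patient-level WSS magnitudes.

## Numerical choices and degenerate inputs

Tolerances: RBF interpolation residual ≤ 10⁻⁸ mm (dense solve); allocation
conservation to 10⁻¹² relative; waveform calibration to 0.1%;
artifact-removal tolerance 0.25 mm. Degenerate inputs are rejected early
with named errors: zero-area triangles, non-manifold edges, boundary edges
off labeled rims, overlapping branch placements, pulsation collapsing the
smallest local radius, empty artifact patches or patches touching a rim,
duplicate RBF controls, zero Laplace-law strain, dt failing to resolve the
cycle. Ties in the unfolded-map resampling fall to the nearest face in the
embedded metric; the quartile convention is linear interpolation.
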