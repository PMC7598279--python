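# Methods

## Reference-cylinder shape analysis

Every lumen surface is an open-ended triangle mesh in mm, with the axial
(cranio-caudal) direction fixed to +z. Height is the axis-aligned extent of
the vertex projections — a single scalar distance, not a centerline arc
length. The side surface is the plain sum of triangle areas, which is why
generated meshes are open tubes and externally supplied capped STLs must
pass through `strip_caps` (cap faces = normal within 15° of ±axis and
centroid within 1% of the axial extremes). The enclosed volume closes open
boundary loops with planar centroid fans and takes the orientation-
normalised divergence-theorem sum; disconnected closed components (the
bifurcated grafts) contribute the sum of their absolute volumes.

The reference cylinder of an object of height h and side surface A has
diameter d = A/(πh); the package enforces πdh = A to 1e-9 relative as a
type invariant. The shape factor is defined as

    phi_ref = V_reference_cylinder / V_object.

No closed-form convention is canonical for this quantity; the volume ratio
was chosen because it is exactly 1 for a right cylinder, is scale
invariant, and exceeds 1 for aneurysmal and bifurcated lumens, which
matches how the factor is used downstream (larger = further from a
cylinder). Pairwise comparison of an aneurysm and a graft uses a *common*
height (the aneurysm's) for both reference cylinders; the pair factor
phi_A-S is the ratio of the two reference side surfaces and is exposed in
both orientations (aneurysm/graft and graft/aneurysm) because both ratios
are useful in reports — the package never guesses which one a caller
means.

Mesh hygiene at load time: vertices are merged on a 1e-6 mm quantisation
grid and faces with repeated indices or area below 1e-12 mm² are dropped.
The binary STL writer emits the canonical 84 + 50·n byte layout and is
byte-deterministic, which the reproducibility guarantees below rely on.

## Synthetic anatomy

The generator emulates the *shapes* of a post-EVAR cohort, not any
patient's anatomy. The AAA is a surface of revolution
r(z) = r_neck + (r_sac − r_neck)·w(z) with w a C¹ cosine-tapered window
(center 0.5, width 0.5 of the height by default); smoothness avoids
meshing artifacts at the sac shoulders. Defaults are surgical-scale: neck
Ø 20 mm, sac Ø 55 mm (the intervention-threshold diameter), height 130 mm,
limb Ø 12 mm, bifurcation opening angle 30°. The stent-graft is its
luminal surface only — a trunk of neck radius for body_frac·height, then
two limbs modelled as *sheared* tubes whose horizontal cross-sections stay
circles of the limb radius while the ring centres follow the tilted limb
axes. The shear keeps (a) the total height of AAA, long and short grafts
exactly equal per patient (the common-height convention holds to 1e-6 mm
by construction) and (b) horizontal slice areas exactly circular, so the
quasi-1D reduction below is well posed through the bifurcation. Long and
short configurations differ only in body_frac (0.6 vs 0.25 of the
height).

Cohort jitter is multiplicative log-normal (σ = 0.1 by default) with one
RNG stream per patient id (seeded by (cohort_seed, patient_id)), so a
patient's geometry does not depend on cohort size or ordering. After
jitter the radius ordering (sac > neck > limb) is re-imposed by clipping;
fractions are clipped to (0.05, 0.95).

What the generator does *not* emulate: vessel curvature and tortuosity,
non-circular cross-sections, intraluminal thrombus, wall thickness, graft
struts and fabric texture, and patient-specific neck angulation. Tests
passing on this family therefore demonstrate correctness of the geometric
and hemodynamic *operators*, and plausibility of cohort-level trends — not
agreement with any clinical measurement.

On the default 20-patient cohort the mean shape factors come out near
1.05 (AAA), 1.32 (SL) and 1.70 (SS), and graft/aneurysm volume ratios near
0.37/0.32 — the same ordering and scale a clinical cohort of this kind
exhibits. Individual jittered patients with a shallow sac can have an AAA
shape factor marginally below 1 (the discrete bulge then adds slightly
less lateral area than the volume it removes); this cohort-level
expectation is reported, not asserted.

## Hemodynamic surrogate

A full 3D Navier–Stokes solve is out of scope by design. The surrogate
keeps the same physical assumptions (incompressible, laminar, rigid walls,
velocity inlet) but applies them quasi-statically in one dimension:

1. **Tube reduction.** At each of n_stations (default 40) axial positions
   strictly inside the mesh extent (0.5% margins), the plane-slice
   cross-section area is measured from the triangle/plane intersection
   segments via Green's theorem — segments are oriented by the face
   winding, so no loop chaining is needed — and converted to the
   equivalent-circle radius. Below a bifurcation the limb sections sum,
   giving the equivalent single tube.
2. **Rheology.** Quemada: μ = μ_p (1 − ½ k(γ̇) Hct)⁻²,
   k = (k₀ + k_∞ √(γ̇/γ̇_c)) / (1 + √(γ̇/γ̇_c)). Defaults μ_p = 1.2 mPa s,
   k₀ = 4.33, k_∞ = 2.07, γ̇_c = 1.88 s⁻¹, Hct = 0.40, ρ = 1050 kg/m³ —
   literature-typical values, all configurable. k₀ = k_∞ degenerates to a
   Newtonian fluid, which the test oracles exploit.
3. **Wall shear.** Per time step, Q(t) = v(t)·π·R_inlet² (one Q for all
   stations); per station, τ_w solves the Rabinowitsch–Mooney relation
   Q = (πR³/τ_w³)∫₀^{τw} τ²γ̇(τ) dτ. Implementation: substituting the
   shear rate for τ turns the integral into a function of the wall shear
   rate only, and the reduced flow q = Q/(πR³) is tabulated once per fluid
   on a 2000-point logarithmic shear-rate grid (1e-6–1e8 s⁻¹) with
   8-point Gauss–Legendre panels, then inverted by log-log interpolation
   plus bracketed Newton refinement to 1e-12 relative — cheap enough to
   vectorise over all stations and time steps. Below the grid the
   zero-shear Newtonian limit applies; above it the solver raises (no
   silent extrapolation). Reverse-flow samples enter as |Q|, so WSS is a
   magnitude.
4. **Aggregation.** The series value is the side-surface-weighted mean
   over stations (weights ∝ radius × spacing); the cycle total is the
   arithmetic mean over the n uniform steps (the time integral divided by
   the period, keeping Pa); drag force is WSS_tot × side surface.

Waveform templates (flat plateau; sharp = raised-cosine systolic peak of
width 0.25 T on a 10% baseline; real = triphasic with one reverse-flow
interval) are parametric stand-ins for Doppler-derived profiles: shapes
are physiological, amplitudes (peak 0.5 m/s, period 1 s, 64 steps/cycle by
default) are typical of the abdominal aorta. At 64 steps the cycle totals
are within 0.5% of the 256-step values for these templates.

Consequences worth stating: surrogate WSS magnitudes are order 0.1–1 Pa,
*not* comparable to 3D CFD patch values (no attempt is made to match any
absolute WSS number); only between-geometry and between-condition
comparisons are meaningful. Because τ_w ~ 1/R³ at fixed Q, the aneurysm
sac always lowers mean WSS relative to the neck, and the narrower graft
lumens raise it — which is the behaviour that drives every downstream
ratio.

## Risk layer

phi_WSS = WSS_aneurysm / WSS_graft per graft and condition. The verdict
rule — lower cycle-mean drag across all requested waveforms wins, with a
1% relative indifference band — is a package choice: the comparison is
prescribed by the method, the threshold is not, and without a band the
identical-graft edge case would be decided by rounding noise. The cohort
regression pairs the geometry ratio (graft volume / aneurysm volume, the
quantity whose cohort mean sits near 0.3) as ordinate against the cycle
WSS ratio (graft/aneurysm) as abscissa, one OLS row per graft type per
condition (six rows for the default three waveforms). On the default
cohort all six slopes are negative.

## Imaging QA

The phantom is a bright sphere (or axial tube) on a uniform background
with seeded Gaussian noise; defaults (object 249, background 205, σ = 10,
64³ voxels at 0.8×0.78×0.78 mm) sit in the clinical image-quality regime
BI ≈ 24.9, CNR ≈ 4.4. Region growing is 6-connected and grows in
breadth-first dilation layers against the *running region mean* with a
fixed intensity tolerance until a fixed point; with tolerance 3σ the
segmented volume lands within 5% of ground truth at the default contrast.
Hole filling is morphological interior-cavity filling (idempotent, never
removes foreground). Noise defaults to the pooled SD of two 100 mm²
outside-body ROIs; the alternative literal reading (ROI mean over ROI SD)
is available as `noise_mode="mean_over_sd"`. ROIs are in-plane discs of
the protocol areas (80/100 mm²), averaged across slices. DICOM series and
NIfTI/raw volumes can be ingested, but all tests run on generated
phantoms.

## Statistics

Summaries are mean ± SEM (sample SD/√n). Pearson and Spearman (mid-rank
ties) correlations report two-sided p-values; OLS reports slope/intercept
standard errors with n−2 df. p < 0.05 is the reported significance
threshold, never a data filter; Benjamini–Hochberg adjustment exists
behind an explicit call and is off everywhere by default.

## Numerical choices and degenerate inputs

- Vertex merge grid 1e-6 mm; degenerate-face area cutoff 1e-12 mm².
- Non-manifold boundaries that cannot be fan-capped fall back to trimesh
  hole filling + normal repair; if winding cannot be made consistent the
  volume computation raises rather than returning a signed artifact.
- Rabinowitsch–Mooney tolerance 1e-12 relative on the wall shear rate;
  the Newtonian and power-law closed forms are reproduced to ~1e-9.
- Empty meshes, zero heights, zero flow, zero noise, constant-x fits and
  out-of-volume ROIs/seeds all raise typed errors naming the violation.
- Default problem sizes (20 patients, 96×128 mesh segments, 40 stations,
  64 time steps) keep the full pipeline around half a minute on one CPU
  while staying inside the convergence plateaus noted above.

## Known limitations

The surrogate cannot capture secondary flows, recirculation at the
bifurcation, or fixation-zone pressure loads, all of which contribute to
real migration risk; the verdict is a geometry-driven screen, not a
clinical prediction. The cohort generator's jitter model is uncorrelated
across parameters, whereas real anatomy correlates neck, sac and height.
BI/CNR on the phantom assume stationary Gaussian noise, unlike streak or
beam-hardening artifacts in clinical AngioCT.
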