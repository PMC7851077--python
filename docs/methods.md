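# Methods

## Scope and intent

`vertfe` studies how imaging conditions change QCT-based finite-element
(FE) predictions of vertebral compressive strength.  All experiments run on
synthetic phantoms, so every comparison in this package is *relative*:
condition A versus condition B on the same phantom, or cohort versus
cohort under identical settings.  Absolute failure loads depend on choices
(loading magnitude, damage law, phantom intensities) that are calibratable,
not measurable, at phantom scale.

## Phantom generator

A phantom is an elliptic-cylinder vertebral body (default half-axes
18 × 14 mm, height 28 mm — adult lumbar scale) with:

* a cortical shell of thickness 1.5 mm at 600 HU (walls and endplates);
* a trabecular interior modeled as a stationary Gaussian random field:
  white noise smoothed by a Gaussian kernel of width equal to the
  correlation length (default 3 mm), then standardized over the interior
  voxels and rescaled, so the interior sample mean and SD are *exactly* the
  requested 180 ± 50 HU.  HU in this range keeps the density–modulus
  relations positive;
* optionally a simplified posterior arch: two pedicle columns with
  elliptical cross-section, a bridging lamina plate and a spinous block,
  all labeled 2 and set to 75% of the shell HU.  The arch reproduces the
  load-path *topology* (body ↔ posterior arch), not the anatomy; that is
  sufficient for studying whether including posterior elements changes the
  predicted strength;
* background soft tissue at −80 HU.

Contrast enhancement adds a smooth random offset field (standardized over
the labeled voxels, so the sample mean equals the requested enhancement
exactly) to labeled voxels only.  The default +30 HU is a free parameter of
the generator: clinical literature reports contrast-induced attenuation
increases in bone of a few tens of HU, but no single canonical value
exists.

Slice-thickness degradation averages groups of `factor` consecutive slices
(partial-volume model) and multiplies the spacing; the label mask is
resampled by per-voxel majority vote with ties going to foreground (and
body over posterior), which preserves thin shells better than rounding the
mean.  Resampling is applied along a horizontal axis to mimic sagittal
reformation.

Cohorts are matched pairs: both members share the same noise seed; the
weakened member's trabecular and shell HU are scaled so the density-derived
strength drops by the requested fraction d.  Because the strength power
laws have exponents 1.72–1.93, the apparent density is scaled by
(1−d)^(1/1.8); the measured failure-load decrement lands within a
percentage point of the target.  Between-pair variability is a 10% CV
jitter of the HU level (truncated at ±2 SD), giving failure-load spreads of
roughly 7–10% CV, comparable in order to clinical cohorts.

What the phantoms do **not** emulate: endplate concavity and real process
geometry, scanner noise spectra and beam hardening, fracture deformation,
and HU calibration offsets.  Passing tests therefore demonstrate the
pipeline's internal correctness and the *direction and structure* of
condition effects, not clinical effect sizes.

## Meshing

The labeled region is coarsened to cubic cells of side equal to the target
edge length, on a lattice anchored at the grid origin; voxels are assigned
to cells by their centers, a cell is kept when at least half of its
assigned voxels are foreground (ties kept), and each kept cell is split
into the six Freudenthal tetrahedra sharing the cell's main diagonal.  The
identical split in every cell makes all shared faces conforming with no
parity bookkeeping.  Element labels (body/posterior) follow the majority of
the cell's foreground voxels, ties to body.  When the edge equals the voxel
spacing, cells coincide with voxels and the mesh volume equals the
voxel-counted mask volume exactly.  The stair-step surface is not smoothed:
it is deterministic, and comparisons are internal to the pipeline.

Boundary node sets (`inferior_body`, `superior_body`) are the nodes of
body-labeled elements within a band (default 2% of the body z-extent — one
node layer at coarse meshes) of the body's extreme z, excluding any node
shared with posterior elements, so the virtual platens never touch the
arch.

## Material mapping

Per element, the mean HU over the voxel centers it contains (falling back
to the voxel nearest the centroid for sub-voxel elements) feeds the
density → modulus/strength chain listed in the README.  Units are a
consistent mm–MPa–N system; apparent density is in mg/cm³ (the affine
HU-relation only yields physiological values there) and ash density in
g/cm³ (the 0.317 branch threshold and the power laws require it).  The
branch boundary ρ_ash = 0.317 is assigned to the 1.72-exponent branch; the
two branches differ by <2% there.  Clamps: density floor 1 mg/cm³, modulus
floor 0.01 MPa, ε_AB floor 0 — the affine forms go negative at fat/marrow
HU and the solver needs positive stiffness.

When the pipeline maps a mesh it first replaces background voxels by the
HU of their nearest labeled voxel.  Without this, stair-step boundary
elements average in surrounding soft tissue (−80 HU) and acquire a
spurious weak "skin" whose volume grows with the element size, which makes
the failure load strongly mesh-dependent; with the masked fill the failure
load changes by only a few percent between 2 mm and 1 mm meshes.  The
low-level `element_mean_hu` remains a pure image operation.

Poisson ratios are not part of the HU chain; defaults are ν_xy = 0.381 and
ν_xz = ν_yz = 0.104 (x→z sense), which give a symmetric positive-definite
transversely isotropic tensor across HU ∈ [−200, 2000] (verified by
eigenvalue sweep); if a caller supplies ratios that break positive
definiteness the mapping falls back to isotropic ν = 0.3 with a warning.
Because all moduli are fixed ratios of E_z and the ratios are constant, an
element's 6×6 tensor is E_z times a precomputed unit tensor — this makes
assembly and damage updates cheap.

## Failure solver

Linear constant-strain tetrahedra, small strains, static equilibrium,
sparse LU factorization (SuperLU/COLAMD) of the constrained stiffness.  The
inferior platen is fully fixed; the superior platen is driven in z and held
in x, y (platen loading — the lateral constraint is stated explicitly
because compression rigs grip the endplate).  Default loading: total
compression of 0.4% of the body height over 16 equal increments.  With the
material relations above, the apparent yield strain is near 0.1%, so this
schedule places the force peak in the interior of the curve with ~2-6%
increment resolution; a nominally larger ramp (e.g. 1.9%) merely spends
increments far past the collapse.

Damage is brittle knockdown: after each converged solve, elements with
σ₁ > σ_max or σ₃ < −σ_min (strict inequalities, so ties never fail —
deterministic under exact arithmetic) are marked failed and their stiffness
is multiplied by 0.01; the increment is re-solved until no new failures or
an iteration cap (default 10 per increment; violators remaining at the cap
are caught at the next increment and a warning is recorded).  Failed
elements stay failed, so the failed set is non-decreasing.  ε_AB is
computed and exported, and can optionally serve as an axial-strain failure
cap, off by default: the brittle principal-stress criterion alone
reproduces the "peak of the force–displacement curve" semantics with a
deterministic, testable algorithm, whereas a full plasticity law is out of
scope.  The run stops early once the force falls below 80% of the running
peak; the failure load is the recorded peak.

Within one damage state the response is linear, so each state is factorized
once and the solution at any displacement fraction is obtained by scaling;
refactorization happens only when elements fail.  Equilibrium (driven-set
force + fixed-set force = 0) holds to ~1e−14 relative with the direct
solver; the tests require 1e−8.

Two exact invariants anchor the solver: (i) the constant-strain patch test
— linear boundary displacements reproduce a uniform stress field to 1e−8
and the closed-form platen reaction; (ii) load-path homogeneity — scaling
all stress limits *and* the prescribed displacement by k scales every
reaction exactly by k with an identical failure sequence (with k = 2 the
scaling is exact even in floating point).  Note the displacement must scale
along with the limits: under a fixed displacement schedule, scaling the
limits alone only delays failure, because the stresses are set by the
prescribed displacement.

## Experiments and statistics

* **Condition grid**: per phantom, the 2×2 grid {thin/thick slices} ×
  {plain/contrast}.  Subjects differ by seeded noise plus whole-bone size
  (8% CV) and density (12% CV, shell and trabecular together) jitter,
  giving a between-subject failure-load spread of roughly 15–20% CV — the
  order seen in clinical vertebral cohorts, and large enough that protocol
  comparisons measure agreement rather than discretization noise.  Thick-
  slice data cannot be meshed finer than its slice spacing, so those cells
  use the larger of the configured edge and the spacing.  Agreement between conditions is summarized by OLS R²
  (the squared Pearson correlation) and Bland–Altman bias ± 1.96·SD limits,
  with differences oriented condition-minus-reference (contrast − plain,
  thick − thin), so positive bias means the condition reads higher.
* **Posterior elements**: same phantom with and without the arch label — a
  perfectly paired design — with a paired two-tailed t-test and percent
  differences (reference = without).  A second try with reseeded trabecular
  noise gives the RMSCV reproducibility (CVs use sample SD, n−1); with
  identical seeds the repeats are bit-identical and RMSCV is exactly 0.
* **Cohort**: nine matched pairs at a 15% designed strength decrement,
  paired t-test (the matched design is the reason for pairing; Welch's
  test is used for genuinely independent groups).
* **Mesh sensitivity**: edge lengths 1.0–3.0 mm in 0.5 mm steps; the 2 mm
  mesh is adequate — the failure load changes by only a few percent between
  2 mm and 1 mm.  Edges incommensurate with the voxel lattice (1.5,
  2.5 mm) sit a little lower because the jagged cross-sections concentrate
  stress; this is reported, not hidden, and the convergence comparison is
  made on the commensurate 2 mm → 1 mm pair.

Degenerate statistics conventions: zero-variance samples with equal means
give p = 1; zero-variance nonzero differences give t = ±inf, p = 0 with a
`degenerate` flag.  Percent difference is not antisymmetric (+5% one way is
−4.76% back), so the reference is fixed per experiment.

## Problem sizes

Solver-heavy checks run on geometrically reduced phantoms chosen once:
"small" (half-axes 12 × 9 mm, height 18 mm) for the paired condition and
posterior experiments at 2.5 mm edge (~4–6k elements per run), and "tiny"
(9 × 7 mm, height 12 mm) for the cohort power study and the 1 mm
mesh-refinement runs (~14k elements at 1 mm).  The default adult-scale
phantom (~17k elements at 2 mm) is used for the single-run equilibrium and
direction checks.  The cohort power test uses 20 reseeded replicates of 9
pairs each.

## Known limitations

* Brittle knockdown ignores post-yield hardening; failure loads are lower
  than an elastoplastic model would give and the post-peak branch is only
  qualitative.
* The structured-lattice "edge length" is the cell side, not the maximum
  edge of a body-fitted mesh; the two metrics coincide only in order of
  magnitude.
* HU is used uncalibrated (no BMD calibration phantom); all densities are
  nominal.
* One loading configuration (axial platen compression).  Bending, flexion
  and contact with discs are out of scope.
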