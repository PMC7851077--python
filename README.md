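# vertfe — QCT-style finite-element vertebral strength on synthetic phantoms

`vertfe` implements the standard clinical-CT-to-bone-strength pipeline —
image + segmentation mask → tetrahedral mesh → Hounsfield-unit-based
material mapping → displacement-controlled compression to failure — and the
agreement statistics used to compare the predicted strength across imaging
conditions.  It is aimed at researchers who want to study *methodological*
effects on QCT-based finite element analysis (slice thickness, intravenous
contrast enhancement, inclusion of the posterior elements, cohort strength
differences) without patient data: a seeded synthetic vertebra phantom
generator stands in for the scans.

## The model

Each element's material is derived from its mean Hounsfield value HU:

```
ρ_app  = 47 + 1.122·HU                     apparent density [mg/cm³]
ρ_ash  = 0.6·ρ_app                         ash density [g/cm³ after /1000]
E_z    = −349 + 5.82·ρ_app                 axial modulus [MPa]
E_x = E_y = 0.333·E_z                      transverse moduli
G_xy = 0.121·E_z,  G_xz = G_yz = 0.157·E_z shear moduli
σ_max  = 137·ρ_ash^1.88  (ρ_ash < 0.317)   tensile principal-stress limit [MPa]
       = 114·ρ_ash^1.72  (ρ_ash ≥ 0.317)
σ_min  = 65.1·ρ_ash^1.93                   compressive principal-stress limit [MPa]
ε_AB   = −0.00315 + 0.0728·ρ_ash           plastic strain parameter
```

The vertebra is meshed with linear (C3D4) tetrahedra on a structured
lattice (6 Freudenthal tets per cubic cell), given transversely isotropic
elasticity with the superior–inferior axis (z) as the material axis, fixed
at the inferior body surface and compressed by a prescribed displacement of
the superior body surface.  Elements whose principal stresses exceed their
limits (σ₁ > σ_max or σ₃ < −σ_min) lose their stiffness (brittle knockdown),
the increment is re-solved, and the **failure load** is the peak of the
resulting force–displacement curve.  Agreement between conditions is then
quantified with linear-regression R², Bland–Altman bias and ±1.96·SD limits
of agreement, RMSCV reproducibility, paired/Welch t-tests and percent
differences.

## Worked example

```python
from dataclasses import replace
import vertfe as vf

spec = replace(vf.DEFAULT_SPEC, include_posterior=True, seed=5)
img, mask = vf.generate_vertebra_phantom(spec)      # 40x49x32 voxel grid

mask_wo = mask.copy()
mask_wo.labels[mask_wo.labels == 2] = 0             # drop posterior arch

_, with_post = vf.compute_failure_load(img, mask, edge_mm=2.5)
_, without = vf.compute_failure_load(img, mask_wo, edge_mm=2.5)
print(with_post["failure_load"], without["failure_load"])
# 1044.3512878800999 914.1587731629266
print(vf.percent_difference(with_post["failure_load"], without["failure_load"]))
# 14.24177903817297
```

The default adult-lumbar phantom fails at ≈0.9 kN without and ≈1.0 kN with
the posterior arch: including the posterior elements raises the predicted
strength (here by 14%), because the arch provides a parallel load path past
the weakest trabecular region.  Adding +30 HU of simulated contrast
enhancement to the same phantom raises the failure load from 914 N to
1038 N — contrast inflates density-derived material properties, which is
exactly the bias the agreement analysis quantifies.

The numbered scripts under `analysis/` run the four experiments end to end
(mesh sensitivity, posterior-element effect, contrast × slice-thickness
grid, healthy-vs-weakened cohort) and write their tables under `results/`.

## Coordinate conventions

Volumes are 3D arrays with per-axis spacing (mm) and origin; the center of
voxel `(i, j, k)` is at `origin + (i+0.5, j+0.5, k+0.5)·spacing`.  Axis z
is superior–inferior (the material axis), and slice-thickness resampling is
applied along a horizontal axis, mimicking sagittal reformation.
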