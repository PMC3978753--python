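# meniscus-ssm

Cohort-level 3D statistical shape analysis of the lateral meniscus — the
crescent-shaped fibrocartilage between femur and tibia in the lateral knee
compartment. The package is aimed at musculoskeletal researchers who have
per-subject triangle surface models of the meniscus (segmented from MRI)
plus basic anthropometrics, and who want to know *which* aspects of
meniscal shape vary across a population and whether they track subject
size and loading.

## What it computes

Given a cohort of closed triangle meshes (PLY/STL/OBJ, mm):

1. **Correspondence** — every surface is rigidly aligned to a reference
   subject by iterative closest point (ICP); a multi-resolution cubic
   B-spline free-form deformation (FFD) then maps the reference surface
   onto each subject, so the reference vertices projected onto each
   subject give point-to-point correspondence on a shared topology.
2. **Point-distribution model** — each subject becomes a shape vector
   x = (x₁…xₙ, y₁…yₙ, z₁…zₙ). PCA of the sample covariance (normalised
   by N−1) yields the mean shape, orthonormal modes ("principal
   morphological variations", PMVs) and per-mode standard deviations λₖ.
   No size normalisation is applied, so PMV 1 is overall size.
3. **Morphometry** — on any shape (a subject or the model sampled at
   −2λ…+2λ along one mode): seven landmark distances (horn widths
   PH_Wid/AH_Wid, horn lengths PH_Len/AH_Len, inter-horn distance PA_Dis,
   peripheral thickness/width LPH_Thic/LPH_Wid), projected areas
   (tibial coverage Cov_Area, inter-horn gap Gap_Area, femoral contact
   Con_Area), and the derived indices

   Cov_Pct = Cov_Area / (Gap_Area + Cov_Area),
   Tcon_Area = Gap_Area + Con_Area,
   RDL = PA_Dis / (½ (PH_Len + AH_Len)),

   plus per-mode change rates Δf = (f₊₂λ − f₋₂λ) / f_mean.
4. **Statistics** — two-tailed Pearson tests of mode scores against
   height, weight, BMI, femoral condyle width and knee axial rotation,
   with Fisher-z 95% confidence intervals, in mixed and per-sex groups.

A parametric generator (`meniscus_ssm.synthetic`) builds crescent-shaped
cohorts with known latent modes (size, horn openness, horn-width taper),
linked anthropometrics and analytic ground truth, so the whole chain is
testable without any imaging data.

## Worked example

```python
from meniscus_ssm import (CohortSpec, generate_cohort, run_pipeline,
                          variance_explained)

cohort = generate_cohort(CohortSpec(n_subjects=20, seed=5))
result = run_pipeline(cohort.meshes)

print(result.model.mode_stddevs[:3])        # lambdas, mm
table = result.change_table(k_modes=3)      # percent change rates
corr = result.correlations(cohort.anthro, modes=(1,),
                           covariates=("height", "weight"),
                           groups=("mixed",))
```

prints (abridged):

```
modes: 19; first three lambdas (mm): 43.9, 25.1, 14.0
variance explained by first 3 modes: 99.8%

change rates (% between -2 and +2 SD):
      dCov_Area  dCov_Pct  dPA_Dis  dPH_Len  dRDL  dTcon_Area
mode
1         -44.0      -1.4    -27.5    -20.8  -6.2       -42.6
2           1.8      -5.1    -27.4      3.6 -30.0         6.9
3          19.1      11.3     10.9      4.2   5.2         7.7

mode-1 score vs anthropometrics (mixed group):
covariate  n      r     p
   height 20 -0.732 0.000
   weight 20 -0.656 0.002
```

Reading this: mode 1 moves every area by ~±44% and every distance by
~±21–28% while barely changing the coverage fraction — a size mode (the
sign of a mode is a convention; only |r| and the relative signs within a
row are meaningful). Mode 2 changes the inter-horn distance and RDL with
the horn lengths essentially fixed — horn openness. The mode-1 scores
correlate strongly with height and weight, the links planted by the
generator.

The same analysis is available from the shell:

```bash
meniscus-ssm synth --out cohort/ --n 50 --seed 0
meniscus-ssm pipeline --cohort cohort/ --out results/
meniscus-ssm measure --mesh cohort/S000.ply
```

## Layout

```
src/meniscus_ssm/
  mesh_core.py      triangle meshes, PLY/STL/OBJ I/O, Laplacian smoothing
  registration.py   ICP, B-spline FFD, correspondence
  shape_model.py    PCA point-distribution model, mode sampling
  morphometry.py    anatomical frame, landmarks, distances, areas, change rates
  correlations.py   Pearson tests, Fisher CIs, group tables
  synthetic.py      parametric meniscus and cohort generator, ground truth
  pipeline.py       cohort-level orchestration
  cli.py            meniscus-ssm command-line interface
docs/methods.md     models, conventions, parameter choices, limitations
```
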