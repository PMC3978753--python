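# Methods

This note documents the models and conventions the package implements,
the parameters that matter and their defaults, what the synthetic cohort
does and does not emulate, and the numerical choices made where the
design was genuinely open. Units are millimetres and degrees throughout;
the anatomical frame is right-handed with +x lateral, +y anterior,
+z superior, and left-knee surfaces are mirrored at ingest (`side="left"`)
into the right-knee convention.

## Mesh model and smoothing

Surfaces are plain indexed triangle meshes. Validation enforces finite
coordinates, in-range and non-degenerate faces, no unreferenced vertices
and strictly positive area. Vertex order is part of the I/O contract for
PLY and OBJ because correspondence vectors index vertices positionally;
STL stores an unindexed triangle soup, so STL import welds exactly
duplicate vertices in first-occurrence order and cannot preserve an
external ordering.

Noise reduction is uniform-weight Laplacian smoothing: each interior
vertex moves a fraction `step` (default 0.5) toward the mean of its edge
neighbours per iteration; boundary vertices are pinned; topology is never
changed. One iteration is the pipeline default, matching common practice
for segmentation-derived surface models. The returned displacement report
(mean and maximum per-vertex movement) is the quality figure to inspect:
at the synthetic cohort's default noise level it is of the order of
10⁻¹–10⁻² mm, and a large value signals over-smoothing.

## Rigid alignment (ICP)

ICP alternates exact closest-point matching against the reference surface
(k-d tree on triangle centroids proposing candidates, exact
point-to-triangle distance deciding) with a Kabsch least-squares rigid
fit. Initialisation is deterministic: centroid alignment plus
principal-axes alignment, with the four proper-rotation sign combinations
disambiguated by lowest RMS. Iteration stops when the RMS improvement
falls below `tolerance` (default 10⁻⁶ mm) or at `max_iterations`
(default 100); if RMS never improves on the initialisation a diagnostic
warning is emitted and the best iterate returned.

## Deformable correspondence (B-spline FFD)

Correspondence is established by deforming the reference surface onto
each (already rigidly aligned) subject and projecting the deformed
reference vertices onto the subject surface, so every subject inherits
the reference topology.

The deformation model is a global affine stage followed by a
coarse-to-fine cubic B-spline lattice (default control spacings 20, 10,
5 mm, each covering the joint bounding box with a one-control-point
margin). Design choices worth knowing:

* **Point-to-plane affine stage.** A closest-point data term constrains
  a surface only along its normal; the tangential part of an affine map
  (uniform scaling in particular) is recovered only geometrically slowly
  by point-to-point matching. The affine stage therefore iterates
  closest-point matching with a point-to-plane least-squares fit of all
  twelve affine parameters, which the varying normals of a curved surface
  determine in a few iterations. On a uniformly scaled copy this stage
  alone recovers the correspondence to machine precision.
* **Lattice fit.** Each level alternates closest-point correspondence
  with a regularized sparse linear least-squares update of the control
  displacements (Gauss–Newton on: mean squared closest-point residual +
  `bending_weight` (default 0.01) × discrete bending energy, the summed
  squared second differences of the control grid). The data term is
  forward-only (moving vertices matched to the fixed surface); the
  reported per-level residual is nevertheless the symmetric mean surface
  distance. An optional anisotropic point-to-plane variant of the lattice
  data term exists (`plane_min_spacing`) but is off by default — the
  feature constraints below make it redundant at three times the cost.
* **Feature-curve constraints.** Tangential correspondence along a
  surface is invisible to any closest-point data term, and for a
  size-varying cross-section closest-point matching actively prefers
  sliding along the taper gradient. The registration therefore extracts
  the sharp feature curves of both surfaces (edges whose faces meet at
  more than 30°, chained into polylines split at junction vertices),
  pairs them by proximity after the affine stage (pairings worse than
  3 mm mean distance are dropped rather than trusted), and pins each
  moving curve vertex to the point at the same normalised position on its
  partner curve. Arc-like curves are parameterised by the unwrapped polar
  angle about a circle centre fitted to the central half of the curve —
  the circumferential coordinate natural to crescent-shaped anatomy —
  with normalised arc length as the fallback for short or straight
  curves. The parameterisation is computed on the original coordinates so
  the (possibly anisotropic) affine cannot distort it. This convention is
  the package's answer to the inherent ambiguity of surface
  correspondence; on the synthetic family it reproduces the generative
  parameterisation to 0.01–0.05 mm.
* **Fold-over check.** The determinant of the total-map Jacobian is
  evaluated at every vertex; non-positive values raise a warning with the
  count.

Mapped reference points farther than `gate` (default 5 mm) from the
target surface raise a correspondence error listing the offending
indices.

## Shape model

The point-distribution model is a PCA of the corresponded shape vectors
(x₁…xₙ, y₁…yₙ, z₁…zₙ), computed via SVD of the centred N × 3n data
matrix: covariance normalised by N − 1, λₖ = singular value / √(N−1), at
most N − 1 non-zero modes, numerically zero modes (singular value below
10⁻¹⁰ of the leading one) dropped, and each mode's sign fixed so its
largest-magnitude coefficient is positive (mode orientation is otherwise
arbitrary). Training-set reconstruction from the full mode set is exact
to machine precision and total variance equals Σλₖ².

Before the PCA the pipeline applies a **rigid Procrustes re-alignment**
(rotation and translation only, iterated three times against the evolving
mean; never scaling). Surface-based ICP against a single reference has a
systematically shifted optimum between differently sized shapes — of the
order of 1–2 mm translation across a cohort with 6% size variation —
and without this step those rigid-motion components enter the model as
spurious variance that rotates the principal axes. Size deliberately
stays inside the model, so the first mode of a size-varying cohort is
overall size. The re-alignment can be disabled (`procrustes=False`) to
reproduce a strictly ICP-only analysis.

Modes are examined by sampling mean + s·λₖ·modeₖ for s in [−2, +2],
and summarised by the fraction of variance explained by the first k
modes (reported for k = 6 by default).

## Morphometry

All measurements are taken in a deterministic anatomical frame recovered
from the geometry alone:

* **Superior axis**: normal of the best-fit plane of all vertices,
  refitted on the flat inferior facet alone (faces within 10° of the
  first-pass plane normal) so the sloped superior surface cannot tilt
  the frame; oriented so the flat tibial face points inferiorly.
* **Lateral axis**: from the area centroid of the convex hull of the
  projected outline toward the vertex centroid — away from the inter-horn
  gap. Near-spherical surfaces or surfaces without a detectable opening
  raise a pose error.
* **Anterior axis** completes the right-handed frame.

Landmarks are coordinate extrema within deterministic partitions
(ties broken by lowest vertex index): the posterior/anterior horns are
the vertices medial of the midpoint of the x-extent with y < 0 / y > 0,
and the mid-body band is |y| within 10% of the y half-extent. Widths,
lengths and the inter-horn distance are **axial-plane** (x–y) distances —
the vertical outer wall makes purely 3D extrema ill-conditioned (many
points tie in x at different heights), and anatomically these are axial
measures; only the peripheral thickness LPH_Thic involves the superior
axis. PA_Dis is the |Δy| between the two horns' medial landmarks (the
coronal-plane separation).

Areas are planar projections onto the axial plane, computed as shapely
unions of the projected inferior (outward normal z < −0.5) and superior
(z > +0.5) face sets; the threshold is configurable. Gap_Area is
area(convex hull of the inferior footprint) − area(footprint): for a
crescent the hull closes the opening between the horn end faces, which is
the region exposed to cartilage, and for an annulus it reduces exactly to
the enclosed inner region. Whether the underlying quantities should be
projected or true 3D patch areas is an interpretation; projection is used
consistently for all three areas.

The derived indices and the change rate
Δf = (f₊₂λ − f₋₂λ) / f_mean are evaluated exactly as written; the
change-rate table reports them in percent for each mode and parameter,
with all-zero rows for modes beyond the model's rank and NaN cells (with
a warning) for individual measurement failures.

## Correlation analysis

Pearson r with the exact two-tailed t-test (n − 2 degrees of freedom) and
Fisher-z 95% confidence intervals (z ± z₀.₉₇₅/√(n−3); undefined at
n = 3). Inputs must be non-constant with n ≥ 3. No multiple-testing
correction is applied by default, matching common practice for these
screens; Benjamini–Hochberg adjustment is available behind `adjust=True`.
Group tables cover mixed/male/female; a group with fewer than three
subjects is skipped with a warning. Significance is flagged at p < 0.05.

## Synthetic cohort

The generator sweeps a wedge cross-section (flat inferior edge, vertical
peripheral wall, sloped superior face tapering to a sharp inner rim)
along a circular arc of half-angle 180° − α, where α is the opening
half-angle: the crescent opens medially, with the horn tips 2α apart.
Horn taper scales each cross-section's width about its mean radial offset
and its thickness about z = 0, so the tibial facet stays exactly planar.
Defaults are loosely sized to an adult lateral meniscus: arc radius
17.5 mm, body width 10 mm, peripheral thickness 6 mm, opening half-angle
60°, horn tip scale 0.55, with 161 stations × 14 profile points
(≈ 1.1 mm vertex spacing, comfortably below the ≈ 10 mm scale of the
measured features). Meshes are closed, consistently oriented and
deterministic per seed. Analytic ground truth (landmarks, the seven
distances, projected areas) is computed from densely sampled corner
curves of the continuous sweep — never from the mesh.

A cohort draws three independent standard-normal latent scores per
subject. The planted modes are **orthogonalised combinations** of the
raw parameter directions (global scale, opening half-angle, horn taper):
Gram–Schmidt in pose-filtered vertex-field space, in that order. Two
subtleties motivate this bookkeeping, both consequences of testing
recovery with a PCA:

* **Pose-filtering.** A rigid shift of the whole crescent is pose, not
  shape — and the opening-angle direction carries a large rigid
  translation component. Effect magnitudes are therefore measured on
  fields with the six infinitesimal rigid motions projected out, the
  variation a pose-invariant analysis can actually see.
* **Orthogonalisation.** PCA can only recover orthogonal directions, so
  the generator plants orthogonal ones: mode 2 is "openness at fixed
  apparent size", mode 3 horn width with a small compensating
  opening-angle term.

The pose-filtered magnitudes are set in ratio 3 : 2 : 1, anchored by a
relative size SD of 6% (a realistic adult between-subject spread).
Per-vertex Gaussian noise (default 0.05 mm, the scale of
segmentation-smoothing displacements) is added after geometry
construction. Parameter draws violating the geometric invariants — the
opening half-angle in (10°, 85°) and the horn taper in [0.2, 0.95],
outside which the crescent family degenerates (bulging or spike-tipped
horns) — are redrawn, with more than 100 redraws an error.

Anthropometric covariates are drawn conditionally on the latent size
score: height 169.1 ± 9.7 cm, weight 70.93 ± 11.98 kg and femoral condyle
width 75 ± 4.5 mm each at correlation 0.6 with latent size, axial
rotation 7.07° ± 7.12° at correlation 0 (a geometric variable with no
expected load link). Condyle width's mean and SD are typical adult
values. BMI is derived exactly from the sampled height and weight. Sex
alternates for exact balance; no sex effect is simulated.

**What passing tests do and do not show.** The generator emulates the
statistical structure the analysis assumes — a low-dimensional, nearly
linear, nearly orthogonal mode space with size-linked covariates — plus
realistic feature scales and noise. It does not emulate segmentation
bias, mesh-resolution heterogeneity, pathological geometry (tears,
extrusion), sex-specific shape, or real menisci's unmodelled
high-frequency variation. Recovery on this family validates the
machinery (correspondence, model, measurement, statistics), not the
anatomical claims one might derive from real cohorts.

## Known limitations

* Correspondence quality degrades toward the edges of the parameter
  space (strong horn-taper differences between subject and reference);
  across a default 50-subject cohort the residual correspondence
  artefact appears as trailing shape-model modes with λ of a few mm —
  small against the planted modes (λ ≈ 14–50 mm) but not zero, and when
  a planted mode's λ is comparable to the artefact level their ranks can
  swap between seeds.
* The feature-curve machinery assumes the anatomy has sharp rim/corner
  curves; heavily smoothed or very noisy surfaces fall back to
  surface-only matching with weaker tangential determination.
* Gap_Area's convex-hull construction assumes the projected outer
  boundary is convex, true for crescent and annulus geometry.
* The Pearson analysis is deliberately uncorrected for multiple testing
  by default; with ~90 tests per full table, a handful of nominally
  significant cells are expected under the null.
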