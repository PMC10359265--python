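# Methods

This note records the models, conventions and design choices behind
`bonemorph`, and what the synthetic validation does and does not
demonstrate about real data.

## Coordinate frames and sign conventions

All bones are measured in a per-bone anatomical frame with **x anterior,
y superior, z lateral (towards the subject's right)**; the transverse
plane has normal y and the frontal plane normal x. The frames are a
declared convention in the spirit of the International Society of
Biomechanics recommendations:

* **pelvis** — z along left-ASIS → right-ASIS; x from the PSIS midpoint
  towards the ASIS midpoint, orthogonalised; origin at the ASIS midpoint.
* **femur** — y along the condylar-cylinder midpoint → femoral head centre
  (the mechanical axis); provisional z from the epicondyles; origin at the
  condylar midpoint.
* **tibia/fibula** — y along the inter-malleolar midpoint → condylar
  midpoint; provisional z from the malleoli; origin at the condylar
  midpoint.

Left femora and tibiae are mirrored across the sagittal plane (and paired
`*_L`/`*_R` names swapped, triangle winding flipped) before measurement,
so torsion and version carry the same sign on both sides. The pelvis is a
midline structure and is never mirrored.

Signed transverse-plane angles use the right-hand rule about the superior
axis: `signed_angle(u, v, n) = atan2(n · (u × v), u · v)`. Anteversion is
the signed angle carrying the projected neck axis onto the medially
directed posterior condylar axis (positive = neck anterior =
anteversion); tibial torsion is the signed angle carrying the projected
posterior condylar axis onto the malleolar axis (positive = external
torsion). Which physical rotation is labelled "external" is fixed by this
convention together with the generator's construction; nothing downstream
depends on the label.

Projection conventions per angle — these are declared, since clinical
definitions are 2D radiographic in origin and a 3D pipeline must choose:

* AA, TT: transverse-plane projections (torsional quantities);
* NSA: full 3D angle between the neck axis (neck cylinder centre → head
  centre) and the **distal** shaft direction (shaft cylinder centre →
  condylar midpoint, reversed), which places values in the clinically
  familiar 120–160° range;
* mLDFA, BA, mMPTA: frontal-plane projections. mLDFA is taken between the
  distal mechanical-axis direction and the lateral joint-line direction
  (the lateral-distal quadrant), mMPTA between the distal mechanical axis
  and the medial knee-axis direction, so the normal values sit near 87°
  and 88° with varus/valgus moving them in the clinically expected
  direction. BA uses the in-plane perpendicular of the knee axis, folded
  to [0, 90°].

RP ≡ TT − AA is an arithmetic identity evaluated per limb; in batch
outputs it is written on the tibia row of each (case, side) pair that also
has a femur row, never computed from independently drawn numbers.

## Geometric fitting

**Sphere** (femoral head, acetabula): the analytic linearised least
squares (Kåsa solve) — minimising Σ(|p − c|² − r²)² reduces to one linear
system, is exact for points on a sphere, and needs no initialisation.
Coplanar input makes the 4-column design matrix rank deficient and raises
a degenerate-geometry error. The reported residual is the geometric
RMS(|p − c| − r). An iterative geometric fit exists in the test suite only
as an independent oracle; on 500-point clouds with 0.05 cm noise the two
agree within 0.005 cm.

**Cylinder** (femoral neck/shaft/condyles, tibial condyles): nonlinear
least squares over the axis direction only, parameterised as a
tangent-plane chart around the initial direction
(`d(a, b) = unit(d0 + a·e1 + b·e2)`). For each trial direction the axis
position and radius are recovered analytically by a circle fit of the
projected points (variable projection), so the optimiser works in two
well-conditioned parameters. A global spherical-angle parameterisation was
tried first and rejected: its pole singularity degrades convergence
precisely when the cloud's axis aligns with the pole, making results
orientation-dependent at the 1e-4 degree level. Initialisation comes from
the caller (e.g. the neck is initialised along head-centroid −
neck-centroid) or the dominant principal axis. The reported axis point is
the orthogonal projection of the input centroid onto the fitted axis; the
axis sign is canonicalised (largest-magnitude component positive).
Convergence tolerances are 1e-15 (step/objective/gradient) with an
iteration cap; non-convergence raises a fit-failure error carrying the
last residual. Collinear clouds are rejected by a singular-value test.

Extremal landmarks (most-distal condylar points, medial/lateral condylar
extremes) are computed **after** the frame is built, as the argmax of the
dot product with an in-frame direction; exact ties resolve to the lowest
template node index for determinism. No frame re-iteration is needed:
none of the frame-defining inputs depends on an extremal landmark.

## Synthetic bones

The generators build stylised primitive assemblies — spheres, cylinders
and individual landmark vertices — not anatomically realistic shapes.
This is the point: every measurement is defined through landmarks and
primitive fits, so a bone assembled from those primitives with prescribed
angles has *exactly* known ground truth, and recovery can be tested to
fractions of a degree without any imaging data. Each tilt or torsion is
imposed in the anatomical frame the pipeline will itself recover (for the
tibia that frame is twisted about y by the torsion, since the lateral axis
comes from the malleoli), which makes construction parameter and measured
quantity identical by definition.

Key defaults (all configurable): femur — anteversion 15°, NSA 135°,
bicondylar 8°, joint-line tilt 3° (mLDFA 87°), length 30 cm, epicondylar
width 6 cm, head radius 1.5 cm; tibia — torsion 30°, varus tilt 2°
(mMPTA 88°), length 26 cm, condylar width 5.5 cm, malleolar width 4.5 cm;
pelvis — ASIS 16 cm, PSIS 7 cm, depth 9 cm, hip-centre distance 10 cm,
acetabular radius 2 cm; ~400 surface points per region. These sit inside
published paediatric/adolescent reference ranges so the validation runs at
clinically representative geometry.

Two deliberate constructions make ground truth exact and noise behaviour
sane:

* **Congruent condylar regions.** The medial and lateral condylar
  cylinders reuse one local point template, translated along the joint
  line, so paired extremal points differ by an exact joint-line vector and
  fitted centres by an exact translation.
* **Condylar prominences.** Each condylar region contains one explicit
  most-extreme vertex (distal on the femur, medial/lateral on the tibia)
  that dominates the cylinder surface by a 0.3 cm margin, paired with a
  counter-vertex reflected through the cylinder centre so the pair
  perturbs the cylinder fit symmetrically (axis and centre stay exact).
  Without such prominences an extremal point on a noisy sampled surface
  carries an irreducible max-of-noise bias of roughly 2σ per side, which
  is not how prominence-type landmarks behave on smooth template-fitted
  surfaces.

**Noise model.** `noise_sd` adds isotropic i.i.d. Gaussian displacement
(per coordinate) to region surface vertices. Named landmark vertices and
prominences receive attenuated noise (`landmark_noise_factor`, default
0.2). Rationale: in a correspondence-based pipeline a landmark node's
position is constrained by the whole smooth template fit of its
neighbourhood, so its error is far smaller than an independent per-vertex
surface error; a point-pair distance like malleolar width would otherwise
fluctuate by σ√2 ≈ 1.6 % of its value at σ = 0.05 cm, which does not
reflect how such landmarks behave and would swamp the quantity being
validated. The factor 0.2 corresponds to an effective averaging
neighbourhood of ~25 vertices.

What the generator does **not** emulate: realistic cortical geometry,
shape covariation (e.g. neck radius growing with length), correspondence
error that is spatially correlated along the surface, segmentation
artefacts, and growth-plate morphology. Passing closed-loop tests
therefore demonstrates the correctness of the measurement definitions and
their numerical implementation — not robustness to template-fitting
failures on real scans.

## Synthetic cohorts

`simulate_cohort` draws per-case demographics (integer ages uniform on
4–18 or balanced per age and sex, Bernoulli sex, an age-linear height with
Gaussian residual) and per-bone measurement rows
`value = intercept + slope·age + sex_offset·1[male]·1[age ≥ divergence_age] + N(0, sd)`,
with independent draws for left and right sides. The step-at-divergence
sex effect (default age 13) gives the statistics layer a known signal:
sexual dimorphism in linear dimensions appearing around puberty while
torsional measures stay sex-neutral. Default models place linear
measurements on strongly increasing growth curves (height correlations
≈ 0.9+) and torsions/angles on weak trends (|R| ≈ 0.3–0.5), mirroring the
structure reported for paediatric cohorts. RP rows are computed as
TT − AA of the same case and side.

## Statistics

* **Binning**: integer-year age categories 4–18; 5-cm height bins
  [x, x + 5) labelled by the lower bound 95…190. Out-of-range values raise
  a binning error listing offenders.
* **Group summaries**: arithmetic mean and sample SD (n − 1); singleton
  cells report SD as undefined.
* **Growth regression**: OLS on the raw (unbinned) covariate; R is the
  signed Pearson correlation and p the two-sided test of
  t = R·√((n−2)/(1−R²)) on n − 2 df.
* **Two-way ANOVA**: `value ~ C(category) * C(sex)` with **Type II** sums
  of squares — appropriate for the strongly unbalanced cell counts of
  observational growth cohorts, and equal to the classical partition on
  balanced data (verified against a brute-force mean decomposition to
  1e-8 relative). When empty cells make the interaction inestimable the
  additive model is fitted with a warning.
* **Per-category sex comparisons**: two-sided Welch t-tests at an
  uncorrected α = 0.05, requiring ≥ 2 observations per sex; this matches
  common reporting practice but inflates family-wise error across the 15
  age (or 20 height) categories — a documented caveat, not corrected away.
* **Sex-divergence age**: the first category of the maximal suffix in
  which every defined comparison is significant (no smoothing). Requiring
  persistence to the oldest category is what makes the estimate robust: a
  lone false positive among the ~9 pre-divergence categories occurs in
  ~37 % of cohorts at α = 0.05 and would otherwise be reported as the
  onset.
* **Sides**: left and right enter as separate rows by default (ignoring
  their within-case correlation, as the underlying study designs typically
  do); `collapse_sides` averages sides per case first. Mixed-effects
  modelling of side-within-subject correlation is out of scope.

## Problem sizes

The shipped validation uses 100 random spheres; 20 half-cylinder patches
(400 points, σ = 0.02 cm) against a 2° direction-grid oracle refined
locally; a 15-femur anteversion × NSA sweep plus a 4-tibia torsion sweep,
noise-free and at σ = 0.05 cm; 20 random rigid transforms per bone; 500
null replicates and 200 power/divergence replicates for the calibration
studies (10–15 balanced cases per sex per age category, Cohen's d = 1.2
for power and 2.0 for divergence detection); and cohorts of a few hundred
cases for regression structure. These sizes give Monte-Carlo margins
comfortably tighter than the tolerances they check while keeping the whole
validation in the minutes range on one CPU.

## Known limitations

* Correspondence is assumed, never computed: meshes must share their
  registry's template vertex ordering (STL input is accepted only when
  first-appearance welding recovers the template count; isolated landmark
  vertices cannot survive STL at all).
* Fits are plain least squares; no outlier rejection (RANSAC) — degraded
  region selections will degrade measurements silently up to the residual
  diagnostics in the run log.
* The acetabular "hip joint diameter" and femoral "head diameter" are
  deliberately distinct outputs (socket vs ball); on real anatomy the
  acetabular fit surface strongly affects the former.
* Angles are reported for right-convention bones; users disabling
  mirroring must interpret left-side signs themselves.
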