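# Methods

This note documents the models and numerical choices behind `facemasc`:
what each stage computes, what the synthetic cohorts do and do not
emulate, and where design decisions were genuinely open.

## Landmarks and distances

Faces are represented by 21 named Farkas landmarks in millimetres
(frontotemporale, exocanthion, endocanthion, nasion, alare, subalare,
cheilion, pogonion, trichion, glabella, pronasale, subnasale, stomion,
labiale superius/inferius; paired points carry `_l`/`_r` suffixes,
midline points are unsuffixed).  The registry defines 26 standard
inter-landmark distances (forehead width Ft–Ft through mandible height
Sto–Pg); each is measured in Euclidean and geodesic form, giving 52
candidate features per face, plus total facial surface area (the sum of
mesh triangle areas).  All measures are invariant under rigid motion and
scale linearly (area quadratically) under uniform scaling; the
coordinate frame is therefore arbitrary.

Three "hair-border" landmarks (Ft–Ft, Tr, G) are treated like all
others: for geodesic measurement every landmark is snapped to the
nearest surface point, with a 2 mm tolerance (configurable); points
farther from the surface raise an error rather than silently measuring a
different face.

## Geodesic distances

The surface shortest path is approximated in two stages.

1. *Graph stage.*  Each mesh edge carries `steiner_per_edge` evenly
   spaced extra nodes (default 1, i.e. classical midpoint subdivision)
   and within every triangle all boundary nodes are completely connected
   by straight segments; Dijkstra on this graph yields an on-surface
   polyline.  Query points join the graph through straight segments to
   all nodes in the one-ring neighbourhood of their triangle, so the
   result is always the length of a genuine 3D polyline from p to q and
   can never undercut the Euclidean distance.
2. *Refinement stage.*  The polyline is shortened by rubber-band
   iteration: sequential forward/backward sweeps move each interior
   point to its exact 1-D optimum on its mesh edge (closed form in
   unfolded axial/radial coordinates).  Points pinned on a mesh vertex
   may escape onto another edge of the vertex fan when that shortens the
   path, and points whose neighbourhood is exactly flat (all incident
   face normals equal) are deleted, because the straight segment across
   a flat patch lies on the surface.  Each operation is non-increasing
   in length, so the result stays an on-surface upper bound of the true
   geodesic of its corridor.

On the shipped flat fixture the solver is exact (the flat-patch deletion
reduces every path to the straight chord).  On the shipped unit icosphere
(subdivision 4) the antipodal distance is within 0.05% of pi and random
great-circle distances within about 3%; refining the sphere reduces the
error monotonically.  Short paths between points in neighbouring
triangles use the straight chord, which tracks the surface to within the
local mesh resolution.  These accuracy figures are properties of this
implementation at the shipped resolutions, established by a convergence
run, not published values.

## Gender model and masculinity score

Feature selection is a wrapper search: greedy forward selection over the
candidate distances, scored by repeated (3x) stratified 10-fold
cross-validated accuracy of the classifier (folds fixed per fit,
seeded; the repeats damp the fold-overfitting of the maximum over
candidates).  Selection stops when no candidate improves accuracy by
more than `tol` (default 0.01, roughly two subjects at typical cohort
sizes — a looser threshold admits pure-noise features through
one-subject CV fluctuations) or when `max_features` (default 10) is
reached.  Ties are broken by the larger
absolute standardised mean sex difference, then lexicographically, so
fits are fully deterministic.  For at most 12 candidates an exhaustive
all-subsets mode provides the reference optimum; the greedy search is
validated against it in the tests.  Because CV accuracy moves in steps
of one held-out subject, the greedy search can stop early on plateaus;
when a fixed, previously established feature set is to be used (as when
re-applying a published panel), `feature_subset` pins it.

The classifier is the two-class Fisher discriminant: the axis solves
`w = Sw^-1 (mu_male - mu_female)` with `Sw` the pooled within-class
covariance; classification is by nearest projected class mean.  A
singular `Sw` triggers one ridge-regularised retry (relative ridge
1e-8) with a logged warning.

The masculinity score of a face is its signed projection distance from
the midpoint of the two projected class means, oriented male-positive,
min–max scaled over the training sample: the most feminine training face
scores exactly 0 and the most masculine exactly 1.  Scores are computed
on the same sample used to fit the discriminant; cross-validation is
used only to report classifier accuracy.  Out-of-sample projections are
clipped into [0, 1] with a logged count.  The score is monotone along
the discriminant axis by construction.

## Group statistics

Candidate confounders (age, facial area) are screened by Pearson
correlation; covariates with p < 0.05 enter the ANCOVA.  Each analysis
variable is tested in a 2 (family group) x 2 (sex) linear model with
interaction and the active covariates, using effects (Sum) coding and
Type-III F tests — the standard choice for unbalanced factorial designs.
With both covariates and n = 355 the family-group test has (1, 349)
degrees of freedom.  Two geodesic variables with strong positive skew in
adult cohorts — geodesic forehead width and geodesic mandible height —
are natural-log transformed before testing; the transform set is fixed
(a skewness audit merely logs warnings) so the analysis pipeline is
identical across datasets.  Bonferroni correction over the 10-distance
family gives the per-test alpha 0.005; the masculinity score is tested
at the same threshold.

The adjusted effect size is `d = (adjusted group mean difference) /
sqrt(MSE)`, where the adjusted difference is twice the Sum-coded group
coefficient (positive = parents of autistic children larger, i.e. more
masculine) and MSE is the model residual mean square.  Its 95% CI comes
from pivoting the noncentral-t distribution of the corresponding t
statistic.  This convention is stated prominently because published
tables do not always specify theirs; reported d values from other
sources may use different denominators.

Diagnosis-status classification fits the same Fisher LDA to predict
family group from a configured set of facial variables (typically the
masculinity score plus the significant distances) under seeded
stratified 10-fold CV; optionally the majority group is downsampled
first so chance accuracy is 0.5.  Score distributions per group-by-sex
cell are summarised by Gaussian KDEs with Silverman bandwidth, reflected
at 0 and 1 so each density integrates to one on the unit interval;
degenerate (zero-variance) cells fall back to a narrow Gaussian at the
cell value.

## Synthetic cohorts

Two generators provide test beds; both are bitwise deterministic given
their seed (a single NumPy generator per cohort).

**Landmark level** (`generate_cohort`).  Each subject's landmarks are
the female template plus `(s_sex + group_shift) x dimorphism field`,
scaled about the template centroid by
`(1 + 0.035 z)(1 + 0.002 (age - 41))` and jittered with 1 mm isotropic
noise.  The default cohort reproduces the published cell structure: 58
fathers and 134 mothers of autistic children, 50 and 113 comparison
parents, with the published per-cell age distributions.  The template is
an analytic surface — an elliptical dome with nose, brow, lip and chin
features over an elliptical domain — triangulated as a mirror-symmetric
criss-cross grid (denser near the nose, where curvature is highest), so
left/right distances of a symmetric face agree to machine precision.
Template parameters were tuned once so the female template's distances
approximate the comparison-mothers column of the published descriptive
table: the four Euclidean rows agree within ~5%, most geodesic rows
within ~10%, and the cohort mean facial area lands within 10% of the
published 35 435 mm^2.  Two published geodesic rows cannot be
approximated by any smooth surface consistent with the Euclidean rows —
upper facial height (65.5 mm printed, below the Euclidean floor of
N–Sto) and mandible height (71.7 mm printed against a ~35 mm chord) —
and are matched only loosely (+16% / -50%); the distance-level generator,
not the template, carries the exact statistical calibration.  Subject
meshes interpolate their landmarks by a 3D thin-plate-spline warp of the
template mesh (landmarks sit within ~0.8 mm of the discretised surface,
inside the 1 mm jitter scale).

**Distance level** (`generate_feature_table`).  The analysis variables
(ten distances plus a latent masculinity column) are drawn per
group-by-sex cell with the published cell means and standard deviations.
Within a cell, each standardised distance is

    x = r_age * z_age + b * z_size + u * w + residual

where `z_age` is the standardised age, `z_size` a latent size factor
shared with facial area (feature–area correlation `0.8 b`), and `w` a
within-sex masculinity factor loading on the common part of the sex-gap
pattern.  Correlation targets default to `r_age = 0.28` and a uniform size
loading `b = 0.30`, keeping all whole-sample feature–covariate
correlations inside the 0.12–0.56 band reported for real cohorts
(population values 0.32–0.47 for area, 0.28–0.35 for age).

The one structural feature beyond a plain factor model is the *shape
contrast*: the component of the sex-gap pattern orthogonal to the
all-features direction, the size-loading pattern and both per-sex group
gap patterns.  The residual's variance along this fixed mm-space
direction is shrunk by `contrast_shrink = 0.12`.  This reproduces a
robust property of real multivariate face data that independent
per-feature noise cannot: the discriminant finds a combination of
distances whose within-sex variability is far smaller than any single
feature's, which is what makes empirical male–female separations of
4–5 pooled s.d. possible even though every individual distance overlaps
heavily between the sexes.  The shrink strength and the
masculinity-factor scale (0.05) were fixed analytically so that the
population-level discriminant separation sits on the published
very-large-effect scale (about 4.4 pooled s.d.) and both per-sex
family-group shifts project positively on the score axis (about +0.05
and +0.04 on the unit score scale, matching the published cell
differences).  Because the contrast channel lives in a fixed mm frame
while cells are scaled individually, a known cost is that the
within-cell s.d. of the most contrast-loaded feature deviates from its
configured value by up to ~45%; cell *means* remain exactly calibrated,
and the analytic `expected_residual_sd` accounts for the distortion, so
calibration checks use the generator's actual cell standard errors.

The no-group-effect null (`null_group_effect`) equalises, per sex, the
feature means, age distributions and facial-area levels of the two
family groups, so the group factor carries no signal either directly or
through the covariates — the correct null for sizing the group test.
Injected effects (`with_group_effect`) shift both autism-parent cells of
one variable by `d` times the analytic residual s.d. on top of that
null, giving a parameter-recovery oracle with known adjusted d.

What the generators deliberately do not emulate: non-Gaussian feature
distributions (real geodesic widths are right-skewed; the log transform
is still applied for pipeline fidelity), landmark placement error
correlated across neighbouring landmarks, missing data, and any
ethnicity or kinship structure.  Passing tests therefore demonstrate
correctness and calibration of the *pipeline*, not properties of real
faces.

## Problem sizes used in the test suite

Statistical checks run at the published cohort size (n = 355): 1000
replicates for type-I error control, 500 for effect-size recovery, 50
seeds for the classification-structure checks, 60 seeds for cell-mean
calibration, and 25 seeds for the covariate-correlation band.  Geometry
oracles use the shipped fixture resolutions (plane 25 x 25 grid,
icosphere subdivision 4, face grid resolution 18) with over 1000 random
point pairs for the geodesic-vs-Euclidean bound.

## Known limitations

* Geodesics are upper bounds restricted to the Dijkstra corridor; exact
  polyhedral algorithms (MMP, heat method) are out of scope.  The
  flat-patch deletion assumes locally convex flat regions (true for the
  shipped fixtures).
* The greedy selector inherits the step-function granularity of CV
  accuracy and can stop before the best subset on plateaus.
* The adjusted-d convention and its noncentral-t CI are one of several
  in use; comparisons with other reports must check conventions.
* The template is a schematic average face: adequate for exercising the
  geometry pipeline, not for rendering or anthropometric reference.
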