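# Methods

## Model overview

`arcmorph` implements a landmark-free statistical shape model for tubular
anatomies (the motivating case is the aortic arch after coarctation
repair).  Input anatomies are triangle surface meshes in millimetres.  The
analysis follows the *forward* view of computational anatomy: a population
template (the anatomical mean shape) is estimated, every subject is
expressed as a smooth deformation of that template, and statistics are
computed on the deformations rather than on the meshes themselves.  No
landmarks and no point-to-point correspondences are required.

### Currents representation

A mesh `S` is represented by its discrete current: the set of triangle
barycenters `c_f` and area-weighted normals `n_f` (`|n_f|` equals the
triangle area).  Two currents are compared through a Gaussian reproducing
kernel,

    <S, S'> = sum_f sum_g exp(-||c_f - c'_g||^2 / lambda_W^2) (n_f . n'_g),

with squared distance `||S||^2 - 2<S,S'> + ||S'||^2`.  The kernel width
`lambda_W` (mm) is the *resolution*: features much smaller than `lambda_W`
contribute negligibly to the metric, which is what makes the
representation robust to segmentation noise.  The kernel is written
**without** a factor 2 in the denominator; all derived width values assume
this convention.  Normals carry mm^2, so inner products are mm^4.
Evaluation is a direct O(F^2) double sum (meshes in the intended operating
range have <= a few thousand faces); the test suite pins the
implementation against an independent plain-loop oracle at 1e-10 relative.

### Deformation model

Deformations are parameterised by control points `q_k` (a subsample of the
template vertices with spacing `lambda_V / 2`) carrying momentum vectors
`alpha_k`.  The induced velocity field

    v(x) = sum_k exp(-||x - q_k||^2 / lambda_V^2) alpha_k

is integrated by forward Euler over `n_time_steps` (default 10), the
control points flowing with their own field.  The momenta are held
constant along the flow; the stored momenta array still has one slice per
time step so downstream consumers see the full (T, K, 3) trajectory
parameterisation.  The stiffness `lambda_V` (mm) sets the spatial scale of
the deformation: large values give stiff, global deformations.

Matching a source to a target minimises

    J(alpha) = || mu(phi_alpha(S)) - mu(T) ||^2_{lambda_W}
             + gamma * sum_t dt sum_kl exp(-||q_k - q_l||^2/lambda_V^2) alpha_k . alpha_l

by gradient descent with backtracking line search (the step never
increases J).  Gradients are exact hand-derived reverse-mode adjoints of
the Euler recursion and of the currents term; a finite-difference check at
1e-4 relative tolerance is part of the test suite.  The default
regularisation weight is `gamma = 1e-4`; because the data term is mm^4 and
typically O(1e5..1e7), this keeps the regulariser a soft penalty that
suppresses runaway momenta without visibly biasing the fit.

### Template estimation

The template starts from the cohort's reference subject (the subject
closest to the population centre in z-scored gross descriptors: V, A_surf,
L_CL, D_med).  Estimation alternates (a) per-subject momenta optimisation
and (b) backtracked gradient steps on the template vertices against all
subjects jointly; the total cost is non-increasing by construction.  Since
the currents data term is quadratic in the template's current, with all
momenta at zero the first vertex update is exactly a fit of the template
towards the cohort mean current — the "average of all currents" view of
the mean shape.  Convergence is declared when the relative outer-cost drop
falls below 1e-4 (default cap: 6 outer iterations; cohort-level helpers
use 3, which on the synthetic cohorts is already within the validation
criterion).

### Kernel-width selection

An a-priori rule of thumb sets both widths from the smallest surface area
in the cohort: `lambda = sqrt(p * A_surf,min)`, rounded to whole
millimetres, with probing fractions `p_W = 2.5 %` and `p_V = 25 %` by
default (e.g. `A_surf,min = 8825 mm^2` gives 15 mm and 47 mm).  The
optional refinement loop matches the initial template to the smallest
subject while lowering `lambda_V` (down to a floor, default 7 mm below the
start) and then `lambda_W` in 1 mm steps, returning the first —
highest-resolution-sparing — pair that cuts the baseline maximum symmetric
surface distance by at least 80 %.  Surface distance is always symmetric
(vertices of each mesh against the triangles of the other; max and mean
over both directions): whether a one-sided distance was intended is not
decidable from the available description, and the symmetric form is the
safer contract.

### Alignment

Rigid only (rotation + translation, never scaling — size is meaningful
and is handled statistically by the size-residualization step).  Each mesh
is ICP-aligned (vertex-to-nearest-triangle correspondences, Kabsch SVD
solve) to the reference subject; a Generalised-Procrustes-style loop then
re-aligns the cohort to successively recomputed templates while the
*model compactness* decreases.  Compactness is defined as the total
variance of the whitened moment rows (the sum of covariance eigenvalues,
equivalently the mean squared deviation from the mean row).  A
mode-truncated compactness curve would be monotone with this scalar; the
total is used because the loop only needs a scalar stopping criterion.
The GPA loop is capped at 5 rounds; in practice one round suffices.

### Shape modes, size residualization, influence screening

The momenta are flattened into a subjects-by-parameters matrix whose rows
are whitened by the Cholesky factor of the control-point kernel matrix, so
Euclidean row inner products equal the deformation-metric (K_V) inner
products.  Explained shape variability is therefore reported in the metric
norm, not the raw Euclidean momentum norm.

Partial least squares (NIPALS, via scikit-learn, no variable scaling)
extracts the deformation direction most covarying with a response.  The
per-subject projection of the centered rows on a mode is the *shape
vector* `X_S`.  Mode signs are canonicalised so scores correlate
non-negatively with the response.  Size confounding is removed by
deflation, `X_resid = X_orig - XS_size XL_size'`, before fitting the
functional response on the residuals.

Influence screening uses Cook's distance with leave-one-out PLS refits:
`D_i = sum_j (yhat_j - yhat_j(i))^2 / (p * MSE)` with `p = n_components + 1`
and `MSE` the full-fit mean squared residual (floored at `1e-12 * var(y)`
so a perfectly fitting model yields zero distances rather than 0/0
noise).  Subjects with `D_i > 4 * mean(D)` are flagged.

Bivariate associations use Pearson's r unless a Shapiro-Wilk test is
significant (p < .05) for either variable, in which case Kendall's tau is
reported; p-values are two-tailed and unadjusted (the analyses are
exploratory by design).

Mode visualisation deforms the template with momenta
`t * sigma_scores * unwhiten(mode loading)` — the deviation from the mean
deformation along the mode — so `t = 0` returns the template itself
bit-exactly and `t` is in score standard deviations.

## Morphometry

The centreline of an open tubular mesh is extracted by marching cross
sections: starting from the inlet boundary-loop centroid, the mesh is cut
by planes normal to the running tangent; the nearest intersection loop's
**area-weighted** polygon centroid advances the line by half the local
equivalent radius.  The polyline is spline-smoothed, resampled, and then
refined by one re-slicing pass with tangents taken from the smoothed
curve (this removes the tilt lag of the marching tangents on bends; on
analytic tubes the residual centreline error is well below the mesh
facet scale).  This is deliberately a simple replacement for
Voronoi/medial-axis centreline tools, adequate for unbranched tubes.

Descriptors: surface area; volume by the divergence theorem on the mesh
with fan-capped boundary loops; centreline length `L_CL`; tortuosity
`To_CL = L/chord - 1`; median Menger curvature `C_med`; equivalent-area
diameters (`2 sqrt(area/pi)`) along the centreline with 5 % arc trimmed
at each end before taking D_max/min/med; named level diameters at
configurable arc-length fractions (defaults asc 0.15, trans 0.40, isth
0.55, desc 0.80 — anatomical levels are not recoverable from a bare
mesh, so the fractions are an explicit configuration surface); and the
arch height/width pair (A, T).

For (A, T) the centreline is projected on its best-fit plane, the height
axis is the mean limb direction, and the reference level ("spring line")
is found by fitting an axis-aligned ellipse to the sustained-curvature
arch body and taking its centre height; A is the apex elevation above
that level and T the limb separation at it.  For an elliptic arch joined
tangentially to straight limbs every local (width- or curvature-based)
detector is biased, while the ellipse fit recovers the level exactly;
on irregular arches it degrades to a model-based estimate.  A numeric
reference level can be supplied instead.  All descriptors can be indexed
(divided) by body surface area.

## Synthetic cohorts

The generator sweeps circular cross sections along an arch centreline
(straight ascending limb, planar semi-elliptic arch with height A and
width T, straight descending limb), modulating the radius with Gaussian
bumps: a dilated root (x1.15), transverse (x0.85) and isthmus (x0.75)
narrowings by default — the morphology of repaired coarctation.  A
windowed out-of-plane sinusoid adds mild tortuosity, and seeded isotropic
vertex jitter (default sigma = 0.15 mm, roughly the scale of segmentation
noise relative to clinical voxel sizes) perturbs the mesh.

Default cohort geometry (base radius 9 mm, A 45 mm, T 60 mm, limbs
35/80 mm) is chosen so descriptor magnitudes (D_med ~ 18 mm, L_CL ~
230 mm, A_surf ~ 13,000 mm^2) sit in the range of adolescent aortic
arches.  At the population level (default n = 12), body surface area
(BSA ~ N(1.6, 0.2) m^2) drives a global scale factor (slope 0.35 per
m^2) and ejection fraction (EF ~ N(60, 8) %) drives, via its z-score,
the descending-aorta taper (0.12 per z) and the arch A/T roundness
(0.10 per z, high EF = rounder).  Gaussian coupling noise (default sd
0.03) perturbs all three couplings.  A planted-outlier mode scales the
last subject by 1.45 with a strongly gothic arch (A x1.5, T x0.7) and an
extreme low EF, emulating a grossly abnormal subject.

What the generator does **not** emulate: branch vessels, non-circular
lumen sections, wall thickness, imaging/segmentation artefacts beyond
isotropic jitter, or any haemodynamics.  Passing tests therefore
demonstrate correctness of the pipeline's mathematics and its behaviour
under the stated statistical couplings — not performance on clinical
meshes.

## Problem sizes and numerical choices

Cohort meshes default to ~460 faces (12-point sections, 12 mm ring
spacing); morphometry accuracy tests use finer sweeps (16-24 points,
4-6 mm).  Pipeline runs use 10 time steps, up to 60 matching iterations
per momenta block, and 3 outer template iterations; the repeated-seed
outlier screen uses a single outer iteration (one momenta pass against
the reference shape), which is sufficient for influence screening and
keeps 20 seeded cohorts inside a few minutes of CPU time.  These sizes
are the package's default study conditions; all are configurable.

Other numerical choices: duplicate vertices are merged at 1e-8 mm;
degenerate faces dropped; face orientation made consistent by traversal
(closed meshes oriented outward, |V| reported with a warning if the
input was inward).  Decimation is greedy shortest-edge collapse with
midpoint placement; refinement is 1:4 subdivision; the passband smoother
is a two-step (shrink/inflate) filter with lambda = 0.33 and
mu = -1/(1/lambda - passband), boundary vertices pinned — at the default
passband 0.1 and 30 iterations the area of a smooth mesh changes by
under 1 %.  Point-to-triangle distances are exact, with a KD-tree
centroid prefilter whose candidate radius (nearest-centroid distance
plus the largest triangle circumradius) makes the pruning conservative.
The control-point kernel matrix is Cholesky-factored with a jitter
fallback for duplicate control points.  All stochastic components
(generator, fold assignment) take explicit integer seeds.

## Known limitations

- The centreline contract covers unbranched two-boundary tubes only.
- The flow is plain forward Euler without a diffeomorphism guarantee;
  inverted triangles in a deformed mesh are detected and warned about,
  not prevented.
- PLS modes are single-response; multi-response and PCA modes are out of
  scope.
- The (A, T) construction is an operational stand-in for the manual
  2D-imaging measurement it mirrors; absolute values on non-elliptic
  arches depend on the fitted reference level.
- Correlation p-values are unadjusted for multiple comparisons.
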