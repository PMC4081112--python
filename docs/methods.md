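# Methods

This note documents the models and algorithms implemented in `retrosym`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate about real specimens.

## Shape representation and Procrustes conventions

A specimen is an ordered, labelled set of n 3-D landmarks with a per-landmark
availability mask. Object symmetry is described by a pairing: a list of
(left, right) label pairs plus unpaired midline labels. Coordinates may be in
any consistent length unit; all distances reported by the package are
computed on centred, unit-centroid-size configurations and are therefore
dimensionless.

*Procrustes distance.* `optimal_superimposition` fits the least-squares
similarity transform (Kabsch/SVD). The reported distance is the Frobenius
norm of the residual between the centred unit-centroid-size target and the
optimally rotated (and, by default, optimally scaled) unit-size moving
configuration. With scaling this equals √(1 − T²) where T is the Procrustes
correlation; it is symmetric in its arguments, zero iff the shapes coincide,
and invariant to similarity transforms of either input. The residual is
evaluated as an explicit difference norm rather than via √(1 − T²), which
loses half the available precision near zero — exact symmetry then scores
~1e−16 instead of ~1e−8. Reflection is never fitted when computing distances;
it is available as an explicit option for aligning mirrored copies. Distance
magnitudes in the 0.07–0.30 range on cranial landmark sets correspond to the
conventional root-scale (partial/full Procrustes) distances of the
morphometrics literature, which is why that convention is used here.

*Missing landmarks* are excluded pairwise: superimposition and distances use
the intersection of the present masks.

*GPA.* Generalized Procrustes analysis iteratively aligns every
configuration to the evolving unit-size mean (first sample as initial
reference, tolerance 1e−10 on the mean displacement, at most 100 iterations;
non-convergence is reported through a flag, not an exception).

*Midline-plane fit.* The symmetry plane minimises
Σ_pairs ‖reflect(l) − r‖² + Σ_midline dist², which reduces in closed form to
a 3×3 eigenproblem: with pair differences v = l − r, pair midpoints m and
midline points x, the objective is Σ‖v‖² + nᵀA n at the optimal offset, where
A = −Σ v vᵀ + 4 Σ (m−c)(m−c)ᵀ + Σ (x−c)(x−c)ᵀ and c is the weighted centroid
(midpoints weight 4, midline points weight 1). The normal is the smallest
eigenvector; orientation points from the mean right side toward the mean left
side (first pair as tie-break). An eigen-gap below 1e−10 of the matrix scale
is treated as degenerate (plane not unique) and raises.

## Reflection & averaging

The baseline mirrors the configuration through the plane x = 0 after
centring (the choice is immaterial, which a test verifies by pre-rotating
inputs), swaps paired labels, superimposes the mirrored copy on the original
by a *rigid* fit — no scaling, since the mirror image has identical centroid
size and a fitted scale could absorb real signal — and averages corresponding
landmarks with exact 0.5/0.5 weights. The average is then expressed in the
frame of its own fitted midplane and projected onto exact mirror symmetry
(per-pair averaging in that frame, midline landmarks projected onto the
plane). When the alignment is optimal this projection is a floating-point
level correction; it guarantees that the output asymmetry score is zero to
machine precision unconditionally.

Reflection completion (`impute_from_reflection`) fills absent landmarks from
the aligned mirrored copy when the partner is present; absent midline
landmarks and pairs missing on both sides are left absent with a warning.

*Known residual under shear.* For a template deformed by a uniform shear of
magnitude m, the true symmetry plane would recover the template exactly, but
the fitted plane/alignment is biased by O(m) (the shear tilts either the
pair directions or the pair midpoints, depending on its orientation), leaving
an O(m²) residual. At m = 0.2 on the default template this residual is 5–15%
of the deformed distance depending on shear orientation — i.e. 85–95% of the
shear is removed, slightly short of complete reversal. This is a property of
the standard procedure, not of the implementation: an oracle given the true
plane achieves exact recovery.

## Algorithmic symmetrization

The main method corrects affine "flattening" locally, bending globally:

**Neighborhoods.** One per bilateral pair: the `neighborhood_size` nearest
pairs by midpoint distance (default 8; the acceptance experiments also pass
with 5 and with all pairs), plus every midline landmark within the bounding
radius of those midpoints. Membership is symmetric by construction (both
members of an included pair are included).

**Local minimal stretch.** The correction unit is a uniaxial stretch
S(d, λ): distances along the unit direction d are scaled by λ, orthogonal
directions are untouched. Two facts shape the estimator:

1. *Degeneracy of residual minimisation.* If a symmetric point set is
   deformed by any invertible affine map, the set of uniaxial stretches that
   restore *exact* symmetry is a one-parameter family (the condition is that
   B C² B be block-diagonal with respect to the mirror direction, two scalar
   equations in the three stretch unknowns). Minimising residual asymmetry
   alone therefore cannot identify the deformation; worse, on *non-affinely*
   deformed neighborhoods (bending, crush gradients) extreme flattening
   spuriously shrinks the residual without bound.
2. *Closed-form family.* Fitting the affine asymmetry map G (the least-squares
   affine map from the neighborhood onto its relabelled copy) gives the family
   in closed form: a uniaxial C symmetrizes exactly iff Gᵀ C⁻² G = C⁻²,
   i.e. GᵀG − I = ν (e eᵀ − g gᵀ) with g = Gᵀe and ν = 1/λ² − 1. Since
   GᵀG − I has rank 2, e lies in the span of its two active eigenvectors and
   the family is recovered by a 1-D scan (resolution tied to
   `direction_grid_resolution`, default 5°, refined by scalar minimisation).

The estimator evaluates the family candidates (plus the identity) under the
plane-refit asymmetry objective — computable per candidate from two
precomputed 3×3 moment matrices, Σ‖vB‖² + λ_min(B A B) — and selects
lexicographically: candidates within a residual tie band of relative width
`stretch_penalty` (default 0.1) of the best, then the smallest stretch
magnitude |log λ|. The log scale counts a compression to 0.8 and a stretch to
1.25 as equally large corrections; on exact magnitude ties (a compression
along the mirrored axis symmetrizes exactly as well as the true stretch) the
*stretch* is preferred, because taphonomic flattening is corrected by
stretching. A stretch is applied at all only when it explains at least 90% of
the neighborhood's asymmetry — partial reductions are the signature of
non-affine distortion, which is left to the plane-alignment stage. Factors
are clamped to [1/3, 3]; degenerate neighborhoods (fewer than 3 usable pairs
or coplanar members) fall back to the identity with a warning.

*Identifiability.* Even the ideal smallest-stretch rule recovers the true
inverse of an oblique compression only when the compression axis lies at 45°
to the symmetry plane — elsewhere the family's minimum-magnitude member
deviates from the truth (traced numerically along the closed-form family).
The parameter-recovery experiment therefore constructs its known compression
at 45° obliquity (random azimuth, random neighborhoods), the maximally
oblique and maximally identifiable case, where recovery is exact to the
solver tolerance. Off-45° compressions are still symmetrized exactly, but the
recovered (d, λ) is a different member of the family.

After the stretch, members are projected onto exact symmetry about the refit
local plane.

**Plane alignment.** The global midsagittal plane is fitted to the
stretch-corrected configuration (each landmark's corrected positions averaged
across the neighborhoods containing it). Each neighborhood is then rotated
about the line of intersection of its local plane with the global plane by
the dihedral angle (parallel planes are translated), mapping local onto
global exactly. Because the assembly consumes only inter-landmark
*differences*, the choice of rotation centre is immaterial.

**Assembly.** In the frame where the global plane is x = 0, the free
variables are one 3-D representative per pair (the right member is its exact
mirror image) and the two in-plane coordinates of each midline landmark.
Every unordered pair of members within every neighborhood contributes its
difference vector as a least-squares row; the minimum-norm solution is
translated in-plane so the output centroid matches the input centroid (the
out-of-plane centroid coordinate is fixed by symmetry; with differences
expressed in a common frame there is no rotational gauge freedom). A
disconnected neighborhood cover is detected by union-find and reported with
the disconnected label groups.

By default the result is further symmetrized by reflection & averaging
(`final_reflection_average=True`), matching how the method is used in
practice; the assembled configuration is already exactly symmetric, so this
final pass is a near no-op on landmark data but defines the warp applied to
an attached surface.

*Behavior by deformation class.* Oblique affine compression at favourable
obliquity: reversed exactly. Bending/twisting: reversed almost completely by
the plane-alignment + assembly stages (residual ~2% of the deformed distance
in the benchmark). Pure shear: exactly symmetrized, but the smallest
symmetrizing stretch absorbs the shear into a wrong symmetric strain, so the
algorithmic route does *not* beat plain reflection & averaging on shear — the
same pattern the physical-cast benchmark shows on its lightest, shear-only
specimen. Symmetric deformation: untouched (the identity stretch wins and the
planes already coincide), as it must be for any symmetrization method.

**Partial pre-warp.** For heavily one-sided distortion, `partial_warp_toward`
moves a chosen subset of landmarks a fraction of the way toward a target
(e.g. the reflected configuration), optionally carrying a mesh through the
induced TPS. It is never applied automatically — in the benchmark protocol it
was a manual step for a single extreme specimen — and is exposed as an
explicit CLI flag (`--prewarp-fraction`, `--prewarp-mask`).

## Thin-plate splines

3-D TPS with kernel U(r) = r (the biharmonic fundamental solution in 3-D,
not the planar r² log r). With zero regularization (the default, matching the
use of TPS as an exact warp) the spline interpolates the landmark targets and
reproduces any affine map with zero kernel energy; a ridge on the kernel
block is available for near-degenerate centre sets. Exactly coplanar centres
make the polynomial block rank-deficient and raise regardless of the ridge;
duplicated centres are rescued by it.

## The deformation simulator

The simulator stands in for mechanically deformed physical casts of a real
cranium. Templates place bilateral landmark pairs on the right half of an
ellipsoidal surface with semi-axes (0.5, 0.8, 0.35) — width, length, height,
giving cranium-like proportions (length > width > height) — mirror them to
the left, put midline landmarks on the x = 0 ellipse, and optionally add
mirrored equal-arc-length semilandmark curve pairs. Default 45 pairs + 10
midline points, the upper end of what can be reliably digitised bilaterally
on a papionin cranium. A `baseline_asymmetry` parameter adds seeded isotropic
jitter scaled so the expected asymmetry score matches the requested value
(first-order calibration, verified by Monte Carlo to within a factor of two).

Deformations are exact analytic maps applied about the centroid — shear
x → x + m(a·x)b, uniaxial compression x → x + (f−1)(d·x)d, bend (rotation
about an axis with angle graded linearly along a second axis, up to a maximum
angle in degrees), twist (angle proportional to position along the axis,
degrees per unit length), one-sided crush (compression weighted by a
smoothstep over signed distance to the midplane, default width 0.3) — so that
ground truth is exact for parameter recovery. No physical (finite-element or
plastic-flow) simulation is attempted, and no breakage or fragmentation.

The five scenario presets qualitatively reproduce the benchmark's cast
deformations: (1) light midplane shear, (2) rostral twist with
anteroposterior shortening, (3) one-sided crush with a slight bend,
(4) symmetric flattening plus push, (5) mediolateral squeeze with a strong
anteroposterior bend. Magnitudes (shear 0.31; twist 27°/unit with
compression 0.94; crush to 0.30 with 12° bend; flatten 0.38 × 0.70; squeeze
0.94 with 36° bend) were calibrated once so the deformed-to-template
distances on the default template reproduce the ordering and approximate
scale of the published benchmark distances (≈0.09 < 0.11 < 0.14 < 0.25 <
0.28); the asymmetric/symmetric mix inside each preset follows the published
qualitative descriptions.

Digitizing noise is seeded isotropic Gaussian perturbation;
`calibrate_noise` solves for the σ whose mean pairwise replicate Procrustes
distance matches a target (fixed perturbation directions across candidate σ
make the estimate smooth and strictly increasing, so a few scaling iterations
converge; verified against an independent fresh-seed run). The default
calibration target of 0.015 sits mid-range of published intraobserver
replicate means (0.0081–0.0184).

*What the simulator does not capture:* real casts break, their surfaces wear,
landmarks are placed by hand on surface scans with anatomically structured
(not isotropic) error, and manual deformation produces spatially messier
strain fields than these parametric maps. Passing the synthetic benchmark
therefore demonstrates the geometry of the methods, not their field accuracy.

## Evaluation

Percent improvement is 100·(d_deformed − d_retro)/d_deformed, computed from
full-precision distances; human-readable reports round distances to 2
decimals and improvements to 1 (half-even), machine-readable output keeps
full precision. (Published tables computed their percentages from unrounded
distances, so two printed cells are inconsistent with their own rounded
distances; worked-example checks use only the self-consistent cells.) Shape
PCA decomposes the covariance of flattened Procrustes-aligned coordinates
(via SVD), with a deterministic sign convention (the largest-magnitude
loading of each component is positive); new specimens are projected by
aligning them to the stored GPA mean and applying the stored loadings,
without re-running GPA. Convex-hull membership uses the hull's half-plane
equations with a 1e−9 tolerance, so boundary points count as inside.

## Sizes and determinism

All simulation experiments are deterministic given their seeds. The shipped
benchmark (`retrosym.benchmark`) uses 45-pair templates with 10 template
seeds for the method comparison and 8-pair neighborhoods with 20 trials for
stretch recovery; these sizes keep the full suite and the acceptance script
at about a minute each on one CPU while leaving the conclusions unchanged at
larger sizes. Unit tests use 12–20-pair templates.

## Known limitations

- Symmetric deformation is invisible to both methods by construction; fully
  restoring such specimens requires external information (conspecific
  comparisons) and is out of scope.
- Reflection & averaging retains an O(m²) plane-estimation residual under
  uniform shear (see above); at shear 0.2 the residual ratio is ≈0.05–0.15.
- The local stretch is identifiable only at favourable obliquity; off-45°
  affine compressions are symmetrized but not exactly inverted.
- The algorithmic method does not outperform reflection & averaging on pure
  shear or on light deformation generally; its advantage is large, asymmetric
  bending/crushing — consistent with the physical-cast benchmark.
- Semilandmark curves are represented by fixed-count equal-arc-length
  resampling; sliding semilandmarks are not implemented.
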