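# Methods

## Scope and data model

The package quantifies 2-D spore shape and size from binary images (or
directly from outline polygons) and asks how well different descriptor
sets identify species. The analysis chain is: binarize → morphological
cleanup → boundary tracing → orientation standardization → elliptic
Fourier analysis → normalization → three PC shape spaces → linear size
traits → per-image trait averaging → Spearman correlation structure →
repeated cross-validated discriminant comparison. Every intermediate
artifact is plain text (chain-code file, NEFD table, CSVs) and every
run is a pure function of (config, seed).

## Outline acquisition

Thresholding uses Otsu's method by default (spores bright) with a fixed
manual threshold as override. Cleanup is plain mathematical morphology:
opening (`erosion_dilation`) strips protruding noise pixels, closing
(`dilation_erosion`) fills cavities; the structuring element is a disk
of configurable radius (default 1 — the smallest element that removes
single-pixel artifacts while changing a ≥30-px spore's area by well
under 3%).

Boundaries are traced per 8-connected component with Moore-neighbour
tracing from the topmost-then-leftmost pixel, scanning neighbours
counterclockwise (image coordinates) so the emitted Freeman chain runs
counterclockwise once rows are flipped to the mathematical y-up
convention; termination is Jacob's criterion (the start pixel is about
to be left by the initial move again). Objects touching the image
border or below a minimum area (default 20 px) are rejected with a
warning rather than repaired — the automated counterpart of keeping
only intact, fully visible spores. Chain codes convert to µm polygons
at pixel centers; counterclockwise orientation is enforced by signed
area.

Orientation standardization offers only 0°/180° rotation (arbitrary
rotation is removed later by the Fourier normalization). The proximal
(apiculus) end is auto-detected as the outline end with the larger peak
boundary curvature; curvature is measured on an arc-length-resampled,
Gaussian-smoothed copy (σ = 1.5% of perimeter) so pixel staircase noise
does not saturate the turning angles. Detection ties (both ends equally
sharp, e.g. an apiculus-free capsule) leave the polygon unchanged with
a warning; an explicit hint overrides detection.

## Elliptic Fourier analysis

Coefficients follow the chord-length parameterization of the polygonal
outline: on each edge x(t), y(t) are linear in arc length, so the
Fourier projection integrals have exact closed forms (for harmonic n,
`a_n = T/(2π²n²) Σ_i Δx_i/Δt_i (cos φ_i − cos φ_{i−1})`, and cyclically
for b, c, d; A0/C0 are the arc-length-weighted means). A consequence
worth knowing: an eccentric ellipse traced at uniform *angle* does not
have first harmonic equal to its semi-axes under this parameterization
(a 5×2 ellipse gives (4.455, 0, 0, 2.178)); the test suite checks the
closed form against independent brute-force quadrature of the same
integrals rather than against angle-parameterization folklore.

Normalization uses the first-harmonic ellipse: a start-point phase
rotation θ (stationary point of the first-harmonic magnitude; of the
two solutions the one giving the larger semi-axis is kept), a spatial
rotation ψ aligning that axis with x, and division by the semi-major
axis, which is retained as the size scalar in µm. The result satisfies
a₁ = 1, b₁ = c₁ = 0 to machine precision, leaving 77 free coefficients
at 20 harmonics (default; the common range in outline studies is
15–30). If the first harmonic is nearly circular (axis ratio > 0.999)
its phase is ill-conditioned and the start point is pre-aligned from
the second harmonic, with a warning.

The remaining 180° ambiguity (simultaneous spatial half-turn and
half-period start shift, which scales harmonic n by (−1)ⁿ⁺¹) is
resolved intrinsically: the sharper end of the reconstructed normalized
outline — in practice the apiculus end — is mapped to negative x. This
choice is invariant under input translation, rotation, scaling and
start shift, which an orientation-dependent rule could not be. When the
two ends are equally sharp, a deterministic algebraic convention is
used instead (the largest-magnitude symmetric-block coefficient among
the flip-sensitive even harmonics is made positive); restricting the
fallback to the {a, d} block keeps it stable under mirror reflection
too. Reflection itself is deliberately **not** normalized away:
mirroring images is data curation, and reflecting an outline negates
exactly the asymmetric {b, c} block.

Storage order is (a_n, b_n, c_n, d_n) per harmonic, harmonics
ascending; feature vectors drop the three constants, giving 39
symmetric ({a_n≥2, d_n}), 38 asymmetric ({b_n≥2, c_n≥2}) and 77 global
entries.

## Shape spaces

PCA is computed on the covariance matrix of the coefficient vectors —
no standardization, since normalized coefficients share one
dimensionless scale — separately for the symmetric, asymmetric and
global blocks. Eigenvector signs are fixed (largest-magnitude loading
positive) so scores reproduce across runs. "Effective" components
default to eigenvalues strictly above the mean eigenvalue, the
covariance analogue of the Kaiser rule; a literal eigenvalue-above-one
reading is impossible for NEFD covariances (eigenvalues ≪ 1), so the
scaled variant (`kaiser_scaled`, identical set) and a cumulative
`proportion(p)` rule are offered without declaring either the "true"
historic convention. Shape variation along a component is shown as the
mean outline and the mean ± k·SD outlines (k = 2 by default), obtained
by re-embedding the perturbed vector into the full coefficient layout.

## Size traits and aggregation

Length is the maximum Feret diameter (computed on the convex hull);
width is the maximal caliper extent perpendicular to the length axis —
the mycological "broadest dimension across the spore", chosen over the
minimum Feret, which can cut obliquely on bent spores. Derived traits:
Q = L/W and integrated size √(L·W), a size measure less entangled with
shape than either measurement. PC scores are computed per spore and
averaged per image afterwards (never re-fitting PCA on averages);
per-image averages of all traits are the observations of every
comparative statistic, because shape and size acquisitions cannot
always be aligned spore-by-spore within multi-spore images. Spearman
correlations use average ranks and two-sided t-approximation p-values,
unadjusted at α = 0.05 by default with Holm adjustment available.

## Discriminant comparison

Flexible discriminant analysis is implemented by optimal scoring:
regress the class-indicator matrix on the (optionally basis-expanded)
features, eigen-decompose the fitted indicator cross-product in the
class-size metric, drop the trivial constant score, and classify by
nearest class centroid in the discriminant space with per-dimension
weights (n−K)/(λ_l(1−λ_l)) — the within-class variance of discriminant
variate l is exactly λ_l(1−λ_l)/(n−K) — minus 2·log(prior). Priors are
proportional to training class frequencies; distance ties resolve to
the first class in sorted label order. With the default linear basis
this is exactly classical LDA, verified prediction-for-prediction
against an independent implementation; polynomial and ridge bases are
options, with ridge required (and suggested by the error message) for
singular designs.

Cross-validation: per replicate, a stratified split sends
round(0.7·n_s) rows of each species to training (adjusted by one if
rounding would empty a portion; species with a single row are an
error), accuracy is computed on the test rows, and the mean over
replicates (default 1000) is the identification success rate.
Replicate r draws its RNG from the root seed with spawn key (r,), so
results are reproducible and extending the replicate count never
changes earlier replicates. When feature sets are compared, all sets
see the identical partition sequence (paired design, assertable via
partition hashes); pairing removes split noise from between-model
differences and is the package's choice where the historic protocol is
silent.

Feature sets follow the standard naming: S (symmetric PC1), A
(asymmetric PC1–3), G (global PC1–2), LW, Q, QLW, GLW, SALW, SIZEINT
(√(L·W) alone). The trait table always carries sym PC1, asym PC1–3 and
glob PC1–2 regardless of how many components the effective rule keeps,
so the named sets are always well defined.

## Synthetic data generator

The generator is the package's ground-truth instrument, not a fixture.
A spore is a bent capsule: centerline x ∈ [0, L] with lateral offset
`y_c(t) = κ₁ L sin(πt) + κ₂ L sin(2πt)` (single bow + S-curvature
differentiating the ends), half-width `(W/2)(4t(1−t))^p` (taper
exponent p), and a Gaussian apiculus bump (height h, width σ·L) on the
adaxial profile at the proximal end. The four shape axes map one-to-one
onto the interpretable modes of outline variation (relative thickness,
bowing, end curvature, pointedness), which is what makes
parameter-recovery tests possible. Note the bend preserves the
end-to-end span, not the arc length: a bowed spore keeps max Feret ≈ L
while gaining width.

Hierarchy: species means drawn uniformly from configured ranges
(defaults emulate a needle-shaped-to-short-cylindric genus: L 6–16 µm,
W 1.8–4.5 µm, |κ₁| ≤ 0.08, |κ₂| ≤ 0.05, p 0.4–1.0, h 0.2–0.5 µm);
Gaussian between-specimen effects and within-specimen noise on an
internal scale that is logarithmic for length and width (dimensions are
positive and right-skewed; default log-SDs 0.04/0.07) and linear for
the curvature/taper/apiculus terms; draws are clipped to the parameter
invariants. The default design mirrors a herbarium study: 10 species ×
3 specimens, 10–37 spores per specimen, 1–4 spores per image.

What the generator does *not* emulate: illumination gradients, optical
blur, overlapping or broken spores, hyphae/crystal clutter, focus
variation. Passing tests therefore demonstrate the correctness of the
measurement and comparison machinery on clean silhouettes, not
robustness to messy micrographs — on real images the binarization and
cleaning stages carry that burden.

## Numerical choices and problem sizes

Polygons are counterclockwise with implicit closure; duplicate vertices
are dropped inside the Fourier fit. Outline comparisons in tests use
Hausdorff distance between densely arc-length-resampled curves (3000
points), since vertex-set Hausdorff overestimates along long edges.
Reconstruction-error monotonicity is asserted as L2 error at matched
arc-length parameters, the form guaranteed by Parseval; nearest-point
metrics are not exactly monotone. The test suite and the acceptance
script use scaled-down but design-faithful problem sizes (panels of
several hundred spores, 200 CV replicates, 20 panel seeds for the
ordering property) — the package's own choice of sizes at which every
reported quantity is stable to well within its assertion margins.

For the chance-level calibration, CV replicates on one permuted dataset
are not independent, so the standard error of the mean success rate is
taken across 10 independent label permutations (20 replicates each);
the permutation means are independent and their expectation is 1/K.

## Known limitations

* The sharper-end rule assumes an apiculus (or otherwise asymmetric
  ends); on end-symmetric outlines the algebraic fallback gives a
  stable but biologically arbitrary orientation of the shape space.
* Spore-level truth alignment in multi-spore images relies on
  left-to-right ordering of traced components matching generation
  order; real images with vertically stacked spores would need an
  explicit assignment step.
* Touching spores are not separated (no watershed); they are rejected
  as one border/area-filtered object or traced as a merged outline.
* Identification rates on synthetic panels depend on the configured
  species ranges; they are not predictions of rates on any real
  collection, only of the relative ordering of descriptor sets.
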