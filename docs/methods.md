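# Methods

This note documents the models, conventions and numerical choices behind
`gryllomorph`, and what the synthetic data do and do not establish.

## Shape model and superimposition

A specimen is a configuration of k 2-D semilandmarks. Size is measured by
centroid size S = √Σ‖pᵢ − p̄‖²; removing translation and size places every
configuration on the unit preshape sphere. Pairwise superimposition rotates
one preshape onto another by the SVD solution of the orthogonal Procrustes
problem; the rotation determinant is constrained to +1 unless reflections
are explicitly allowed (`allow_reflection`), since dorsal-view outlines have
a consistent handedness but mirrored fossil figures occur.

Generalized (GLS) superimposition seeds the consensus with the first
configuration, then alternates (i) rotating every preshape to the consensus
and (ii) replacing the consensus by the recentered, renormalized arithmetic
mean, until the consensus moves less than `tol` between iterations
(partial Procrustes distance; default `tol = 1e-10`, `max_iter = 100`). The
iteration contracts at a roughly constant rate, converging in a few dozen
iterations at most; the result is seed-independent up to global orientation
for realistically concentrated samples. (For artificially dispersed shape
sets — essentially random point clouds — the GLS objective can possess
multiple local optima; this is a property of the objective, not the solver.)

Two distances are used deliberately: *partial Procrustes distance* d
(root-sum-of-squares after superimposition) everywhere shapes are compared,
and *geodesic distance* ρ = 2 arcsin(d/2), in radians, only in the
tangent-space diagnostic, where the radian scale is the point.

Semilandmarks are fixed after equal-arc-length resampling — there is no
sliding by bending energy or perpendicular projection. Start-point
homology is the digitizer's responsibility (outlines are assumed digitized
from a homologous start vertex, e.g. the anterior midline of the pronotum);
an optional cyclic alignment (`cyclic_align="ref"`) instead picks, per
specimen, the cyclic shift minimizing the Procrustes distance to a
reference, for data where start points cannot be trusted. Closed outlines
carry k distinct points with no duplicated endpoint, avoiding a
double-weighted landmark, and traversal is normalized counter-clockwise by
the signed-area test so that orientation is consistent when reflections are
disabled. Coordinates are taken as digitized (no y-flip) unless the
`y_flip` option is set for image-origin data.

## Tangent-space diagnostic

Each aligned preshape x is projected onto the plane tangent to the unit
sphere at the consensus z: x_t = x − z(z·x), so ‖x_t‖ = sin ρ exactly. The
diagnostic reports per-specimen (ρ, Y = ‖x_t‖), the through-origin slope
ΣρY/Σρ² (primary, matching the historical tool's regression through the
origin), a free-intercept OLS fit alongside (the historical tool's exact
variant is not documented), and the uncentred correlation
ΣρY/√(Σρ²ΣY²). Values ≥ 0.9999 indicate the small-variation regime where
tangent-space (linear) statistics approximate shape-space geometry.

## Genus means and relative warps

The consensus hierarchy mirrors the two-stage workflow of the historical
tool chain: GPA within each genus → genus consensus shapes → GPA of the 13
genus means → relative warps and distances computed among the means. A
monotypic genus contributes its single normalized shape.

Relative warps decompose the n × 2k matrix of tangent residuals from the
consensus, column-centered, by SVD. With α = 0 (default) this is exactly
principal-component analysis of tangent coordinates, uniform (affine) and
non-uniform variation together — the only α under which "SVD of the weight
matrix" and shape PCA coincide, and the historical default. For α ≠ 0 the
residuals are first expressed as partial-warp scores (projections onto the
principal warps of the consensus's bending-energy matrix) scaled by
λ^(−α/2); the affine component, which has no bending-energy eigenvalue, is
excluded in that case. Percent variance is squared singular values
normalized to 100. SVD sign ambiguity is fixed by making the
largest-magnitude loading of each warp vector positive, so runs are
reproducible. The number of nonzero singular values is bounded by
min(n − 1, 2k − 4) (centering, plus the four similarity constraints).

The thin-plate spline uses kernel U(r) = r² log r² with the bordered system
L = [[K, Q], [Qᵀ, 0]], Q = [1 | x | y]; the bending-energy matrix is the
upper-left k × k block of L⁻¹ (symmetrized; exactly three zero eigenvalues
spanning affine maps). Warps are computed by a dense solve of L — k is tens
of points here, so numerical refinements for large k are unnecessary.
Deformation grids warp a regular grid over the consensus at a configurable
magnification (default ×1).

## Ordination and phenetics

The genus-level distance matrix is ordinated by principal-coordinates
analysis (double-centered −D²/2, eigendecomposition, scores =
eigenvectors·√λ; negative eigenvalues are reported and their axes dropped).
PCoA is the faithful reading of an "ordination of genus means from the
Procrustes distance matrix": a canonical variates analysis proper would
require within-group covariance that a means-only design cannot supply.
The PCoA itself is delegated to scikit-bio; the package validates it against
planted planar coordinates in its tests.

UPGMA is implemented in-package because its conventions are pinned:
size-weighted ("unweighted" in the traditional naming) arithmetic-average
linkage, merge heights d/2 so root-to-leaf paths equal half the cophenetic
distance, and ties broken by the lexicographically smallest pair of cluster
indices (leaves in input order, then merge order) for determinism — the
historical program's tie rule is undocumented. The tests cross-check
against scipy's average linkage on random matrices and against the
ultrametric fixed-point property. The cophenetic correlation (Pearson, over
unordered pairs) is reported as the phenogram's fit diagnostic. Newick
branch lengths are height differences, so leaf depths equal tree height.

## Synthetic study design

Real input would be outlines digitized from published habitus figures; none
are deposited, so the generator emulates them. Outlines are truncated
Fourier perturbations of a circle, r(θ) = r₀(1 + Σ_{h≤4} aₕ cos hθ +
bₕ sin hθ), sampled at 400 equal-angle vertices (200 in the replicated
recovery experiment, where the resampling error is still far below the
within-genus scatter). Four harmonics are enough for rounded-quadrate,
transversely oval pronotum silhouettes while keeping analytic symmetry
cases for tests (a pure cos 2θ term gives an exactly bilaterally symmetric
oval).

The default design (shipped as `data/table2.yaml`) fixes the study
composition — 13 genera, 8 monotypic fossil + 5 extant with 10/5/3/1/1
species, 28 specimens — and one mean coefficient vector per genus. The five
extant genera share a rounded-quadrate base (a₂ ≈ 0.06–0.15, a₄ ≈
0.03–0.11, no asymmetry) with pairwise mean separations ≥ 0.05 in
coefficient space; fossil genera carry larger and partly asymmetric
coefficients, ≥ 0.2 from the extant family and dispersed among themselves —
a tight extant cluster against scattered fossils, matching the qualitative
pattern of the source material. Species add i.i.d. N(0, 0.005) per
coefficient (so genus-mean separation is ≥ 10× the per-coefficient
within-genus scatter), vertices add N(0, 0.002) digitizing jitter (0.2% of
outline radius), and each specimen receives a random similarity nuisance:
rotation U(0, 2π), scale log-uniform on [0.5, 2], translation U(−10, 10)².
A single integer seed drives everything; each specimen uses a
counter-indexed substream (`SeedSequence(seed, spawn_key=(i,))`), so records
are independent of generation order and byte-identical across runs.

What the synthetic data do **not** emulate: real digitizing is biased, not
i.i.d. (operator drift, corner rounding, figure reproduction artifacts);
real pronota vary allometrically and asymmetrically in ways a 4-harmonic
radius model cannot express; fossil compressions deform non-affinely.
Passing tests therefore demonstrate that the *pipeline* recovers planted
structure under controlled conditions, not that the original biological
conclusions are reproduced — the original outlines would be required for
that, and the study's two headline numbers (tangent correlation, RW1+RW2
percent variance) are consequently properties of its undeposited data that
this package can parallel but not reproduce.

## Degenerate inputs and tie-breaking

Zero-length or self-degenerate (zero signed area) curves, coincident
landmark pairs (singular spline systems), all-coincident configurations
(zero centroid size), identical specimen sets (undefined tangent
diagnostic), and empty genus groups are rejected with explicit errors
rather than propagating NaNs. Exact zeros in relative-warp scores map to an
explicit "axis" quadrant rather than being forced into a quadrant.

## Problem sizes

Defaults throughout are the study's own scale: 28 specimens, 50
semilandmarks, 13 genera. The full pipeline runs in well under a second;
the 100-replicate recovery experiment in a few seconds. These sizes are the
design point of the package, not a performance ceiling — the dense solves
involved (SVD on n × 2k, k × k inversions) remain trivial up to hundreds of
landmarks and specimens.
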