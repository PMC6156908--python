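# Methods

This note documents the models and algorithms implemented in `landscaper`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and the scope of what the synthetic validation studies show.

## The smoothed surface

Raw force-field energies over a 2D principal-component projection are far
too rugged to expose basin structure directly: the projection collapses all
remaining degrees of freedom, so nearby samples can carry very different
energies. Both reconstruction methods therefore operate on a Nadaraya–Watson
kernel-regression estimate

    ê(x) = Σᵢ K(‖x − xᵢ‖ / h) · eᵢ  /  Σᵢ K(‖x − xᵢ‖ / h)

— a local weighted average that simultaneously damps ruggedness and adapts
to non-uniform sampling density (the weights renormalize per query point).

**Domain.** The estimator is only meaningful where samples exist. The
domain is the alpha-convex shape of the sample cloud: the union of Delaunay
triangles whose circumradius is at most `1/alpha` (with the default
`alpha = 0.15`, a ball radius of ≈ 6.7 PC units). In the large-radius limit
this degenerates to the convex hull; smaller radii follow concavities and
can open holes. The literature contains both `radius = alpha` and
`radius = 1/alpha` parameterizations; this package fixes the latter, which
produces sensible hulls across the sample densities it targets (with
`radius = alpha = 0.15` virtually no triangle of a realistically sampled
cloud survives). A regular grid at spacing `delta1 = 0.1` is clipped to the
domain (boundary-inclusive); grid points with no sample inside the
h-neighborhood are dropped from the working grid `S_max` regardless of the
kernel in use — estimates there would be extrapolation from afar.

**Kernels.** Four profiles: Gaussian `exp(-u²/2)`, Epanechnikov `1-u²`,
Tricube `(1-u³)³`, and a bounded-support Gaussian truncated at radius `h`
whose neighbor sets are found through a kd-tree proximity index (the
acceleration is exact: the truncated sum has finitely many terms, and the
indexed path reproduces the brute-force all-pairs computation to 1e-9).
Default bandwidth `h = 0.7` PC units.

The default analysis kernel is the (unbounded) Gaussian. This is a
deliberate numerical choice: the hard truncation of the bounded kernel makes
ê only piecewise-smooth — each sample entering or leaving the h-ball steps
the estimate by `O(e^{-1/2}·|eᵢ - ê| / ΣK)`, which at a few thousand samples
is a gradient-scale discontinuity of order 1e-2, far above the gradient-zero
tolerance `eps_g = 1e-3` that the critical-point machinery must resolve.
The Gaussian estimator is C^∞; for iterative work its sums are truncated at
radius `5h`, where the discarded relative weight is `e^{-12.5} ≈ 4e-6` and
the induced derivative noise sits well below `eps_g`. Reported grid
energies are computed with dense all-pairs sums (no truncation).

**Derivatives.** Gradient and Hessian of ê are evaluated in closed form by
the quotient rule over the weighted sums (`grad K = -K·dx/h²`,
`hess K = K·(dx dxᵀ/h⁴ - I/h²)`), and are validated against central finite
differences of the same evaluator. Off-grid queries evaluate the estimator
directly rather than interpolating the grid, so the saddle search sees one
consistent C² surface with no cell-boundary artifacts.

## Basin-driven reconstruction

Descent of the level `c` from `c_max` in steps `delta2 = 0.3`, tracking
connected components of the sublevel set restricted to the current basin's
grid points. Connectivity is 8-neighbor adjacency on the regular grid
(raster flood fill) — deterministic and exactly testable against an
independent breadth-first-search oracle; the alpha hull is then fitted per
component to obtain the polygonal boundary used for saddle geometry. The
recursion is realized with an explicit work stack, so deep hierarchies
cannot hit the interpreter's recursion limit.

When a component splits, each pair of sibling basins whose minimum
boundary-vertex distance is at most `d_th = 20·alpha = 3.0` receives a
working-definition saddle at the midpoint of the minimum-length segment,
with energy evaluated on the smoothed surface at that midpoint. Ties between
equally short vertex pairs break to the lexicographically smallest pair.
Because the level descends in finite steps, the split is detected up to
`delta2` below the true pinch energy; the midpoint itself, however, lies
spatially near the pinch, so its *energy* error is second-order (for a
symmetric two-well surface the midpoint sits essentially at the saddle).

Cost controls, active only above the detail cutoff `c > c_min + c0`
(default `c0 = 200`, sized for force-field energy ranges of hundreds of
units): the jump test lowers `c` by `m·delta2` (default `m = 50`) at once
and reverts to a single step if the jumped sublevel set has split or
emptied — basins that appear and die entirely inside an accepted jump are
knowingly missed (they are small and shallow by construction); and
components with fewer than `n0 = 100` grid points are recorded but not
descended into. On landscapes whose total energy range is below `c0`
(including the synthetic fixtures at their default depths) both
modifications are inert unless `c0` is lowered explicitly; the suite
exercises real jumps with `c0` raised into range.

## Saddle-driven reconstruction

**Minima.** A damped-Newton descent (analytic gradient and Hessian; Newton
direction where the Hessian is positive definite, steepest descent
otherwise; backtracking on the estimator value) is launched from every grid
point. For efficiency the bulk phase runs vectorized over all seeds on a
k-nearest-neighbor truncation of the estimator (k = 32); the endpoint
groups are then polished per-representative on the accurately truncated
estimator, where the minimum test is applied: `‖∇ê‖ < eps_g`, positive
definite Hessian, and at least one sample within `h` (walks are not
advanced from poorly sampled regions). Duplicates are merged by
single-pass leader clustering at radius `eps = 0.01` — a point joins the
first cluster whose representative lies within `eps`, else founds one.

**Saddles.** Critical points solve both equations of `∇ê = 0`; dropping one
leaves a curve (the zero set of the retained component `g_j`) through all
critical points, with tangent orthogonal to Hessian column `j`. The four
2D variants (two columns × two orientations) are all followed from every
minimum. The predictor moves `p = 0.1` along the normalized tangent; the
corrector solves the 2×2 system `{H_j·c = -g_j, t·c = 0}` (iterated to
tolerance, with step-halving on near-singular systems); the combined mode
solves `{H_j·d = -g_j, t·d = p}` in one step. Both modes are supported and
agree to within the clustering radius. A walk ends on leaving the sampled
region, after 10,000 steps, or on re-entering an `eps`-ball of its start.

On a discrete walk the strict test `‖∇ê‖ < eps_g` rarely fires exactly at
a curve point, so saddle collection is triggered by a sign change of the
neglected gradient component between consecutive points: a 2D Newton polish
of `∇ê = 0` from the midpoint, followed by the exact saddle test
(`‖∇ê‖ < eps_g` and Hessian eigenvalues of opposite signs). Saddle
estimates from different curves are merged by leader clustering and
re-verified.

**Basin boundaries.** The gradient vanishes at a saddle, so tracing starts
from two seeds jittered off it by `2·delta1` along the eigenvector of the
smallest (negative) Hessian eigenvalue — the direction into the two basins.
Each seed is projected onto a contour just below the saddle energy and
followed orthogonally to the gradient with re-projection each step, closing
when it returns within 1.5 steps of its start. Two numerical guards matter
here: (i) at exactly the saddle energy the two basin boundaries pinch
together at the saddle and a discrete tracer can hop branches, so the
traced level is dropped by `4·p²·|λ₋|` (λ₋ the negative eigenvalue), which
keeps the pinch gap `≈ 2·√(2·drop/|λ₋|)` several trace steps wide; (ii)
through hairpin bends the local step is halved until successive tangents
turn by less than ~60°. The traced level is recorded as the resulting
basin's `birth_level`. The methods keep their outputs separate: nesting is
the basin-driven method's product; saddle-attached basin pairs are the
saddle-driven method's.

## Descriptors and mining

d(State, Saddle) is the PC-space Euclidean distance from a reference state
to the saddle separating the On and Off basins; dE(State, Saddle) =
E(Saddle) − E(State). Five tracked states give a 10-component vector per
variant. The On↔Off saddle is, by default, the basin-driven saddle recorded
at the split separating the basins containing the On and Off reference
locations (fallback: lowest-energy saddle). Two state representations are
supported: the reference conformation's own location and energy (default),
or the deepest point of the containing basin.

The correlation screen computes all descriptor × parameter Pearson
correlations across variants, pairwise-complete over missing values (the
per-cell n is reported so downstream multiple-testing control is possible;
none is applied here, and the screen itself is a reporting threshold, not
an inference). Filtering is on |r| ≥ 0.5 with the sign retained. Values may
be min-max normalized, `(x - min)/(max - min)`, for presentation; Pearson
correlation is affine-invariant, so the screen is identical either way —
the suite asserts this. (The rescaling is implemented in its standard form;
a denominator of `x - max(x)` would not be a rescaling at all.) The
normalization is undefined for constant columns, which are rejected with a
per-column error.

## Synthetic study conditions

The generator emulates what sample-based landscape representations look
like statistically — it makes no attempt to mimic force-field energetics
beyond ruggedness and multi-basin structure. Surfaces are negated Gaussian
mixtures `e(x) = -Σ Aₖ exp(-‖x-cₖ‖²/2wₖ²) + κ‖x‖²`; the weak harmonic
confinement (`κ = 0.02`) makes energy rise away from the sampled basins, as
real landscapes do at the rim of the populated region, and removes
physically meaningless flat plateaus where critical points would be
conditioned on sub-noise energy variations. Critical points are enumerated
by Newton polishing from a dense lattice with Hessian classification
(degenerate points flagged and excluded) — self-validating and exact to
1e-9, which makes every study below an absolute comparison.

Default sampling: Boltzmann-like density ∝ exp(-0.1·e) by rejection
(basins oversampled relative to barriers, emulating exploration runs),
additive Gaussian energy noise with sd = 2% of the deepest well, n = 5,000
at test scale and 50,000 for the full-scale barrier study (which uses noise
sd = 5% of depth).

Fixture geometry is sized against the smoothing bias of the estimator, not
tuned to test outcomes. For a well of width w, kernel smoothing attenuates
depth by roughly `w²/(w² + h²)`, and the leading barrier bias is
`(h²/2)·[tr H(saddle) − tr H(minimum)]`; numerical convolution of the
candidate geometries put the bias at −9.0% of the barrier for w = 3.0 and
−6.9% for w = 3.4 at the default h = 0.7. The canonical two-well fixture
therefore uses w = 3.4, depth 10, centers (±7.5, 0) — a ~7% systematic
barrier bias, within the 10% recovery target with margin for sampling
noise. Its sampling rectangle extends 5.5 units beyond the wells in x and
to ±6.5 in y: the estimator's one-sided windows at the rim bias rim
estimates low by roughly `|∇e|·h/2`, and the margin keeps the saddle-level
sublevel set interior to the sampled region despite that bias — the premise
under which boundary tracing is well-posed. The nested fixture (a broad
shallow well containing two narrow deep wells) exercises hierarchy; the
randomized recovery study draws 2–4 wells of one width (1.4–1.7) along
randomly bending chains with neighbor spacing 4.15–4.35 × width, just above
the two-minimum merge limit, so every analytic saddle has genuine curvature
in both directions and every critical point is deep relative to the noise
scale — features whose positions are conditioned on energy variations below
the noise (saddles on near-flat plateaus between distant wells) are
excluded by construction rather than by a post-hoc filter.

**What passing studies do and do not show.** The studies establish that the
implemented pipeline recovers the geometry of smooth multi-basin surfaces
from noisy, non-uniformly sampled evaluations at realistic densities, with
known and bounded smoothing bias. They do not establish anything about
landscapes whose features are narrower than the bandwidth (smoothed away by
design), about sampling distributions with coverage gaps inside the domain,
or about the fidelity of any particular force field or projection.

## Problem sizes and determinism

Validation-suite scale: n = 5,000 samples per fixture (≈ 25,000–35,000 grid
points at delta1 = 0.1), the barrier study at n = 50,000, and 20 randomized
landscapes in the recovery study. All sampling is seeded; the algorithms
themselves contain no randomness (ties broken by fixed sort orders, leader
clustering in deterministic input order), so identical configuration,
inputs and seed reproduce identical outputs.

## Known limitations

- Strictly 2D: the reduced-gradient machinery and the alpha-shape domain
  are implemented for two projection coordinates plus energy.
- The working-definition (midpoint) saddle energy inherits up to one
  `delta2` of level-quantization error in pathological geometries, though
  in practice the midpoint lands near the pinch and the error is far
  smaller.
- Leader clustering is order-dependent by construction; representatives may
  shift by up to `eps` under reordering (counts on well-separated surfaces
  do not).
- The saddle of a wide two-well surface has a soft transverse Hessian mode
  (an order of magnitude below the well curvatures), which makes the saddle's
  position the noisiest recovered quantity: at the 5,000-sample test scale
  its error across sampling seeds is typically 0.05-0.3 PC units, an order
  larger than the minima's.
- Bandwidth selection is by inspection; `LandscapeFit.bandwidth_sweep`
  reports the smoothing/variance trade-off but no automatic selector is
  provided.
- The non-smooth kernels (Epanechnikov, Tricube) support estimation only;
  critical-point analysis requires the Gaussian family.
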