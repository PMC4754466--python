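# Methods

## Model and pipeline

A white-matter tract is represented by a continuous medial model: a
triangulated skeleton surface `m` with a per-vertex radius `r` (mm) such
that the tract boundary lies at distance `r` along the two spoke
directions

    U± = −∇_M r ± √(1 − ‖∇_M r‖²) · n,      b± = m + r·U±,

where `∇_M r` is the tangential gradient of the radius and `n` the vertex
normal. This is the classical Blum medial (inverse-skeletonization)
relation; it is valid only where `‖∇_M r‖ ≤ 1`, and vertices violating
that feasibility condition are flagged invalid, counted in the run log,
and excluded downstream rather than clamped — clamping would silently
hide defective inputs.

Per subject, the spatially normalized diffusion-tensor volume is sampled
at equally spaced points along each chord `b− → m → b+` (both spokes
pooled, skeleton point included once), tensors are interpolated
component-wise trilinearly, and the sample with the largest FA is kept,
provided it reaches the 0.2 FA floor; its FA and the *same sample's* MD
become that vertex's measurements. Sub-threshold vertices are missing for
that subject. Per-subject FA and MD surface maps are then smoothed with a
surface heat kernel of 8 mm FWHM before any fitting.

At every vertex, for each sex separately, two mean models are fitted to
measure-versus-age:

* linear `y = b + a·age` by ordinary least squares;
* exponential `y = C + A·e^(−age/t)`, the canonical maturation shape:
  fast change in childhood levelling off at the adult asymptote `C` with
  e-folding time `t` years.

Each fit carries an F test against the constant-mean null, the
goodness-of-fit correlation `r` (signed for the linear model,
`√(1 − SSE/SST)` for the exponential — the two conventions are stated in
the output header), and AIC `n·ln(SSE/n) + 2(k+1)` counting the residual
variance as a parameter (k = 2 linear, 3 exponential).

Vertexwise significance is corrected familywise with random field theory:
per-vertex p values are mapped to equivalent Gaussian z, and the
peak-level threshold `z*` solves `E[EC](z*) = α` with

    E[EC](z) = P(Z > z) + R₂ · (4 ln 2)/(2π)^{3/2} · z · e^{−z²/2},
    R₂ = area / FWHM²,

at α = 0.01. Model selection: both models significant → smaller AIC;
one → that model; neither → no age effect. A direction filter then drops
anti-maturation vertices (FA must rise: exponential `A < 0` / linear
slope > 0; MD must fall: the opposite signs) — such vertices are rare and
never survive correction in practice, and the filter changes inclusion
only, never estimates.

For exponential vertices the plateau age is the age at which 90% of the
remaining change from the youngest modeled age is complete:

    T = age_min + t·ln 10,    se_T = ln 10 · se_t  (exact, T is linear in t),

with `age_min = 6`. The annual rate up to the plateau is
`|y(T) − y(6)|/(T − 6) = 0.9·|A|·e^(−6/t)/(t·ln 10)`; linear vertices
report `|a|`. Sex differences in T are declared per vertex (or tract)
only where the female and male `T ± se_T` intervals are disjoint, also
reporting which sex is earlier. Tract summaries report the percentage of
vertices per model relative to all valid vertices, with means of `t`, `T`,
SEs and rates over the significant-exponential mask (linear rate over the
linear mask); bilateral tracts are pooled by unioning the two sides'
vertex sets before averaging, while fitting itself stays per side.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `fa_min` | 0.2 | FA floor for the max-FA projection; below it a vertex is missing |
| `samples_per_spoke` | 11 | samples per half-spoke; auto-densified so the step ≤ half the smallest voxel edge |
| `fwhm` | 8 mm | surface smoothing kernel width, also used for resel counts |
| `alpha` | 0.01 | familywise (RFT-corrected) significance level |
| uncorrected p | 0.05 | per-vertex F-test level applied before correction |
| `age_min, age_max` | 6, 30 years | modeled age window; T is flagged when beyond it |
| exponential t grid | 0.5–50 y, step 0.5 | global stage of the exponential fit |
| t bound | 1000 y | refinement bound; hitting it marks the fit non-converged (effectively linear data) |
| noise SD (synthetic) | FA 0.03, MD 0.05×10⁻³ mm²/s | additive Gaussian measurement noise |

## Numerical choices

**Surface smoothing.** Discrete heat diffusion with the cotangent
Laplacian and lumped (one-third triangle area) mass, integrated by
explicit Euler for total time `τ = FWHM²/(16 ln 2)` in steps bounded by
`dt ≤ 0.5·min_i A_i/W_i`. Each step is then a convex combination of
neighbour values, so constants are preserved exactly and field variance
never increases. The graph (umbrella) Laplacian was considered and
rejected: it approximates the Laplace–Beltrami operator only up to a
mesh-dependent constant (≈√3 on an equilateral mesh), so a requested
8 mm kernel would not measure 8 mm; with the cotangent weights the
empirical FWHM of a smoothed impulse on a 1 mm grid is within 0.2% of
target. Negative cotangent weights from obtuse triangles are clipped at
zero to keep the convex-combination property. Missing vertices are
removed from every stencil with the remaining weights renormalized, so
missingness neither leaks zeros nor shrinks neighbours.

**Exponential fitting.** The model is linear in (C, A) given t, so stage
one profiles the SSE over a coarse t grid by conditional linear least
squares — immune to local minima at grid resolution — and stage two
polishes (C, A, t) with bounded trust-region least squares (ftol 1e−10 on
relative SSE; xtol/gtol 1e−12 so zero-residual fits also terminate).
Standard errors come from the Gauss–Newton covariance
`SSE/(n−3)·(JᵀJ)⁻¹`. Exactly linear data drive t to its upper bound; the
fit is flagged non-converged and the vertex falls back to the linear
model.

**RFT correction.** Applied to the Gaussianized p map with Gaussian EC
densities rather than native F-field densities, and the 1-dimensional
boundary resel term is omitted; resels use the nominal applied smoothing
(8 mm) for determinism, with the resel count overridable (e.g. for
residual-estimated smoothness or a joint-across-tracts correction, both
exposed as options; the default corrects per tract surface). The
combination is validated by simulation: on 2 000 smooth Gaussian null
fields matched to the fixture sheet and kernel, the familywise error at
nominal 0.01 measures ≈0.01 (≤ 0.02).

**Determinism and ties.** FA ties in the max-FA selection break toward
the sample nearest the skeleton. Out-of-bounds samples are skipped, not
zero-filled (zeros would bias the maximum). Table output rounds half away
from zero. Tensor component order on disk (lower- vs upper-triangular) is
an explicit flag, never guessed. All generators are pure functions of
their parameters and seed.

## The synthetic cohort

The generator emulates the cross-sectional study design the analysis
assumes: 178 subjects (83 M / 95 F) with ages uniform on 6–30 years by
default (a truncated-normal preset matches the empirical per-sex moments
15.6 ± 6.1 / 16.0 ± 6.4 via parent-parameter moment matching); per-vertex
ground truth drawn per labeled region as exponential, linear, or no-age-
effect, then spatially smoothed so parameter maps are smooth at the
analysis kernel scale; additive Gaussian noise on the projected measures;
optional sex effects (scaled male time constants, offset asymptotes); and
optional embedded tensor volumes in which in-tract voxels carry prolate
tensors (principal axis along the local surface tangent) whose FA and MD
equal the growth curves at the subject's age, against an isotropic
background below the projection threshold.

Default parameter ranges are anchored to published tract-level fits:
asymptotes C ∈ 0.45–0.60 (FA), time constants t ∈ 3–6 y, and amplitudes
A ∈ −0.45…−0.25, the range implied by back-computing
`|A| = rate·t·ln 10/(0.9·e^(−6/t))` from tabulated rates and time
constants; MD regions use C ∈ 0.70–0.80×10⁻³, A ∈ 0.25–0.50×10⁻³ mm²/s.
With the default noise, vertexwise fit correlations fall in the 0.4–0.7
band typical of maturation fits at ~90 subjects per sex.

What the generator does *not* emulate: registration error and
inter-subject anatomical misalignment, Rician noise on raw diffusion
images, crossing-fiber effects on the tensor model, spatially correlated
measurement noise, and longitudinal (within-subject) structure. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the stated noise model, not that the projection is
robust to misregistration or tensor-model violations on real MRI data.

## Problem sizes used in validation

Simulation-based checks run at sizes chosen to keep the full suite fast
while leaving Monte-Carlo error well below the tested margins: recovery
uses 500 exponential vertices × 90 subjects per sex (fitted on smoothed
maps, the pipeline's measurement path — on raw unsmoothed vertices the
median relative t error roughly triples); familywise calibration uses
2 000 null fields on a 1 891-vertex 1 mm sheet; F-test calibration uses
10 000 null vertices; projection round trips use a 200-vertex sheet in a
1 mm-voxel volume.

## Known limitations

* The boundary-resel omission makes the RFT threshold slightly liberal
  for surfaces whose perimeter is large relative to their area; the
  simulation check covers the bundled fixture geometry, not arbitrarily
  thin tracts.
* The plateau age is undefined for linear vertices by construction, so
  tract mean T is a mean over the exponential subset only; tracts whose
  maturation is near-linear over 6–30 y (large t) report T from the few
  vertices where curvature is detectable, a selection that biases T
  downward.
* Per-vertex exponential SEs assume independent Gaussian residuals;
  surface smoothing correlates neighbouring vertices, so mean-over-mask
  SEs understate tract-level uncertainty (means of per-vertex SEs are
  reported, matching the published tables' convention).
* Tensor interpolation is component-wise linear, not Log-Euclidean;
  differences are second-order at voxel scale but bit-for-bit results
  depend on this documented choice.
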