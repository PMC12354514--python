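# Methods

## Model

A planar leaf boundary is represented in polar coordinates about a pole
near the leaf base.  The simplified Gielis equation (the `k = m = 1`
specialisation of the superformula) gives the radius at polar angle θ as

    r(θ) = a · (|cos(θ/4)|^{n2} + |sin(θ/4)|^{n3})^{−1/n1},   θ ∈ [0, 2π).

`a` (length units) sets the scale and tracks leaf size; `n1` is the
principal shape exponent — smaller `n1` gives a longer, narrower outline;
`n2` and `n3` shape the two flanks and are equal exactly when the outline
is bilaterally symmetric.  The three fitted variants are nested: SGE-1
frees all four parameters, SGE-2 ties `n3 = n2`, SGE-3 additionally fixes
`n2 = n3 = 1`.  Two properties matter computationally: the radius is
homogeneous of degree one in `a` (so `∂r/∂a = r/a`, used as a derivative
oracle in the tests), and `r(θ)` is only 4π-periodic when `n2 ≠ n3`, so
every evaluation path wraps θ into `[0, 2π)` with one fixed convention.

Absolute values are taken before exponentiation, so non-integer exponents
are safe everywhere; the integrand is non-differentiable only where
`cos(θ/4)` or `sin(θ/4)` vanishes (θ = 0 in the working domain).

## Estimation

Parameters are estimated per leaf and variant by least squares on the
polar radii, `RSS = Σᵢ (rᵢ − r̂(θᵢ))²`, with Nelder–Mead.  Design choices:

* **Positivity** is enforced by optimising in log-parameter space; all
  reported quantities are back-transformed.  Out-of-basin parameters
  (scale above a few contour diameters, pole far outside the contour's
  neighbourhood) receive a large finite penalty: beyond that region the
  radius profile flattens and `a` and `n1` become confounded.
* **Multi-start**: a deterministic lattice of initial vectors
  (`a ∈ {0.5, 1, 1.5}·max rᵢ`, `n1 ∈ {0.01, 0.05, 0.1, 0.5}`,
  `n2, n3 ∈ {0.5, 1, 2}`; 12–108 points by variant) is screened by a
  single objective evaluation each, and full Nelder–Mead runs start from
  the best `n_starts` (default 3) plus warm starts.  Screening rather
  than optimising from every lattice point keeps 500-leaf batches
  tractable without sacrificing determinism: identical inputs and
  configuration give bitwise-identical results.
* **Pose**: the polar frame (pole x, y and axis rotation) is seeded at
  the two endpoints of the contour's maximal chord (nudged just inside,
  since the Gielis pole lies inside the outline at distance r(π) from the
  base) and then, by default, co-optimised with the shape parameters as
  nuisance coordinates.  Co-optimisation is necessary for exactness: no
  pole fixed from raw geometry reproduces a noise-free curve, because the
  true pole sits r(π) inside the base, a distance that depends on the
  unknown `n1`.  The nuisance coordinates are *excluded* from the
  parameter count `P` used in RMSE, AIC, `K_c` and the curvature
  diagnostics, so `P` is always the variant's 4/3/2.  A pure two-stage
  mode (`co_optimize_pose=False`) keeps the chord-endpoint pole fixed.
* **Nesting**: variants are fitted simplest-first and each richer variant
  is warm-started at its nested predecessor's full solution (parameters
  and pose).  Since Nelder–Mead never returns a point worse than its
  start, RSS(SGE-1) ≤ RSS(SGE-2) ≤ RSS(SGE-3) holds exactly per leaf.
* **Convergence**: `xatol = fatol = 1e−10`, 5000 iterations per run, with
  restart rounds from the incumbent best vertex until the objective stops
  improving (recovers from simplex collapse; reaches RSS ≈ machine zero
  on noise-free data).

Goodness of fit per leaf: `RMSE = √(RSS/(N−P))` and the full Gaussian
log-likelihood AIC, `AIC = N ln 2π + N ln(RSS/N) + N + 2(P+1)`, counting
the error variance as a parameter.  The additive constants cancel in
within-leaf model comparisons, so any consistent AIC convention yields the
same orderings; the constant-included form keeps absolute values
comparable across tools.  `RSS = 0` maps to `AIC = −∞` with a warning.

## Nonlinearity diagnostics

At a converged fit the local linearisation is built by central finite
differences **in the original parameters** (the close-to-linear question
concerns `a, n1, n2, n3` themselves, not their logs): steps
`max(|φ̂ⱼ|, 0.01)·1e−5` for the velocity matrix `V` (N×P) and `·1e−3` for
the acceleration array `W` (N×P×P, symmetrised).  Angles within 1e−9 of
the |·| kinks are excluded and N reduced accordingly.  Finite differences
were preferred over symbolic derivatives because the kinks make global
symbolic forms piecewise; the analytic `∂r/∂a = r/a` column and closed-form
test models validate the FD machinery.

The Bates–Watts construction then proceeds via the thin QR of `V`:
transforming `W` on both parameter indices by `R^{−1}` expresses the
acceleration in an orthonormalised parameterisation; each face's
observation vector is split into its tangent-space component (coordinates
on Q) and normal component (orthonormal basis of the residual span), and
scaled by the standard radius `ρ = s√P` with `s = √(RSS/(N−P))`.  The
root-mean-square relative curvatures are the sphere averages of the
squared directional curvature, computed in closed form through
`E[(dᵀAd)²] = (2 tr A² + (tr A)²)/(P(P+2))`:
tangent faces give the parameter-effects curvature `γ_T`, normal faces the
intrinsic curvature `γ_N`.  Both scale linearly in `s` by construction;
`γ_N` is invariant under smooth reparameterisation while `γ_T` is not —
both properties are asserted in tests, the former to 0.1%, as is agreement
with a 100,000-direction Monte-Carlo sphere average to 1%.

Curvatures are judged against the critical curvature
`K_c = 1/√F(P, N−P; α)` with α = 0.05 (upper-α F quantile; note that K_c
*increases* with P at fixed N, since upper F quantiles fall as the
numerator degrees of freedom grow).  `γ_N < K_c` accepts the planar
assumption, `γ_T < K_c` the uniform-coordinate assumption.

Per parameter, Box's second-order bias approximation

    bias = −(s²/2) (VᵀV)^{−1} Σᵢ vᵢ tr[(VᵀV)^{−1} Wᵢ]

is reported as a percentage of the estimate, `P_b = 100·bias/φ̂`, with
|P_b| < 1% flagging close-to-linear behaviour of that estimator.  The
formula is validated against the mean bias of 20,000 simulated refits of a
one-parameter exponential model; antithetic noise pairs are used there
because the bias (~6e−5) is smaller than the naive Monte-Carlo standard
error at that sample size, while pairing cancels the linear error term
exactly.

## Model comparison

Per-leaf RMSE and AIC are compared between variant pairs with the
two-sided Wilcoxon signed-rank test at α = 0.05, without multiplicity
correction across the three pairs.  Zero differences are discarded
(classical convention; Pratt's method available behind a flag); tied
absolute differences receive midranks.  For ≤ 25 effective pairs the exact
null distribution is computed by dynamic programming over doubled midranks
(exact even under ties); above that, the normal approximation with
continuity and tie corrections.  Population summaries report percentages
of leaves passing each curvature/bias criterion, always with the
denominator actually used: non-converged fits and fits whose velocity
matrix is numerically rank-deficient are excluded and counted, never
silently folded into a denominator.

## Synthetic data

The generator emulates the target study's conditions: populations of ~250
leaves per species, ~2000 arc-length-equidistant boundary points per leaf,
small multiplicative radial noise, and arbitrary placement in the plane.
Per leaf: the equal-arc-length angle grid is solved on the true curve (16×
oversampled cumulative arc length, inverted by interpolation), so
noise-free points lie exactly on the curve while spacing is uniform to
well under 0.1%; radii are then perturbed as `r·(1+ε)`,
`ε ~ N(0, σ_rel²)` clipped at ±4σ (σ_rel default 1%, a value chosen to
keep diagnostics non-degenerate while leaving fits identifiable; the
clipping bound must stay below 1, i.e. σ_rel < 25%); finally the contour
is rotated and translated.

Truth parameters are drawn log-uniformly: `a ∈ [5, 15]` length units,
`n1 ∈ [0.02, 0.12]`, `n2, n3 ∈ [0.5, 2]` with `|log(n3/n2)| ≤ log 1.5`
(mild asymmetry).  Draws whose noise-free outline leaves the lanceolate
width-to-length band [0.05, 0.35] are rejected and redrawn.  These ranges
were calibrated once to produce the lanceolate regime, not tuned to any
per-leaf estimates.

What the generator does **not** emulate: spatially correlated digitisation
noise along the boundary, scanner artefacts, leaf damage, serration or
petiole remnants.  Radial noise is independent across points, which at
2000-point density produces a locally jagged polygon; consequences are
(i) polygon perimeter is not a robust statistic of noisy contours (area
is), and (ii) passing tests demonstrate correctness of the estimation and
diagnostic machinery under the stated error model, not robustness to
structured real-world artefacts.

## Problem sizes and numerical conventions

The shipped verification suite runs the method at the scales it targets:
parameter recovery on 100 leaves × 2000 points, the population trade-off
study on 200 leaves × 3 variants × 2000 points, 100,000-direction
Monte-Carlo curvature averages and 20,000-refit bias simulations — chosen
as the smallest sizes at which the population statistics are stable.  All
batch CSV output is printed with 10 significant digits, making repeated
runs byte-identical.  Degenerate inputs are surfaced, not patched:
collinear contours, poles on the boundary, empty or short files, and
all-zero Wilcoxon differences each raise (or flag) a distinct, named
condition.

## Known limitations

* The pole/axis convention (maximal-chord seeding + co-optimisation) is a
  reconstruction; digitised datasets produced with a different pole
  convention will yield slightly different absolute RMSE values, though
  within-leaf model orderings are insensitive to this.
* The AIC constant convention matters only across tools, not across
  models on the same leaf.
* Box bias and the curvature measures are local second-order quantities;
  they say nothing about multimodality of the RSS surface (handled
  separately by multi-start).
* With misspecified variants (e.g. SGE-3 on an asymmetric leaf) `s`
  absorbs model error, inflating relative curvatures; this mirrors how
  the measures behave on real data, where every model is an
  approximation.
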