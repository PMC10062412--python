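# Methods

## Model and state space

The package implements a four-dimensional Itô SDE for tumor virotherapy
under immune pressure.  In non-dimensional variables (populations
scaled by the tumor carrying capacity `C`, time by the lysis rate `δ`):

    dx  = [ r x (1 − x − y) − a x y − l2 x z2 ] dt
    dy  = [ a x y − l1 y z1 − y ] dt
    dz1 = [ e1 y z1 − d1 z1 ] dt + τ1 z1 dW1
    dz2 = [ e2 y z2 − d2 z2 ] dt + τ2 z2 dW2

with independent standard Brownian motions `W1, W2`.  Free virus is
implicit in the bilinear infection term `a x y`.  The noise is
multiplicative and diagonal — each driver multiplies exactly one
coordinate, and that coordinate's diffusion coefficient depends only on
itself — which the integrator exploits.  The set
`D = {x, y, z1, z2 ≥ 0, x + y ≤ 1}` is almost surely invariant for the
exact flow; simulated states may leave it only by discretization error,
which the stepper monitors (below).

The map between dimensional and non-dimensional constants is
`r = λ/δ`, `a = βC/δ`, `l_i = k_iC/δ`, `e_i = s_iC/δ`, `d_i = c_i/δ`,
with `τ_i → τ_i/√δ` so the rescaled Brownian motions remain standard.
`nondimensionalize` records `(δ, C)` in a provenance field because the
non-dimensional system forgets them; `redimensionalize` inverts the map
exactly.  The ratio `ρ = e2/e1` is computed once at parameter
construction and carried on the parameter object so every module uses
one consistent value.

## Regime classification

Long-term behavior is decided by closed forms: the infection value
`θ = r(a−1)/(a(a+r))`, the stochastic relative clearance rates
`h_i = d_i/e_i + τ_i²/(2e_i)`, the exponents `λ_i = e_i(θ − h_i)`, and
for `h1 = h2 =: h` the combined `λ = θ − h`.  The decision tree first
orders `h1` vs `h2` (Case 1 `h1 < h2`: adaptive compartment dies out;
Case 2 the mirror image; Case 3 equality), then compares `a` with 1 and
the case's exponent with 0.

Floating-point choices:

* `h1 = h2` is measure-zero in floats; equality uses a relative
  tolerance `eq_tol` (default 1e−10) and the report records which
  branch was taken together with `|h1 − h2|`, so the symmetric analysis
  only triggers for deliberately symmetric parameters.
* `a = 1` or a vanishing exponent (within `eq_tol`) yields an explicit
  `"critical"` outcome rather than a silent side: the classification
  theorems do not cover the thresholds, and the attractor at such
  points is genuinely unresolved.

For symmetric clearance, `λ > 0` is equivalent to `a ∈ (a1, a2)` where
`a1 < a2` are roots of `m(a) = a² + r(1 − 1/h)a + r/h`; the window
exists iff `h < 1` and `r > 4h/(1−h)²`.  Roots come from the closed
quadratic formula (cross-checked in tests against a polynomial root
finder at 1e−10).

Supports of the persistent invariant measures are represented
symbolically (parameter map plus open interval) with a sampler for
tests and plots.  The leaf segments `S(k)` are reported on the printed
interval `(0, (a−1)/l1)`, but for large `k` their infected-cell
coordinate turns negative partway: the sampler restricts to the
sub-interval where the image stays in the closure of `D` (the root of
`l1 z1 + k a l2 z1^ρ / r = a − 1`, found by bisection), where all the
measure's mass lives.  Boundary-measure Lyapunov exponents are obtained
by evaluating the per-capita growth rates of the model fields at the
degenerate supports — e.g. the tumor exponent at the origin measure is
`r`, the infected-cell exponent at the tumor-only state is `a − 1`, and
the innate exponent at the immune-free point is `λ1`.

## Integration schemes

Two steppers share one compiled inner loop:

* **euler-maruyama** — `U + f dt + g ΔW`, strong order 1/2.
* **srk1** (default) — a derivative-free strong-order-1 scheme for
  diagonal noise: the drift is advanced with a two-stage Heun step
  (predictor includes the noise increment), and the Milstein term
  `g_j' g_j I(j,j)` is replaced by the stage difference
  `(g_j(H_j) − g_j(U))/√dt · I(j,j)` with supporting value
  `H_j = U + f dt + g_j √dt`.  On scalar geometric Brownian motion the
  step equals the analytic Milstein step up to O(dt^1.5) stage terms;
  with zero noise it is exactly Heun's method.  For this diffusion the
  cross iterated integrals carry zero coefficients, so only the exact
  diagonal `I(j,j) = ((ΔW_j)² − dt)/2` enters the update.

The scheme family was chosen for validation transparency rather than to
match any particular published coefficient tableau: the order claims
are established empirically (root-mean-square endpoint error against
the exact GBM solution coupled to the same Brownian path has log–log
slope 0.5 for Euler–Maruyama and 1.0 for srk1, tested at ±0.15).

`iterated_integrals` also provides the cross integrals for generality:
sub-step Euler sums over a Brownian-bridge refinement conditioned on
the supplied increments.  With a single substep the cross entries are
zero (degenerate approximation); with ≥ 2 substeps the discrete
quadratic covariation is split symmetrically between `I(1,2)` and
`I(2,1)` so the integration-by-parts identity
`I(1,2) + I(2,1) = ΔW1·ΔW2` holds exactly, and the variance of the
construction is `dt²/2 · (1 − 1/(2m))` at `m` substeps, converging to
the exact `dt²/2`.

**Positivity.**  The immune components are almost surely positive under
the exact flow, but any explicit scheme can step them across zero.
Log-space updates would change the order analysis, so instead a local
step whose `z` would turn non-positive is rejected and split into two
conditioned half-steps (Brownian-bridge midpoint), recursively to depth
10, after which the run aborts.  This preserves the stepper's
distributional accuracy; at the default `dt = 1e−3` and baseline noise
the mechanism never fires (it is exercised in tests with coarse steps
and strong noise).  The bridge midpoints are the only randomness not
drawn from the trajectory's numpy generator; they come from a stream
seeded deterministically from the trajectory seed.

**Domain handling.**  Tumor-fraction overshoots of `D` up to
`domain_tol` (default 1e−6 per step) are clamped and counted; larger
overshoots up to a hard cap (1e−3) are clamped and recorded as
violations; beyond the cap the run aborts, since `D`-invariance of the
exact flow means persistent violations indicate a step-size problem.
On the baseline fixture at `dt = 1e−3` the clamp fraction is zero in
practice (the acceptance suite asserts < 0.1% over random interior
starts).

**Defaults.**  `dt = 1e−3` and `save_stride = 100` (saved grid spacing
0.1) for horizon-2000 studies; halving `dt` changes reported Lyapunov
estimates by well under 1% (the manifold-identity error, a direct probe
of pathwise discretization error, is ~4×10⁻⁴ and halves with `dt`).
Brownian increments are generated on the fine grid from
`numpy.random.default_rng(seed)` and partially summed for the saved
driver values, so stored paths are exactly those the stepper consumed;
identical inputs give bit-identical trajectories.  Per-replicate seeds
are derived by `SeedSequence` spawning, so sweeps are embarrassingly
parallel and reproducible.

## Ergodic analysis

**Occupation histograms.**  By the strong law of large numbers for an
ergodic invariant measure, the relative occupation time of one long
trajectory approximates the stationary density.  The default is a
60×60-bin histogram of the `(x, y)` projection over the retained data
range, with 10% of the horizon discarded as burn-in for density work
(the endpoint exponent estimator uses no burn-in by default, matching
its defining formula).

**Shape classification.**  "One-peak" vs "crater" is operationalized
as: smooth the histogram mildly (Gaussian, σ = 1.5 bins), standardize
each axis by the occupation standard deviation, and compare the density
near the occupation centroid (maximum over the disc of radius one
quarter of the RMS distance — robust to sub-bin peaks slightly offset
from the centroid, while inside a crater the disc sits in the
low-density hole) with the maximum density on the ring at the RMS
radius.  Ratios above 1.5 are `unimodal`, below 0.67 `crater`,
otherwise `indeterminate`.  The disc radius was calibrated on synthetic
fixtures with known shape (Gaussian cloud, uniform annulus, jittered
limit cycle) and on the baseline leaves; the ratio thresholds are the
package defaults and configurable.  At horizon 2000 the label is
realization-dependent near the transition: mid leaves (the `k = 5`
demo) are genuinely ambiguous, and an occasional realization of an
extreme leaf can read `indeterminate`.

**Lyapunov exponents.**  The defining estimator is the endpoint
quotient `ln c(T)/T` per solution component.  With a positive burn-in
`b` the difference quotient `(ln c(T) − ln c(b))/(T − b)` is used
instead, removing the `ln c(0)/T` initial-value term and the transient
while the tumor components settle; a regression slope of `ln c(t)` on
the retained window is always reported alongside as a diagnostic.  For
components bounded in (0, 1] the endpoint estimate is ≤ 0 by
construction.  Extinction-rate checks compare seed-averaged estimates
with the predicted exponents within Monte-Carlo standard errors; the
study conditions for those checks use noise `τ = 0.2` so the estimator
has measurable spread (at `τ = 0.01` its fluctuation is smaller than
the unavoidable O(1/T) finite-time bias, and a standard-error bracket
would be vacuous), with horizons chosen so `ln z` stays far above the
float64 underflow floor of ≈ −709.

**k-sweep.**  For each `k` on a grid (default 25 log-spaced points in
[0.01, 10]) and each replicate seed, one trajectory starts from
`(0.5, 0.5, 0.01k, 0.01)` and all four endpoint exponents are
estimated; the result records sign changes of the seed-averaged `z1`
exponent along the grid.  Only the existence of at least one sign
change is asserted anywhere — crossing locations are figure-level
quantities.  The sweep refuses parameter sets outside the symmetric
Hopf window, pointing the user to `classify_regime`.

**Invariant-manifold identity.**  For symmetric clearance the foliation
identity `z2(t) = k z1(t)^ρ exp(τ2 W2 − ρ τ1 W1)` holds almost surely
with `k = z2(0)/z1(0)^ρ`.  `manifold_check` evaluates it along a saved
path using the stored drivers; the maximum relative deviation is pure
discretization error (≈ 4×10⁻⁴ at `dt = 1e−3` on the baseline, halving
with `dt`).  Asymmetric parameter sets are refused at the default
tolerance; a diagnostic override exists and is used in tests to confirm
the check has power (deviation grows secularly once `d2` is perturbed).

**Distance to support.**  Euclidean distance of retained states to a
support segment, minimized over the parameterization by dense sampling
(2048 points) plus local parabolic refinement.  Note a structural
limitation: the martingale factor in the foliation identity has a
Brownian exponent, so a path's `z2/z1^ρ` wanders around its initial `k`
on long horizons and the pathwise distance to a *fixed* leaf segment
does not shrink to zero — the meaningful statement, which the tests
assert, is that a path stays markedly closer to its own leaf than to
distant leaves.

## What the generator does and does not emulate

The simulation module doubles as the data generator for all ergodic
analysis.  Its defaults are the study conditions: baseline parameters
`r = 0.36, a = 5, l1 = l2 = 0.48, e1 = e2 = 10, d1 = d2 = 0.4,
τ1 = τ2 = 0.01`, initial states `(0.5, 0.5, 0.01k, 0.01)`, horizon
[0, 2000].  It emulates exactly the model's assumptions — logistic
tumor growth, implicit free virus, immune-only multiplicative noise,
independent drivers.  It does not emulate features of real tumors
outside the model: explicit virion dynamics, spatial structure,
cell-cycle delays, measurement noise, or parameter uncertainty.
Passing tests therefore validate the mathematical claims about this
SDE, not the fidelity of the SDE to any particular tumor system.

## Known limitations

* Critical parameter values (`a = 1`, vanishing exponents) are
  reported as unclassified; the attracting object there is unknown.
* Stationary densities are approximated by single-trajectory occupation
  only; no kernel density estimation or confidence bands.
* The interior measures `π(k)` have no closed form (the associated
  stationary Fokker–Planck problem is intractable); all interior
  statements are Monte-Carlo.
* Exponent estimates carry O(1/T) finite-time bias; the k-sweep's sign
  structure is robust to it, but individual values near zero are not
  sign-stable across realizations — which is precisely the
  D-bifurcation phenomenon under study.
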