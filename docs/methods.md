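# Methods

## Model

The package implements stochastic actor-based models for the joint
evolution of a directed friendship network and an ordinal behavior
(alcohol-use frequency, six levels coded 1–6) between two observation
waves.  The core assumptions are the standard ones for this model class:

* **Continuous time, one change at a time.**  Between waves the state
  follows a Markov chain whose elementary transitions are micro-steps: one
  actor toggles one outgoing tie, or moves its behavior one level.  Change
  opportunities arrive as a Poisson process with intensity
  `n(λ_net + λ_beh)` over the unit-length period; the period is normalized
  to 1 and the rates absorb real elapsed time (about a year between
  waves).  The focal actor is uniform among all students; the side
  (network vs behavior) is drawn proportionally to the rates.
* **Myopic stochastic optimization.**  At a micro-step the actor evaluates
  each candidate state through its objective function
  `f_i = Σ_k β_k s_ik(x, z, v)` plus an independent random component.  The
  random component is standard Gumbel, which makes the choice a
  multinomial logit over candidate states — realized directly by logit
  sampling, never by explicit utility draws.  Utilities are computed as
  objective differences (change statistics), which is identical to
  evaluating `f_i` at each candidate state because the logit is
  shift-invariant.
* **Covariates are fixed** within a period; behavior enters the network
  side as a time-varying covariate (alcohol ego / alter / similarity).

### Effect catalog

Network side: density `Σ_j x_ij`, reciprocity `Σ_j x_ij x_ji`, transitive
triplets `Σ_{j,h} x_ij x_jh x_ih`, 3-cycles `Σ_{j,h} x_ij x_jh x_hi`,
in-/out-degree popularity `Σ_j x_ij deg(j)` (raw degrees, not square-root
variants; the square-root form would be a one-line change in the kernel),
out-degree activity `(Σ_j x_ij)²`, and covariate effects ego
`(v_i − v̄) Σ_j x_ij`, alter `Σ_j x_ij (v_j − v̄)`, similarity
`Σ_j x_ij (sim_ij − s̄im)` with `sim_ij = 1 − |v_i − v_j|/range(v)`, and
same `Σ_j x_ij 1[v_i = v_j]` (uncentered).  Behavior side: linear and
quadratic shape `z̃_i`, `z̃_i²`, average-alter influence
`z̃_i · (Σ_j x_ij z̃_j / Σ_j x_ij)` (0 for actors without out-ties), an
average-similarity variant behind the same catalog, and covariate effects
`z̃_i (v_i − v̄)`.

The default catalogs cover the full model: 19 network-selection
effects (structure, age/gender/race homophily, alcohol ego/alter/
similarity) and 8 behavior effects (shape, average-alter influence, age,
gender, minority status, parental drinking, family bonding).  Gender and
race enter selection as *same* indicators, age and alcohol as similarity
effects.  The influence effect defaults to the average-alter form —
closest to "drift toward the average drinking of immediate friends" — with
average-similarity available by name.

### Centering

Constants are fixed once per school and reused in every simulation for
that school: numeric covariates centered at the school mean, similarity
scores at the mean wave-1 pairwise similarity, behavior at the grand mean
over both observed waves (carried-forward entries excluded).  The behavior
range is the fixed scale range 5; covariate ranges are observed ranges.
The synthetic generator, which must act before wave 2 exists, centers
behavior at the wave-1 mean; the resulting shift is absorbed almost
entirely by the linear-shape parameter (logit choices depend only on
statistic differences) and a self-consistency experiment (t-ratios at the
generating parameters centered on zero across panels) confirms no material
bias.

## Sample construction

Following the conventions for two-wave school panels: actors who neither
name nor are named by anyone at either wave are removed (idempotent);
wave-2 non-responders get their outgoing tie row and behavior carried
forward from wave 1 and flagged non-informative, while incoming ties
reported by responders are kept; a school is retained only if its Jaccard
tie-stability index `J = F11/(F11+F01+F10)` is at least 0.20 (boundary
inclusive), computed over responder rows only so that carried-forward
copies cannot inflate apparent stability.  Retention percentages use a
floor-at-one-decimal rule (2299/2563 = 89.69…% reports as 89.6).

## Estimation

Unconditional Method of Moments: one target statistic per parameter — the
observed tie-change count and behavior-change count for the two rates, and
the wave-2 effect statistics `Σ_i s_ik(x(t2), z(t2))` for the βs.  All
sums run over responding actors only, with non-responder out-rows zeroed
before evaluation, for observed and simulated states alike; imputed data
therefore never enter the moment conditions.  Estimation is declared
degenerate when a modeled side shows zero observed change.

The solver has the classic three-phase shape with two modernizations:

1. **Phase 1.**  Sensitivity matrix `D = ∂E[S]/∂θ` at the starting point
   (density −1, other βs 0, rates from observed change counts) by central
   finite differences with common random numbers (ε = 0.3, halved if a
   perturbed simulation misbehaves; `estimate_derivative` keeps ε = 0.1 as
   its own default and raises on condition numbers above 1e8).
2. **Phase 2.**  Robbins–Monro subphases (default 3), one simulation per
   iteration, update `θ ← θ − a·D⁻¹(S_sim − S_obs)` with the gain halved
   and the iteration count doubled per subphase, and θ set to the
   trajectory average at each subphase end (Polyak averaging).  Updates
   use only the *diagonal* of D: the diagonal of the paired-simulation
   estimate is accurate, while noisy off-diagonal entries can flip the
   update direction for near-collinear effects and send the iteration
   running away.
3. **Polish + Phase 3.**  A damped Newton (Levenberg–Marquardt) iteration
   on simulated moment means with escalating replicate counts, using the
   full sensitivity matrix estimated by the likelihood-ratio identity
   `D = Cov(S, ∂log P/∂θ)` from the same replicates — the path score is
   accumulated exactly during simulation (chosen-option statistic minus
   its choice-probability expectation per micro-step; `N_side/λ − n` for
   the rates).  Steps are accepted only if the sd-weighted residual norm
   does not increase; the damping parameter adapts accordingly, and the
   best point by max |t| is retained.  Phase 3 freezes θ, simulates a
   large replicate set (default 2500) for the convergence t-ratios
   `t_k = (mean S_k − S_obs,k)/sd(S_k)`, and forms the delta-method
   covariance `D⁻¹ Σ D⁻ᵀ` with Σ the replicate target covariance; standard
   errors are the square roots of its diagonal.  Non-convergence triggers
   up to three restarts that re-enter phase 2 (from the initial point when
   the current estimate is badly stuck); the best solution is returned
   with `converged = False` if the 0.10 threshold is never met.

The phase-3 replicate count matters for the convergence declaration: the
Monte-Carlo noise floor of each t-ratio is about `1/√n3`, so certifying
max |t| < 0.10 over ~8 statistics meaningfully requires a few thousand
replicates.  The `scaled` profile (n3 = 2000, smaller phase-1/2 sizes) is
used throughout the test suite; a 60-student school fits in seconds to a
couple of minutes on one CPU.

Per-parameter p-values use the normal approximation `θ̂/se`: right-sided
`1 − Φ`, left-sided `Φ`, two-sided `2·min`.

## Meta-analysis

Per-school estimates are pooled effect by effect (rates are
school-specific).  The Snijders–Baerveldt two-stage test treats
`θ̂_j = μ + U_j + E_j` with `Var U_j = σ²` and known `Var E_j = se_j²`,
iterating weighted least squares with weights `1/(se_j² + σ̂²)` and a
method-of-moments update of σ̂² on the weighted residual statistic
(Paule–Mandel fixed point, truncated at zero, Δ < 1e-8, ≤ 100 iterations);
σ̂² = 0 collapses to fixed-effect inverse-variance pooling.  The two-sided
p uses a t reference with N − 1 degrees of freedom — honest at a dozen
schools, where a normal reference would be anti-conservative.  Fisher's
combination `T = −2Σ ln p_j ~ χ²(2N)` is applied separately to the
right- and left-sided per-school p-values (clamped below at 1e-12 with a
logged warning).  The decision rule marks an effect significant when
either Fisher tail is ≤ .025 (the halved level controls for testing both
tails; boundary inclusive) or the pooled two-sided p is < .05; on
disagreement the note records the Fisher verdict as decisive, schools
varying widely in size.  Selection coefficients convert to odds ratios as
`exp(β)` (reported to two decimals; the function itself returns the exact
value so that `exp(−β)` is exactly the reciprocal), with an optional
normal-approximation interval `exp(β ± 1.96·se)` — note this interval
construction is the only interval offered for such
coefficients, and no attempt is made to match any other construction.

## Synthetic data

The generator emulates the statistical shape of a saturated-school
adolescent panel; its defaults are the study conditions.

* **Schools:** 13, sizes (48 … 987) summing to 2,563 students.
* **Covariates** (independent marginals): male 0.508; race five categories
  (0.609, 0.164, 0.016, 0.034, 0.177) with minority = non-white 0.391;
  age truncated normal 15.8 ± 1.3 on [12, 18], rounded to the month;
  parental drinking five levels (0.562, 0.271, 0.074, 0.056, 0.037);
  family bonding 1–5 with P(≥4) = 0.60.
* **Initial behavior:** (0.496, 0.183, 0.142, 0.083, 0.048, 0.048) — the
  top survey category mass split evenly over internal levels 5 and 6.
* **Wave-1 network:** a homophilous configuration-style draw, not a
  stationary model draw (wave 1 is conditioned on, not modeled, in the
  analysis): out-degrees Poisson with mean 2.04 truncated at the
  10-nomination instrument cap, targets chosen by Gumbel-top-k logit
  scores on age proximity, same gender, same race and alcohol similarity,
  plus a 13% reciprocation step (base mean deflated accordingly) that
  brings the mutual-tie share near the observed ~23%.
* **Wave 2:** forward simulation at a known `theta_true` — by default
  density −3.0 (shifted per school by `−ln(n/197)` so that mean degree,
  not tie density, is the cross-school invariant), reciprocity 2.5,
  transitive triplets 0.6, gender-same 0.36, age similarity 1.48, alcohol
  similarity 1.28; behavior linear −0.6, quadratic 0.07, average-alter
  0.07; rates 3.5 and 1.2, calibrated so that between-wave Jaccard indices
  fall within [0.15, 0.45] (bracketing the observed .200–.325) and about
  half the students change drinking frequency.
* **Attrition:** wave-2 response only; `logit P(lost) = −2.197 + 0.392·1[z₁ ≥ 5]`,
  i.e. ~10.0% for lighter and ~14.1% for weekly-plus drinkers.  This
  reproduces both the overall 89.6% retention and the observed
  composition contrast (weekly-plus drinkers are ~13% of the lost vs ~9%
  of the retained).  Carried-forward imputation is applied on generation.

What the generator does **not** emulate: school stratification or survey
weights, grade structure, within-wave timing, cross-covariate correlation
(age by race, etc.), or any dependence of attrition on network position.
Passing tests therefore demonstrate the correctness of the machinery under
a faithful but idealized data-generating process, not the substantive
conclusions of any particular survey.

## Numerical choices

* All randomness is pre-drawn from a single numpy Generator per
  simulation (event count, sides, actors, one choice uniform per event),
  so runs are bit-reproducible and the compiled kernel and the pure-Python
  trace path follow identical micro-step paths.
* Per-replicate seeds derive from the master seed by `SeedSequence`
  spawn keys, making replicate sets independent of evaluation order; every
  fit records its seed.
* Softmax evaluations subtract the maximum utility; probability vectors
  sum to 1 within 1e-12.
* θ is kept in a sane box during optimization (rates in [0.05, 30],
  effects in [−12, 12]); steps are norm-capped.
* Ties are dense int8/float64 matrices; per-effect payloads are value
  vectors plus centering scalars, O(K·n) memory, so the largest school
  (n ≈ 1000) stays cheap.
* The out-degree nomination cap is not enforced in estimation by default
  (an `out_degree_cap` option exists for sensitivity analysis); at the
  observed densities the cap virtually never binds.

## Known limitations

* **Behavior-side identification at small n.**  The linear-shape and
  average-alter statistics are nearly collinear in a single small
  two-wave panel: the sensitivity matrix routinely has condition numbers
  in the thousands with its weakest direction loading on exactly that
  pair.  Consequences: (i) standard errors on influence parameters from
  one small school are honestly enormous; (ii) for a minority of data
  draws the observed moment vector lies slightly off the model's
  attainable manifold along that direction, and *no* parameter value
  brings every convergence t-ratio below the strict 0.10 threshold — the
  fit then reports `converged = False` with its best solution, whose
  estimates still recover the generating values within their (large)
  standard errors.  The acceptance suite's recovery experiment documents
  this directly: recovery within 3 SE succeeds in all ten seeded runs,
  while the 0.10 convergence threshold is met in seven.  Pooling across
  schools is the remedy.
* Unconditional estimation only (rates as free parameters); conditioning
  on observed change counts is left as a configuration stub.
* No maximum-likelihood or Bayesian estimation, no generalized-MoM
  weighting, no goodness-of-fit auxiliary statistic suites.
* Valued or multiplex ties, endogenous covariates, dyadic covariates and
  interaction effects are out of scope.
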