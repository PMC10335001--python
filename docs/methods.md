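# Methods

## The generative model and what it emulates

`slopesim` simulates balanced three-level longitudinal CRTs: every
student is observed at every wave, every classroom has the same number
of students, and treatment is assigned at the classroom level with a
fixed count `round(p·J)` of treated classrooms (only *which* classrooms
are treated is random).  The outcome is the direct sum of the
combined-model terms — eight fixed effects plus a classroom intercept,
a correlated student intercept/slope pair, and an occasion residual.

Defaults are the study conditions of the factorial design: fixed
coefficients γ000 = 0, γ001 = 0.1, γ010 = 0.5, γ011 = 0.3, γ100 = 0.1,
γ110 = 0.5, γ111 = 0.1; σ² = 1, Tπ = [[0.2, 0.05], [0.05, 0.1]];
aptitude ~ Normal(0, 15²).  Two parameters vary by condition: γ101
(treatment × time) is 0.2/0.4/0.6 for small/medium/large slopes
difference effects (implying population contrasts 0.1/0.3/0.5 at
aptitude −1), and the classroom variance τβ00 is solved from the ICC
identity `ICC = τβ00/(σ² + τπ00 + τβ00)`, giving 0.113, 0.153 and 0.3
at ICCs 0.086, 0.113 and 0.2 (carried internally at full precision; the
3-decimal values are roundings).  Wave codes are centered and spaced by
one: (−1, 0, 1), (−1.5, −0.5, 0.5, 1.5), (−2, −1, 0, 1, 2).

Choices the design leaves open, fixed here once:

* **Aptitude distribution** — Normal.  Only the mean (0) and SD (15)
  are prescribed; Normal matches the centered-IQ framing.
* **Outcome scale** — the outcome is whatever the generative parameters
  imply; no rescaling to an IQ-like SD is applied.  (The "both
  variables on an SD-15 scale" framing is in tension with σ² = 1 and is
  not enforced; the test statistic is scale-free, so power is
  unaffected.)
* **"Low aptitude" conditional value** — −1 in raw units, even though
  aptitude has SD 15.  The probe is configurable
  (`aptitude_value`), but the default follows the stated z = −1
  convention literally.
* **Stream order** — each replication consumes its seeded stream in a
  fixed order (treatment assignment, classroom effects, aptitudes,
  student effects, residuals), making every dataset a pure function of
  (condition, parameters, seed).

What the generator does **not** emulate: missing data or dropout,
unequal class sizes, unequally spaced or varying wave schedules,
non-Normal residuals, measurement error in aptitude, more than two
arms.  Passing tests therefore speak to the idealized balanced design,
not to robustness against those features of real trials.

## REML estimation

The analysis model mirrors the generative model.  Estimation is REML
with the residual variance profiled out.  The optimizer works on
θ = (l11, l21, l22, sb), where `[[l11,0],[l21,l22]]` is the Cholesky
factor of Tπ/σ² and sb² = τβ00/σ².  This parameterization is
unconstrained — any real θ maps to a valid PSD covariance — so boundary
("singular") solutions are ordinary stationary points rather than
optimizer failures, reproducing the singular-vs-nonconverged
distinction of the lme4 family, and its profiled deviance convention
matches lme4's `REMLcrit` exactly (verified against lme4 to ~1e-5 on
identical data).

Because the design is balanced and wave codes are shared, the marginal
covariance is block diagonal by classroom with two nested closed-form
Woodbury corrections (a 2×2 capacity matrix for students, a rank-one
update for the classroom intercept).  A single O(N) pass reduces the
data to small cross-product matrices, after which one deviance
evaluation costs only 2×2/4×4/8×8 arithmetic; the hot path is
numba-compiled.  One fit of a 600-row trial takes ~2 ms, which is what
makes a 648-condition × 100-replication sweep a ~90 s computation and
1,000-replication conditions a matter of seconds.  The structured
deviance is validated against an independent dense-matrix evaluation of
the restricted likelihood (agreement to 1e-7 or better in tests).

Numerical choices:

* **Optimizer** — two-stage Nelder-Mead (initial simplex step 0.2 from
  θ0 = (1, 0, 1, 1), then a restart with step 0.02 from the first
  optimum), terminating when the simplex spread falls below
  fatol = 1e-11 / xatol = 1e-7, with a 4,000-evaluation cap per stage.
* **Convergence criterion** — the optimizer terminated by tolerance
  *and* the central-difference gradient norm of the profiled deviance
  at the solution is ≤ 1e-2.  The original study does not state its
  criterion, so reported convergence rates are criterion-dependent;
  this one is documented and configurable (`FitOptions.grad_tol`).
* **Singularity criterion** — any relative-scale Cholesky diagonal
  (|l11|, |l22|, |sb|) ≤ 1e-4, i.e. the lme4 `isSingular` convention;
  |l22| ≤ tol covers both a vanishing slope variance and a student
  intercept-slope correlation at ±1, and the correlation is also
  checked directly against 1 − tol.  A degenerate fit with σ̂² ≈ 0 is
  flagged singular outright.  On a 40-dataset sample of the
  worst-singularity condition the flag agreed with lme4 40/40.
* **Degenerate inputs** — rank-deficient fixed-effect designs
  (single-arm data, constant aptitude), fewer than two classrooms per
  arm, fewer than two waves and non-centered time codes are refused
  with explicit errors; a failed fit inside the Monte Carlo engine is
  recorded as a failed replication, never aborts a condition.

## Probing statistics

Three probes operate on the fitted fixed effects and their covariance:
the omnibus test of γ̂111, simple slopes of time at chosen (aptitude,
treatment) values, and the slopes difference test.  The default
reference distribution is Normal ("unbounded df"); a `residual` policy
(df = N − p − 1, the single-level regression convention) is available
and differs negligibly at the smallest simulated size (600 occasions).

The slopes difference test's printed formula adds `+2·cov(γ̂101, γ̂111)`
inside the variance, whereas the delta-method variance of the same
contrast at aptitude −1 subtracts it.  Both modes are implemented
(`as_printed` is the default, to follow the source formula); in the
simulated designs the covariance is numerically negligible (aptitude is
centered in expectation), so the two modes give essentially identical
power.

## Monte Carlo engine

Power is the share of significant replications at α = 0.05 (two-sided).
The default denominator is *all* replications (non-converged or failed
replications count as non-significant); a converged-only power is
always reported alongside, since the "share of all replications" definition leaves the choice open — at convergence rates
≈ 0.999 the difference is negligible, but it is surfaced rather than
hidden.  Singular fits still yield a test: they count toward power and
toward the singularity rate independently.  Replication r of condition
c under master seed s draws from `SeedSequence(entropy=(s, c, r))`, so
serial and parallel sweeps are bitwise identical; grids checkpoint per
condition (full-precision CSV plus a config-digest metadata file, with
digest-mismatch refusal on resume).

## Meta-analysis

The ANOVA unit of analysis is the condition (648 rows for the default
grid); the six factors are categorical, the power model includes all
two-way interactions, and convergence/singularity models are
main-effects only.  η² = SS_term/SS_total with Type-II sums of squares
(identical to Type I/III on the complete balanced factorial; unbalanced
or incomplete tables are rejected, not silently handled).  Tukey HSD
post-hocs use the studentized-range distribution with the residual mean
square of the main-effects ANOVA, gated by convention at η² > 0.03 and
α = 0.05 (both configurable).

## Problem sizes used by the checks

The test suite re-runs the full 648-condition grid at 100 replications
per condition (≈ 90 s) and the two extreme cells at 1,000 replications;
the acceptance script uses 1,000 replications per stochastic target.
Type-I calibration uses 1,000 null replications of a large cell
(5 waves, 30 students, 50 classrooms), and the estimate-accuracy gate
6,000 replications of a mid-grid cell, sized so that Monte Carlo error
is well inside the 5% relative-bias bound for the smallest non-zero
coefficient (0.1).

## Known limitations and expected deviations

* Wald SEs from `(XᵀV̂⁻¹X)⁻¹` ignore variance-parameter uncertainty, and
  the Normal reference ignores small-sample df; with 20 classrooms the
  slopes difference test is therefore mildly liberal.  Re-running the
  lowest-power cell at high replication gives a stable power of ≈ 0.147
  against the reference value 0.128 — consistent with that mild
  liberality plus the fact that a *minimum over 648 noisy estimates*
  (each with MC sd ≈ 0.011 at 1,000 replications) is biased low.
  Small-sample corrections (Satterthwaite/Kenward-Roger) are out of
  scope.
* Convergence rates here are ≈ 1.0 (the reference mean is 0.999); with
  an exact structured likelihood and a derivative-free optimizer there
  is essentially nothing to fail, so the non-convergence phenomenology
  of general-purpose fitters is not reproduced.  Singularity, which is
  a property of the likelihood surface rather than of the optimizer, is
  reproduced closely.
* Only the balanced, two-arm, linear-growth design is supported; the
  fitter refuses anything else rather than approximating it.
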