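# Methods

## The model of activity

We treat a subject's movement record as an alternating renewal process:
*active events* (maximal runs of counts above a threshold) of duration
`a_i` separated by *inactive waiting times* `w_i` (runs at or below the
threshold).  The threshold is data-driven — the arithmetic mean of the
subject's non-zero worn counts — so it adapts to each subject's overall
activity level.  Counts exactly equal to the threshold are classified
inactive; this is a convention (the crossing definition does not dictate
it) and is configurable (`strict_above`).  Runs truncated by the start or
end of the recording, a non-wear gap, or a wake/sleep transition in
state-specific analyses are censored and excluded: a gap is unobserved
time, not inactivity, so concatenating across it would fabricate
durations.  Bouts spanning the wake/sleep boundary are likewise censored
in state-specific analyses — the source data do not dictate an
assignment, and censoring is the only choice that cannot bias either
state.

## Candidate duration distributions

Seven families are defined on the tail domain `x ≥ x_min` (all densities
individually normalized there):

| family | density ∝ | free parameters (k) |
|---|---|---|
| power law | `x^(−α)` | α (1) |
| exponential | `e^(−λx)` | λ (1) |
| log-normal | `exp(−(ln x − μ)²/2σ²)/x` | μ, σ (2) |
| Weibull (stretched exp.) | `x^(β−1) e^(−λx^β)` | β, λ (2) |
| truncated power law | `x^(−α) e^(−λx)` | α, λ (2) |
| biexponential | `δ·Exp(λ) + (1−δ)·Exp(γ)` | λ, γ, δ (3) |
| composite (exp + TPL) | `δ·Exp(γ) + (1−δ)·TPL(α, λ)` | α, λ, γ, δ (4) |

Mixture components are normalized separately so δ is the probability mass
of the first component and the total integrates to one automatically.
`x_min` is selected, not estimated by likelihood, and is shared by all
families of a subject's fit set, so it is not counted in k for BIC.

The truncated power-law normalizer is `λ^(1−α)/Γ(1−α, λ·x_min)` with an
upper incomplete gamma of (typically) negative first argument, which
scipy does not provide.  We evaluate `Γ(s, z)` for `s ≤ 0` by the upward
recurrence `Γ(s, z) = (Γ(s+1, z) − z^s e^(−z))/s` from a positive shift
when `z < 1`, and by a Lentz continued fraction when `z ≥ 1` (where the
recurrence cancels catastrophically); both agree with arbitrary-precision
references to better than 10⁻⁹ relative over the parameter ranges the
fits can visit.  The biexponential's components are exchangeable, so
fitted parameters are reported in the canonical order λ ≥ γ.

## Fitting protocol

`x_min` is chosen by the standard robust power-law procedure: candidate
values are the unique observed durations (capped so at least 50 tail
observations remain, thinned evenly to ≤ 500 candidates for very large
samples); at each candidate the exponent is the maximum-likelihood value
on the grid α = 1.10–5.00 (step 0.01), and the candidate minimizing the
Kolmogorov–Smirnov distance between the fitted power law and the tail
empirical CDF wins (ties → smaller `x_min`).  The remaining six families
are then fitted at that shared `x_min` by maximum likelihood: closed
forms where they exist (exponential `λ̂ = 1/(x̄ − x_min)`, power law
`α̂ = 1 + n/Σ ln(x_i/x_min)`), otherwise bounded L-BFGS-B on a partially
transformed scale (log rates in [10⁻⁸, 10²], α ∈ (1.01, 10], δ ∈ [0, 1]
raw — the boundary values are admissible mixture collapses, so a logit
transform would exclude them) from three deterministic data-driven starts
plus seeded jitter to five.  A fit is non-convergent if no start succeeds;
degenerate samples (all values equal) are attempted with the exponential
only.

**Discreteness.** Threshold extraction reports whole epochs, so 1-s data
are integers with a large atom at 1 s.  The naive continuous likelihood
degenerates there — for the composite it drives α to its bound by
spending the power-law component on the atom.  Fits of extracted
durations therefore use the exact likelihood of grid-valued data: the
probability of observing `d` is the integral of the continuous density
over `[d, d + epoch)`, evaluated by 12-point Gauss–Legendre quadrature
per occupied cell (vectorized over unique values).  This restores
unbiased parameter recovery on second-resolution data while keeping the
continuous families and the continuous `x_min`/grid scan.  Fits of
genuinely continuous samples (e.g. direct draws in simulation studies)
use the plain continuous likelihood.

Scoring: BIC = k·ln(n_tail) − 2·logL (the likelihood being whichever of
the two above matches the data's resolution — all families of a fit set
use the same one, so BICs are comparable), plus the KS distance of the
fitted CDF on the tail.

## Group-level selection

Per-family approximate log evidence is −BIC/2 (the standard Laplace-style
bridge; additive constants cancel in every renormalization below).
Random-effects model selection iterates the variational scheme

    u_nk ∝ exp(logev_nk + ψ(α_k) − ψ(Σ α)),   α_k = α₀ + Σ_n u_nk

with uniform Dirichlet prior α₀ = 1, to convergence (max |Δα| < 10⁻⁶,
≤ 10⁴ iterations).  Exceedance probabilities φ_k = P(frequency_k largest)
come from 10⁶ Monte Carlo draws of the posterior Dirichlet with a
recorded seed (exact Beta closed form when only two families are in
play).  Families missing for a subject (non-convergent fits) are handled
by row-wise renormalization over that subject's available families;
subjects with fewer than two converged fits are dropped.

Group-averaged parameters: within each subject, a family is *plausible*
if its evidence is at least 0.05 of the subject's best evidence (we read
the plausibility cut as a ratio of evidences — a log-evidence difference
of 0.05 would declare nearly everything plausible); evidences
renormalized over the plausible set give weights, and the group average
of a family's parameter is the weight-normalized mean over subjects where
that family is plausible, with an NA marker when it is plausible for
none.

Subgroup contrasts use a log Bayes factor: the evidence (−BIC/2) of
fitting the composite family to each group separately minus the evidence
of one pooled fit.  Positive values favor distinct distributions;
|LogBF| > 5 is reported as strong evidence.  The composite family is used
because it nests both contrasted regimes.

## Synthetic cohorts

The generator emulates what the analysis needs to be tested against, not
device physics.  Each subject alternates bouts drawn from an active and
an inactive duration model (defaults: composite exp + TPL with α = 1.73,
λ = 0.03, γ = 0.42, δ = 0.48; truncated power law with α = 1.64,
λ = 2×10⁻⁴ — the group-level regime the analysis is designed to detect),
with per-subject heterogeneity in α (uniform on [1.6, 1.9] active,
[1.5, 1.8] inactive).  A bout of continuous duration `u` covers
`floor(u)` complete 1-s epochs.  Days repeat in 24-h blocks with a
contiguous sleep window at the end of each block
(`wake_fraction` of the day awake); sleep bouts use a separate model pair
whose active default is a plain exponential, matching the absence of
heavy-tailed movement in sleep.

Pure families are sampled by inverse CDF; mixtures by component
indicator; the truncated power law by rejection — from a pure power-law
proposal with acceptance `exp(−λ(x − x_min))` when α > 1 (acceptance ≈
`(α−1) x_min^(α−1) λ^(α−1) e^(λ x_min) Γ(1−α, λ x_min)`, near 1 for the
small λ of interest), and from a shifted-exponential proposal with
acceptance `(x/x_min)^(−α)` for 0 < α ≤ 1.  The sampler aborts after a
bounded proposal budget rather than looping forever on pathological
parameters.

Amplitudes come in two modes.  **Strict** mode puts active seconds at
2× and inactive seconds strictly below a target threshold, so extraction
at that threshold returns the generating durations exactly (boundary
bouts excepted) — the round-trip contract the extraction tests rely on.
**Graded** mode is for threshold-sweep studies: each active bout gets a
log-normal intensity level with median 2× the target threshold
(σ = 0.5), multiplied by small per-second log-normal jitter (σ = 0.15)
and damped "shoulder" seconds at the bout edges; inactive seconds are
zeros (p = 0.55) or low sub-threshold uniform marks.  Intensity is
assigned per bout rather than i.i.d. per second deliberately: real
activity intensity is coherent within a bout, and bout-level assignment
makes a threshold sweep reclassify whole marginal events instead of
shredding every long bout into per-second fragments (which would destroy
the duration distributions the sweep is supposed to perturb only mildly).
What graded mode does **not** emulate: correlation between bout duration
and intensity, device noise, and non-wear artifacts beyond inserted zero
runs — so passing sweeps bound the pipeline's sensitivity to the cut, not
the full variability of field recordings.

## Study conditions and problem sizes

The simulation studies in `actibout.studies` (used by the acceptance
tests and `scripts/acceptance.py`) fix these conditions:

* **Threshold robustness** — 20 graded-mode subjects, 200,000 s each,
  factors {0.5, 0.75, 1.0, 1.25, 1.5}; winning family refit per factor at
  `x_min` = 1 s; reported as the cohort mean of each subject's mean
  absolute proportional change of α versus the factor-1.0 fit.
* **Sleep-regime recovery** — 30 subjects × 2,000 exponential durations,
  rates uniform on [0.1, 0.5]; all seven families fitted at `x_min` = 1;
  exceedance of the exponential family reported.
* **Parameter recovery** — each family fitted to six independent samples
  of 10⁴ of its own draws; the replicate-averaged estimate must sit
  within 10% relative (δ: 0.1 absolute) of truth.  Truth points were
  chosen a priori from the Fisher-information bound so every parameter's
  sampling sd at this n is a few percent; the exponential-cutoff rate λ
  of a deep power-law tail (e.g. λ = 2×10⁻⁴ at α = 1.64) has CRLB
  relative sd above 10% at n = 10⁴ for *any* estimator, so a single-draw
  check there would measure identifiability, not correctness.  Averaging
  replicates tests the estimator's bias instead of one draw's noise.
* **Model recovery** — two 20-subject cohorts of 10⁴ durations each from
  the composite-active and TPL-inactive truths.  10⁴ per subject matches
  the ~10⁴–10⁵ events of a week of 1-s data; at 5×10³ the log-normal (2
  parameters) mimics the composite closely enough that the BIC penalty
  gap 2·ln n makes individual selection genuinely marginal — an
  instructive boundary of the method, documented rather than hidden.
* **Subgroup contrast** — 10 replicates of 5,000 power-law (α = 3.19)
  vs 5,000 composite (α = 1.85, λ = 0.01, γ = 0.55, δ = 0.47) durations.

## Numerical choices and limitations

* Normalization integrals are exact to < 10⁻⁶; CDFs use closed forms
  (incomplete gamma for TPL) rather than quadrature.
* BIC ties break toward fewer parameters, then family name; KS ties in
  the `x_min` scan toward smaller `x_min`.
* Re-epoching drops a trailing partial window (a short final window
  would bias its count sum low); windows containing any non-wear second
  are non-wear.
* Diary timestamps are rounded to whole seconds; intervals are half-open
  `[start, end)`.  Days without diary entries are excluded from
  state-specific analyses (masked as unworn by default).
* The wake:sleep sufficiency rule (worn ratio > 3 → wake-only analyses)
  uses strict inequality.
* The exceedance Monte Carlo error is ~3/√10⁶ ≈ 0.003; reported φ values
  are not meaningful beyond that resolution.
* The variational BMS assumes the −BIC/2 evidence approximation, which
  ignores prior-volume differences between families beyond the BIC
  penalty; with n_tail in the thousands this is the dominant term, but
  for small tails the approximation is rough.
* Protected exceedance probabilities, bootstrap goodness-of-fit p-values
  for the power law, and non-nested likelihood-ratio tests are out of
  scope.
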