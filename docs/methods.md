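# Methods

`seqmetabias` quantifies two biases that arise in accumulating
(cumulative/sequential) meta-analysis when earlier results steer later
research: **sequential decision bias**, from letting the probability of
conducting the next trial depend on the current pooled estimate, and
**sequential design bias**, from plugging the current estimate into the
next trial's sample-size calculation in place of a fixed clinically
relevant effect.

## Generating model

Each trial reports a mean-difference estimate θ̂ᵢ, an effective sample size
nᵢ = (1/N_iT + 1/N_iC)⁻¹ (so Var θ̂ᵢ = σᵢ²/nᵢ for a common within-arm
variance; N/4 for a balanced trial of total size N), and a pooled sample
variance sᵢ² with dᵢ degrees of freedom.  The generating model is

* θ̂₁ ~ N(θ, σ²/n₁ + τ²), with τ² ≥ 0 the between-study heterogeneity
  variance of a random-effects model (τ² = 0 gives the fixed-effect model);
* d₁s₁²/σ² ~ χ²(d₁), independent of θ̂₁ (exact for normal outcomes).

`TrueState` carries (θ, σ², τ², n₁, d₁).  Scenarios that fix the *total*
variance of the estimate directly — e.g. a per-estimate variance of 1/3 —
are expressed with n₁ = 1, which is arithmetically identical.

Fixed-effect pooling uses inverse-variance weights: `combine_fixed` weights
observed summaries by wⱼ = nⱼ/sⱼ², while the simulator pools with the
known-variance weights wⱼ = nⱼ/σ² (or equal weights), matching the
analytic theory's assumption that weights are independent of the effect
estimates.  Random-effects behaviour enters only through τ² in the
generating law, never through τ²-adjusted weights.

## Decision models

The probability p(θ̂₁) of conducting the next trial takes one of four forms
(`DecisionModel`):

* **power law** — p = (θ̂/θ₀)ᵗ on (0, θ₀), 0 elsewhere.  t > 0 governs how
  sharply "promising" results encourage a new trial; no trial is needed
  once the clinically relevant effect θ₀ is reached.
* **extreme value / probit** — Copas-style selection functions
  p = [1 − G(θ̂)]/[1 − G(rθ₀)] for θ̂ > rθ₀ and 0 otherwise, with
  G = exp(−exp((θ₀ − θ̂)/σ)) or G = Φ(α + β(θ̂ − θ₀)/σ).  The truncation
  fraction r ∈ (0, 1) makes a new trial certain just above rθ₀ and
  increasingly unlikely as the estimate approaches or exceeds θ₀.
* **power-calculation window** — deterministic given the data: run a new
  trial iff its required size n₂ = c²s₁²/θ̂₁² − n₁ lies in (a, b], where
  c = z₁₋α/₂ + z₁₋β (c ≈ 2.802, c² ≈ 7.85 at the conventional α = 0.05,
  β = 0.2).  Ties at a stop, ties at b continue.  Setting `a = None` drops
  the lower restriction entirely, so the rule is n₂ ≤ b; this is the
  reading under which the worked example's "unrestricted" continuation
  probability (≈ 0.41) is reproduced, whereas the literal 0 < n₂ ≤ b gives
  ≈ 0.397.

For the window rule the conditional continuation probability follows from
the chi-square law of s₁²:

P(a < n₂ ≤ b | θ̂₁ = θ₁) = F_χ²(d₁(b + n₁)θ₁²/(c²σ²)) −
F_χ²(d₁(a + n₁)θ₁²/(c²σ²)),

with the lower CDF argument 0 when no lower restriction applies.  The
unconditional probability integrates this against the normal law of θ̂₁.

## Decision bias

Let ω₁ be the normalised first-stage weight and Y the continue indicator.
With an unbiased first stage,

* E[θ̂₍₂₎] − θ = (ω₁ − 1)·Cov(p, θ̂₁)
* E[θ̂₍₂₎ | Y = 1] − θ = ω₁·Cov(p, θ̂₁)/E[p]  (+ ω₁(Eθ̂₁ − θ), carried so
  the expression composes)
* E[θ̂₍₂₎ | Y = 0] − θ = −Cov(p, θ̂₁)/(1 − E[p])

A positive covariance — promising estimates encourage the next trial —
biases the pooled estimate downward unconditionally, upward on the
continue branch and downward on the stop branch.  For K sequential
decisions the conditional bias obeys the recurrence
bias_{i+1} = ω̄ᵢ(biasᵢ + Covᵢ/E[pᵢ]) with ω̄ᵢ the relative weight of the
first i studies in the (i+1)-study pool (`recurrent_bias`).

All expectations are one-dimensional adaptive quadratures (`scipy`
`quad`) over θ ± 10 standard deviations — the omitted normal tail mass is
below 1e−22 — with absolute/relative tolerance 1e−10 and the decision
function's kinks (0, θ₀ or rθ₀) passed as breakpoints.  For the window
model, p(θ₁) is the chi-square expression above, so the sample variance is
already integrated out; by the tower property the covariance equals that
of the raw indicator.

## Design bias

When the next trial is sized from the estimated effect θ̂₁ + δ (δ a fixed
"correction") with variance guess σ_g² = d²σ₂²,
n₂ = max((c²/(θ̂₁+δ)² − w₁)σ_g², 0) and w₂ = n₂/σ₂².  The pooled
estimator (w₁θ̂₁ + w₂θ̂₂)/(w₁ + w₂) collapses to θ̂₁ when n₂ ≤ 0.  Its
expectation (`unconditional_design_expectation`) is computed by quadrature
for a fixed guess and by Monte Carlo when σ_g² = s₁².

Stopping (n₂ ≤ 0) is the event |θ̂₁ + δ| ≥ c/√w₁ — both tails are kept
even though the lower one is usually negligible — and the stopped-branch
mean E[θ̂₁ | n₂ ≤ 0] has the closed two-sided truncated-normal form
(`stopped_expectation`).  It overshoots θ badly for small trials (0.647
versus θ = 0.2 at n₁ = 15 in the reference scenario) and converges to θ
as n₁ grows.

At d = 1 the bias is bounded above by φ(h)·σ₁/√n₁ + 2(θ + δ)/c² with
h = (c/√w₁ − δ − θ)/(σ₁/√n₁): the first term bounds the stopped branch
(a truncated-normal moment), the second the continuation branch via a
Stein-identity argument using that the estimator's effective shrinkage
weight w₁(θ̂₁+δ)²/c² is capped at 1 on the continuation region.  Relative
to the sizing target θ + δ the second term is 2/c² ≈ 25% at the
conventional α and β.  The published rendering of this bound is ambiguous;
this derivation reproduces both the 25% remark and the dominance over the
simulated d = 1 bias, which is how it is validated.

Percent bias is 100·(E[θ̂] − θ)/θ throughout.

## Monte-Carlo engine

`simulate_decision` draws study 1, applies the decision (a Bernoulli draw
with probability p(θ̂₁) for the selection models — p is a probability, not
a hard threshold — or the deterministic window check), draws study 2 for
the continuing replicates and pools.  Replicates that stop keep their
estimate frozen; branch means over an empty branch are reported as NaN,
never zero.  Sequences of up to `steps` decisions are supported for the
pointwise selection models (each decision applied to the running
cumulative estimate); the window rule is restricted to a single decision,
since multi-trial window scenarios in the source example depend on
unpublished study-level estimates.  A single seeded generator drives each
run; grid sweeps (`grid_sweep`, `simulate_design` with a d-grid) give
every grid point its own `SeedSequence`-spawned substream, so any point is
reproducible in isolation and bit-identical under reruns.

The window model's second trial defaults to the fixed size b
(`next_trial_size_policy="fixed_b"`), the reading of the rule under which
the worked example's simulated bias triple is reproduced; sizing by the
computed n₂ is available as `computed_n2`.

### Variance reduction

Some published quantities are stated with a precision that a plain
10,000-replicate estimate cannot deliver (the branch-conditional percent
biases have MC standard errors of 1.3–2.4 points; the design-bias mean,
≈ 1.8 points).  Both simulators therefore offer `variance_reduction=True`,
which estimates the *same* expectations by

* stratified (inverse-CDF) or antithetic first-stage draws,
* conditional Monte Carlo: the decision indicator is replaced by its
  conditional probability given θ̂₁, and the second trial by its
  conditional mean θ,
* regression control variates on θ̂₁ and s₁², whose means are known.

This brings the standard errors to ≲ 0.3 points at the same replicate
count.  The plain paths remain the defaults and the cross-checks: tests
verify that reduced and plain estimates agree within joint Monte-Carlo
error.  Reported standard errors for the stratified path use the iid
formula and are conservative.

## What the generator does and does not emulate

The synthetic draws reproduce exactly the stochastic structure assumed by
the theory: normal effect estimates with variance σ²/n + τ², independent
scaled-chi-square sample variances, and independence across trials.  Real
meta-analytic data depart from this in ways the package deliberately does
not model: non-normal outcomes (binary endpoints, ratio measures),
correlation between effect estimates and their variance estimates,
weights estimated from the same data that is being pooled, multiplicity
adjustment of α across sequential looks, and publication bias acting on
*past* studies rather than the decision about the next one.  Passing tests
therefore demonstrate the internal consistency of the bias theory and its
implementation, not the magnitude of these biases in any particular
literature.

## Worked-example conventions

The dentifrice fixture ships the first three trials' effective sizes
(61.30, 81.06, 69.24) and pooled variances (19.94, 24.96, 8.56), the
first-trial estimate 0.86, and the nine-trial pooled values θ = 0.28 and
σ² = 21.62 used as the assumed truth (the nine individual effects are not
part of the fixture).  The first-trial variance d.f. defaults to
round(n_eff) − 1 = 60, matching the published simulation's use of the
effective size; the per-arm convention d = N − 2 = 243 is exposed and
shifts the windowed continuation probability by only ~0.001.

In the design-bias sweep of the example (δ = −0.36, "correcting" 0.86 to
0.50), the d ≈ 1 bias under the stated truth θ = 0.28 is *negative*
(≈ −7%, matching the closed-form d = 1 moment 2(θ+δ)/c² of the model),
while the prose magnitude of about +15% corresponds to treating the
observed first-trial effect 0.86 as the truth (θ + δ = 0.50, giving
2·0.50/7.85 ≈ 14.8% of 0.86 — ≈ 15%).  `run_design_report` defaults to
θ = 0.28 and takes θ as a parameter so both readings are available; the
test suite pins down both.

## Problem sizes and tolerances

Quadrature results are accurate to ~1e−8 and checked against Monte Carlo
at 3 standard errors.  Simulation-based tests use 10,000 replicates where
a published quantity specifies that size, and 50,000–400,000 replicates
(seconds of runtime) where they serve as oracles for quadrature; one-off
oracle comparisons use 10⁶–2×10⁶ draws.  The d-sweep default grid is
d = 0.1(0.1)10.  All randomness flows from explicit integer seeds.

## Known limitations

* Random-effects *estimation* (DerSimonian–Laird and relatives) is out of
  scope; τ² is a generating parameter only.
* The window rule's multi-decision recurrence (cumulative weights Wᵢ in
  the sizing formula) is provided for probabilities via
  `sample_size_fixed_target` with a prior weight, but the simulator runs
  single-decision window scenarios only.
* No multiplicity adjustment of α across sequential decisions, and no
  bias-correction procedures — the package measures the biases, it does
  not remove them.
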