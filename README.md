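# seqmetabias

Sequential decision bias and sequential design bias in accumulating
(cumulative/sequential) meta-analysis.

When a meta-analyst uses the current pooled estimate to decide **whether**
to run the next trial, or to compute **how large** it should be, the
updated meta-analytic estimate is biased even though every individual
trial is unbiased.  `seqmetabias` implements the analytic theory of both
effects, the decision-probability models, power-based sample-size rules, a
seeded Monte-Carlo engine, and a packaged worked example (the Johnson
fluoride-dentifrice meta-analysis), for biostatisticians and evidence-synthesis
methodologists who want to quantify these biases in their own scenarios.

## The model in brief

Study effects are mean differences with effective sample size
n = (1/N_T + 1/N_C)⁻¹, pooled by fixed-effect inverse-variance weights
w_i = n_i/σ_i².  The first estimate is θ̂₁ ~ N(θ, σ²/n₁ + τ²) with sample
variance d₁s₁²/σ² ~ χ²(d₁).  If the next trial is run with probability
p(θ̂₁), the pooled two-trial estimate θ̂₍₂₎ = ω₁θ̂₁ + ω₂θ̂₂ satisfies

- E[θ̂₍₂₎] − θ = (ω₁ − 1)·Cov(p, θ̂₁)                (unconditional)
- E[θ̂₍₂₎ | run] − θ = ω₁·Cov(p, θ̂₁)/E[p]            (continue branch)
- E[θ̂₍₂₎ | not run] − θ = −Cov(p, θ̂₁)/(1 − E[p])    (stop branch)

so any correlation between the estimate and the decision biases all three
expectations (*sequential decision bias*).  Supported decision models: a
power law (θ̂/θ₀)ᵗ, Copas-style extreme-value and probit selection
functions, and a power-calculation rule that runs the next trial when its
required size n₂ = c²s₁²/θ̂₁² − n₁, with c = z₁₋α/₂ + z₁₋β, falls in a
window (a, b].  If instead the next trial's size is computed from the
*estimated* effect θ̂₁ + δ rather than a fixed clinically relevant θ₀, the
pooled estimate acquires *sequential design bias*, reaching tens of
percent in realistic scenarios.  See `docs/methods.md` for the full
account.

## Worked example

```python
from seqmetabias import JohnsonFixture, run_decision_report

report = run_decision_report(JohnsonFixture.load(), reps=10_000, seed=0)
print(report.to_string(index=False))
```

```
                     quantity      value                                        note
                  required_n2 150.309873 effective size of a definitive second trial
        p_continue_quadrature   0.345530                    P(50 < n2 <= 500), df=60
p_continue_quadrature_df_arms   0.346811          same, per-arm df=243 (sensitivity)
    p_continue_no_lower_bound   0.410016           P(n2 <= 500), lower bound dropped
         p_continue_simulated   0.349600                10000 simulated first trials
   percent_bias_unconditional -22.702655                   simulated, all replicates
        percent_bias_continue   8.716059           simulated, second trial conducted
            percent_bias_stop -39.590697       simulated, second trial not conducted
```

Reading: after the first dentifrice trial (estimate 0.86, variance 19.94,
effective size 61.30), a second trial powered at the *estimated* effect
would need ~150 effective patients, inside the feasible window (50, 500] —
so the decision to continue depends on the data.  Under the assumed truth
(θ = 0.28, σ² = 21.62) that window fires with probability ≈ 0.35, and the
pooled estimate is biased by about −20% unconditionally, +9% when the
second trial goes ahead and −40% when it does not, at this seed and
replicate count.  The scripts in `examples/` walk through each capability
(analytic decomposition, window probabilities, design-bias sweep, the full
worked example) and print annotated numbers.

A thin CLI mirrors the library: `seqmetabias prob`, `bias-analytic`,
`simulate-decision`, `sweep`, `design-bias`, `johnson` — each writes a
delimited table; see `seqmetabias --help`.

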