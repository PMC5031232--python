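"""Sequential decision bias, analytically.

A first trial estimates an effect of interest; the probability of running a
second trial follows a power law in the estimate, p = (theta_hat/theta0)^3
below the clinically relevant target theta0 and 0 above it.  The script
evaluates the exact (quadrature) bias decomposition of the pooled two-trial
estimate for a true effect well below the target.
"""

from seqmetabias import DecisionModel, TrueState, bias_decomposition

# total variance of the first estimate is 1/3 (n1 = 1 expresses that directly)
state = TrueState(theta=0.3, sigma2=1.0 / 3.0)
model = DecisionModel.power_law(theta0=0.5, t=3.0)

dec = bias_decomposition(state, model, omega1=0.5)  # equal pooling weights

print(f"true effect                  {state.theta:.3f}")
print(f"P(second trial)              {dec.p_continue:.4f}")
print(f"Cov(p, theta_hat1)           {dec.cov_p_theta:+.5f}")
print(f"unconditional bias           {dec.unconditional:+.5f}")
print(f"bias | second trial run      {dec.conditional_continue:+.5f}")
print(f"bias | second trial not run  {dec.conditional_stop:+.5f}")
print()
print("The covariance is positive (promising estimates encourage the next")
print("trial), so the pooled estimate is biased downward unconditionally,")
print("upward when the trial goes ahead, and downward when it does not --")
print("even though each trial is individually unbiased.")
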