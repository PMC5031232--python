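"""The power-calculation window rule.

A second trial is run when its power-based required size
n2 = c^2 s1^2 / theta_hat1^2 - n1 falls in a window (a, b].  The script
computes the required size at an observed estimate, then the conditional
(given theta_hat1) and unconditional probabilities that the rule fires,
integrating the sample variance out through its chi-square law.
"""

from seqmetabias import (
    DecisionModel,
    TrueState,
    continuation_prob_conditional,
    continuation_prob_unconditional,
    power_constant,
    sample_size_estimated_target,
)

c = power_constant(alpha=0.05, beta=0.2)
print(f"power constant c = {c.c:.3f} (c^2 = {c.c2:.2f})")

# first trial: estimate 0.86, sample variance 19.94, effective size 61.30
n2 = sample_size_estimated_target(0.86, 19.94, 61.30, 0.0, c)
print(f"required second-trial size at theta_hat1 = 0.86: n2 = {n2:.2f}")

state = TrueState(theta=0.28, sigma2=21.62, n1=61, df=60)
model = DecisionModel.power_window(a=50.0, b=500.0)

print("\nconditional continuation probability P(50 < n2 <= 500 | theta_hat1):")
for theta1 in (0.3, 0.6, 0.9, 1.2):
    p = continuation_prob_conditional(theta1, state, model)
    print(f"  theta_hat1 = {theta1:.1f}  ->  {p:.4f}")

p_win = continuation_prob_unconditional(state, model)
p_free = continuation_prob_unconditional(state, model.without_lower_bound())
print(f"\nunconditional, window (50, 500]: {p_win:.3f}")
print(f"unconditional, no lower bound:   {p_free:.3f}")
print("\nSmall estimates demand unaffordably large trials and large estimates")
print("need none, so the rule fires for a middling range of estimates only.")
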