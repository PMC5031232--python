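"""Sequential design bias against the variance-guess ratio d.

The second trial is sized from the *estimated* effect theta_hat1 + delta
with a guessed variance sigma_g^2 = d^2 sigma_2^2.  The script sweeps d,
adds the sample-variance-guess run (sigma_g^2 = s1^2) and the unbiased
control sized from the true effect, and prints the closed-form upper bound
at d = 1.
"""

import dataclasses

import numpy as np

from seqmetabias import (
    DesignScenario,
    TrueState,
    design_bias_upper_bound,
    power_constant,
    simulate_design,
)

state = TrueState(theta=0.2, sigma2=19.94, n1=61, df=60)
scenario = DesignScenario(
    true=state, sigma2_second=24.96, delta=0.2, reps=10_000, seed=0
)

table = simulate_design(scenario, d_grid=np.arange(0.5, 5.01, 0.5),
                        variance_reduction=True)
print("percent bias of the pooled estimate by variance-guess ratio d:")
for _, row in table.iterrows():
    print(f"  d = {row['d']:4.1f}   {row['percent_bias']:6.1f} %")

s1_run = simulate_design(
    dataclasses.replace(scenario, use_s1_sq=True), variance_reduction=True
)
print(f"\nsigma_g^2 = s1^2 (sample variance): {s1_run['percent_bias'].iloc[0]:.1f} %")

control = dataclasses.replace(
    scenario, sigma2_guess=24.96, size_from="truth", delta=0.0
)
ctrl = simulate_design(control, variance_reduction=True)
print(f"control (sized from the true effect): {ctrl['percent_bias'].iloc[0]:.2f} %")

bound = design_bias_upper_bound(state, 0.2, power_constant(0.05, 0.2))
print(f"\nclosed-form upper bound at d = 1: {100 * bound / state.theta:.1f} %")
print("\nSizing from the estimated effect inflates the pooled estimate by")
print("tens of percent; sizing from a fixed clinically chosen effect does not.")
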