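"""Stepwise evaluation of a DoE response.

Fits the screening model with the enter/exit stepwise procedure
(p_enter = 0.05, p_exit = 0.10) and compares the residual noise of the
selected model to the set-point noise that the a priori power analysis
relied on.
"""

from dsdpower import (
    cc1_like_scenario,
    residual_sd_ratio,
    simulate_study,
    stepwise_select,
)

scenario = cc1_like_scenario()  # DoE noise inflated ~8x above set-point noise
response, setpoint = simulate_study(scenario, seed=1)

model = stepwise_select(scenario.design, response)

print("selected terms:")
if not model.terms:
    print("  (none - intercept-only model)")
for term, coef, p in zip(model.terms, model.coefs, model.pvalues):
    print(f"  {term.name:<28s} coef={coef:+.4f}  p={p:.4f}")
print(f"intercept = {model.intercept:.4f}")
print(f"sigma_residuals = {model.sigma_residuals:.4f} (raw, denominator n-1)")
print(f"sigma_residuals / sigma_SP = {residual_sd_ratio(model, setpoint):.2f}")
print("selection trace:", " | ".join(model.trace) or "(no moves)")

# A residual/set-point sigma ratio well above 1 is the warning sign: the
# experiment was much noisier than the pre-experiment estimate, so the
# a priori power statement no longer describes this data set.
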