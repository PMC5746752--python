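"""Pre-experiment power of a definitive screening design.

Builds a 5-factor DSD, derives the critical gap between the set-point
performance and the intermediate-stage threshold, and asks: if effects of
critical size were present — split among the parameters in every proportion
— what is the chance the overall-model F test would see them?
"""

from dsdpower import (
    apriori_power,
    cc1_like_scenario,
    critical_gap_setpoint,
    simulate_study,
)

scenario = cc1_like_scenario()
response, setpoint = simulate_study(scenario, seed=1)

cg = critical_gap_setpoint(scenario.threshold, setpoint.mean)
result = apriori_power(scenario.design, cg, setpoint.sd, step_count=100)

print(f"design: {scenario.design.n_runs} runs x {scenario.design.n_factors} factors")
print(f"threshold = {scenario.threshold}, set-point mean = {setpoint.mean:.3f}")
print(f"critical gap (set point) = {cg.value:.3f} CQA units")
print(f"sigma_SP = {setpoint.sd:.4f}")
print(f"a priori mean power = {result.mean_power:.4f}")
print(f"worst combination  = {result.per_combination.min():.4f}")

# A mean power of 1 means: under the promised set-point noise, no split of
# the critical gap among the five parameters could have slipped past the
# experiment. Whether that promise held is what the retrospective test asks.
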