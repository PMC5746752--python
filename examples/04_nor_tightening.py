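"""Raising retrospective power by tightening a normal operating range.

When power is short and more experiments are not an option, narrowing a
parameter's NOR means a steeper slope is needed to consume the critical gap
— a larger critical effect, which the experiment has more power to detect.
"""

from dsdpower import (
    RetroPowerConfig,
    cc1_like_scenario,
    fit_terms,
    nor_scan,
    simulate_study,
)

scenario = cc1_like_scenario()
response, _sp = simulate_study(scenario, seed=1)
# the fitted model here happens to select nothing: all five factors are
# assessed for overlooked critical effects
model = fit_terms(scenario.design, response, [])

config = RetroPowerConfig(n_iterations=1000, step_count=100, seed=7)
scan = nor_scan(
    scenario.design,
    response,
    model,
    scenario.cqa_spec(),
    config,
    target_factor="wash_strength",
    shrink_fractions=[0.0, 0.25, 0.5],
)

print(f"{'shrink':>8s} {'CG':>8s}  per-parameter power")
for frac, res in scan:
    powers = "  ".join(
        f"{n}={p:.3f}" for n, p in res.per_parameter_power.items()
    )
    print(f"{frac:8.2f} {res.cg_used.value:8.3f}  {powers}")

# Halving the wash-strength NOR doubles its critical effect, roughly
# doubling its power, while the other parameters' powers are untouched:
# the tightened range buys assurance only for the parameter it constrains
# (tightening a parameter that IS in the model would instead enlarge the
# critical gap and lift every power).
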