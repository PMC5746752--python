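"""The complete criticality-assessment workflow on one CQA.

a priori power -> stepwise fit -> retrospective power -> one call per
process parameter: critical (significant), non-critical (powered), or
potentially overlooked (with the mitigation options to consider).
"""

from dsdpower import (
    RetroPowerConfig,
    assess_cqa,
    cc1_like_scenario,
    simulate_study,
)

scenario = cc1_like_scenario()
response, setpoint = simulate_study(scenario, seed=1)

report = assess_cqa(
    scenario.design,
    response,
    setpoint,
    scenario.cqa_spec(),
    power_cutoff=0.8,
    retro_config=RetroPowerConfig(n_iterations=1000, step_count=100, seed=7),
)

print(f"CQA: {report['cqa']}  threshold={report['threshold']}")
print(f"a priori mean power: {report['apriori']['mean_power']:.3f}")
print(f"sigma_residuals/sigma_SP: {report['sigma_ratio']:.2f}")
print(f"selected terms: {[t['term'] for t in report['model']['terms']] or 'none'}")
print("calls:")
for call in report["calls"]:
    extra = ""
    if call["p_value"] is not None:
        extra = f"p={call['p_value']:.3f}"
    if call["power"] is not None:
        extra = f"power={call['power']:.3f}"
    print(f"  {call['parameter']:<24s} {call['status']:<24s} {extra}")

# "potentially_overlooked" does not say an effect exists - it says this
# experiment could not have ruled one out. The report lists the options:
# re-measure, re-run, or tighten the NOR and re-assess; absent all three,
# treat the parameter as critical and monitor it in qualification runs.
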