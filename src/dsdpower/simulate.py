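"""Synthetic DoE studies with known ground truth.

Responses are generated from the same linear model the analysis assumes,
``y = b0 + X beta_true + eps``, with independent set-point replicates
``N(b0, sigma_sp^2)``.  The axis that distinguishes the two bundled
scenario presets is the ratio ``sigma_resid / sigma_sp``: a
process-characterization campaign whose DoE runs turn out far noisier than
the set-point replicates promised (ratio >> 1, the "inflated-noise"
chromatography-like case) versus one where the pre-experiment noise estimate
held (ratio ~= 1, the precipitation-like case).  Residuals are Gaussian by
default; a scaled Student-t (df=3) mode exercises the permutation test's
freedom from normality assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .apriori import apriori_power, expected_ss_res
from .design import (
    DesignMatrix,
    FactorSpec,
    ResponseVector,
    SetPointSample,
    generate_dsd,
)
from .retro import RetroPowerConfig, retrospective_power
from .stepwise import stepwise_select, term_from_name
from .thresholds import CQASpec, critical_gap_setpoint

__all__ = [
    "SimulationScenario",
    "simulate_study",
    "cc1_like_scenario",
    "pr_like_scenario",
    "recovery_suite",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to regenerate one synthetic DoE study.

    ``true_beta`` maps term names (``"x1"``, ``"x1^2"``, ``"x1:x2"``) to
    ground-truth coefficients; absent terms are zero.
    """

    design: DesignMatrix
    sigma_resid: float
    sigma_sp: float
    true_beta: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    n_sp_replicates: int = 6
    threshold: float | None = None
    cqa_name: str = "cqa"
    residual_family: str = "gaussian"

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_beta", dict(self.true_beta))
        if self.sigma_resid < 0 or self.sigma_sp <= 0:
            raise ValueError("sigma_resid must be >= 0 and sigma_sp > 0")
        if self.n_sp_replicates < 2:
            raise ValueError("need >= 2 set-point replicates")
        if self.residual_family not in ("gaussian", "t3"):
            raise ValueError(f"unknown residual_family {self.residual_family!r}")

    @property
    def noiseless_response(self) -> np.ndarray:
        y = np.full(self.design.n_runs, float(self.intercept))
        for name, coef in self.true_beta.items():
            y += coef * term_from_name(name).build_column(self.design)
        return y

    @property
    def setpoint_mean(self) -> float:
        """True response at the set-point condition of every factor."""
        sp = {f.name: f.set_point for f in self.design.factors}
        val = float(self.intercept)
        for name, coef in self.true_beta.items():
            term = term_from_name(name)
            contrib = 1.0
            for fname in term.factors:
                contrib *= sp[fname]
            if term.kind == "quadratic":
                contrib = sp[term.factors[0]] ** 2
            val += coef * contrib
        return val

    def cqa_spec(self) -> CQASpec:
        if self.threshold is None:
            raise ValueError("scenario has no threshold")
        return CQASpec(self.cqa_name, threshold_direct=self.threshold)


def _doe_noise(
    scenario: SimulationScenario, rng: np.random.Generator
) -> np.ndarray:
    n = scenario.design.n_runs
    if scenario.residual_family == "gaussian":
        return rng.normal(0.0, scenario.sigma_resid, size=n)
    # t(3) rescaled to sd sigma_resid (var of t_3 is 3)
    return rng.standard_t(3, size=n) * (scenario.sigma_resid / np.sqrt(3.0))


def simulate_study(
    scenario: SimulationScenario, seed: int | np.random.Generator = 0
) -> tuple[ResponseVector, SetPointSample]:
    """Draw one DoE response vector and one set-point replicate sample."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y = scenario.noiseless_response + _doe_noise(scenario, rng)
    sp = rng.normal(
        scenario.setpoint_mean, scenario.sigma_sp, size=scenario.n_sp_replicates
    )
    return ResponseVector(scenario.cqa_name, y), SetPointSample(sp)


# --------------------------------------------------------------------------
# presets emulating the two case-study regimes
# --------------------------------------------------------------------------

_CC1_FACTORS = (
    FactorSpec("end_pooling", set_point=-0.55, nor_low=-1.1, nor_high=0.0),
    FactorSpec("elution_strength", set_point=-0.225, nor_low=-1.1, nor_high=0.65),
    FactorSpec("wash_strength", set_point=0.0, nor_low=-1.1, nor_high=1.1),
    FactorSpec("column_loading_density", set_point=0.295, nor_low=-0.51, nor_high=1.1),
    FactorSpec("ph", set_point=0.0, nor_low=-0.55, nor_high=0.55),
)

_PR_FACTORS = (
    FactorSpec("temperature", set_point=-0.65, nor_low=-1.71, nor_high=0.41),
    FactorSpec("time", set_point=0.37, nor_low=0.33, nor_high=0.41),
    FactorSpec("mixing", set_point=0.0, nor_low=-0.95, nor_high=0.95),
    FactorSpec("ph", set_point=0.0, nor_low=-0.61, nor_high=0.61),
)


def cc1_like_scenario(
    sigma_ratio: float = 7.79,
    sigma_sp: float = 0.05,
    true_beta: Mapping[str, float] | None = None,
) -> SimulationScenario:
    """Five-factor chromatography-like study whose DoE noise inflates well
    beyond the set-point estimate (default ratio 7.79).

    13 runs: the five-factor definitive screening design (six-factor
    fold-over with one column dropped).  The impurity-clearance response
    sits at 0.4 at set point against an intermediate threshold of 1.0, a
    critical gap of 0.6 in CQA units.
    """
    design = generate_dsd(5, factors=_CC1_FACTORS)
    return SimulationScenario(
        design=design,
        true_beta=true_beta or {},
        intercept=0.4,
        sigma_resid=sigma_ratio * sigma_sp,
        sigma_sp=sigma_sp,
        n_sp_replicates=6,
        threshold=1.0,
        cqa_name="impurity_clearance",
    )


def pr_like_scenario(
    sigma_ratio: float = 1.0,
    sigma_sp: float = 0.01,
    true_beta: Mapping[str, float] | None = None,
) -> SimulationScenario:
    """Four-factor precipitation-like study whose realized DoE noise matches
    the set-point estimate (default ratio 1.0) and whose critical gap dwarfs
    the run-to-run noise (CG / sigma_resid = 60), the regime in which the
    experiment retains essentially full power to flag critical effects.
    11 runs: a 9-run DSD plus two replicated center runs; threshold geometry
    as in the chromatography preset."""
    design = generate_dsd(4, extra_center_runs=2, factors=_PR_FACTORS)
    return SimulationScenario(
        design=design,
        true_beta=true_beta or {},
        intercept=0.4,
        sigma_resid=sigma_ratio * sigma_sp,
        sigma_sp=sigma_sp,
        n_sp_replicates=6,
        threshold=1.0,
        cqa_name="impurity_concentration",
    )


def recovery_suite(
    seed: int = 0,
    n_datasets: int = 20,
    n_iterations: int = 300,
    step_count: int = 20,
) -> dict:
    """End-to-end self-check: simulate -> stepwise -> retrospective power.

    Verifies on freshly simulated studies that (a) a strong true effect is
    recovered by stepwise selection at high signal-to-noise, (b) power rises
    with effect size, and (c) when the DoE noise matches the set-point
    estimate, a priori and retrospective mean power agree.  Returns the
    measured numbers; callers assert on them.
    """
    rng = np.random.default_rng(seed)
    base = cc1_like_scenario()

    # (a) active-set recovery at high SNR: every true effect must be found
    # (spurious extras occur at the procedure's own false-entry rate, about
    # 1 - (1-p_enter)^k over k null candidates, and are not counted against)
    strong = replace(base, true_beta={"wash_strength": 0.5}, sigma_resid=0.02)
    hits = 0
    for _ in range(n_datasets):
        y, _sp = simulate_study(strong, rng)
        model = stepwise_select(strong.design, y, include_quadratic=False)
        if "wash_strength" in model.term_names:
            hits += 1
    recovery_rate = hits / n_datasets

    # (b) retrospective power grows with the critical effect: shrink the gap
    # by raising the set-point mean (same data, larger threshold distance)
    y, sp = simulate_study(base, rng)
    model = stepwise_select(base.design, y, include_quadratic=False)
    config = RetroPowerConfig(
        n_iterations=n_iterations, step_count=step_count, seed=int(rng.integers(2**31))
    )
    thresholds = (1.0, 1.5, 3.0)  # CG grows left to right
    mean_powers = []
    for threshold in thresholds:
        res = retrospective_power(base.design, y, model, threshold, config)
        mean_powers.append(
            float(np.mean(list(res.per_parameter_power.values())))
        )
    monotone_in_cg = all(a <= b + 1e-12 for a, b in zip(mean_powers, mean_powers[1:]))

    # (c) matched-noise scenario: a priori ~= retrospective mean power
    matched = pr_like_scenario()
    y_m, sp_m = simulate_study(matched, rng)
    model_m = stepwise_select(matched.design, y_m, include_quadratic=False)
    cg = critical_gap_setpoint(matched.threshold, sp_m.mean)
    apriori = apriori_power(
        matched.design, cg, sp_m.sd, step_count=step_count
    ).mean_power
    retro = retrospective_power(
        matched.design, y_m, model_m, matched.cqa_spec(), config
    )
    retro_mean = float(np.mean(list(retro.per_parameter_power.values())))

    return {
        "recovery_rate": recovery_rate,
        "power_by_threshold": dict(zip(thresholds, mean_powers)),
        "monotone_in_cg": monotone_in_cg,
        "apriori_mean_power": apriori,
        "retro_mean_power_matched": retro_mean,
        "apriori_retro_gap": abs(apriori - retro_mean),
    }
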