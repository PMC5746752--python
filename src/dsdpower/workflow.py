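"""End-to-end criticality assessment of a process-characterization DoE.

Per CQA the workflow runs: a priori power at the set-point critical gap,
stepwise model selection, retrospective permutation power for the
non-significant factors, and a criticality call per factor:

* ``critical_significant`` — the factor entered the selected model;
* ``non_critical_powered`` — not selected, and the retrospective power to
  have detected a critical effect meets the cutoff (default 0.8);
* ``potentially_overlooked`` — not selected and under-powered; the report
  enumerates the mitigation options (re-measure samples, re-run experiments,
  tighten the NOR) but never applies one automatically.

The report is a pure function of (inputs, configuration, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .apriori import apriori_power
from .design import (
    DesignMatrix,
    ResponseVector,
    SetPointSample,
    factors_from_json,
    load_design,
    load_response,
    load_setpoint,
)
from .retro import RetroPowerConfig, retrospective_power
from .stepwise import residual_sd_ratio, stepwise_select
from .thresholds import CQASpec, cqas_from_json, critical_gap_setpoint

__all__ = ["CriticalityCall", "MITIGATION_OPTIONS", "assess_cqa", "run_workflow"]

MITIGATION_OPTIONS = (
    "re-measure backup samples with a lower-variance method",
    "re-run experiments to reduce reproducibility variance",
    "tighten the parameter's NOR and re-assess",
)


@dataclass(frozen=True)
class CriticalityCall:
    """Per-parameter outcome of the criticality assessment."""

    parameter: str
    status: str
    p_value: float | None = None
    power: float | None = None
    mitigation: str = "none"

    _STATUSES = (
        "critical_significant",
        "non_critical_powered",
        "potentially_overlooked",
        "non_critical_after_mitigation",
    )

    def __post_init__(self) -> None:
        if self.status not in self._STATUSES:
            raise ValueError(f"unknown criticality status {self.status!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def assess_cqa(
    design: DesignMatrix,
    response: ResponseVector,
    sp_sample: SetPointSample,
    cqa: CQASpec,
    alpha: float = 0.05,
    power_cutoff: float = 0.8,
    retro_config: RetroPowerConfig | None = None,
    include_quadratic: bool = True,
    include_interactions: bool = False,
    apriori_step_count: int = 100,
) -> dict:
    """Assess one CQA: power analyses, model fit, per-parameter calls."""
    if not 0.5 <= power_cutoff < 1.0:
        raise ValueError(f"power_cutoff should be in [0.5, 1), got {power_cutoff}")
    retro_config = retro_config or RetroPowerConfig(alpha=alpha)
    threshold = cqa.threshold
    cg_sp = critical_gap_setpoint(threshold, sp_sample.mean, cqa.direction)
    apriori = apriori_power(
        design, cg_sp, sp_sample.sd, alpha=alpha, step_count=apriori_step_count
    )
    model = stepwise_select(
        design,
        response,
        include_quadratic=include_quadratic,
        include_interactions=include_interactions,
    )
    sd_ratio = residual_sd_ratio(model, sp_sample)
    retro = retrospective_power(design, response, model, cqa, retro_config)

    calls = []
    sig = model.significant_factor_names()
    pv_by_factor: dict[str, float] = {}
    for term, p in zip(model.terms, model.pvalues):
        for name in term.factors:
            pv_by_factor[name] = min(float(p), pv_by_factor.get(name, np.inf))
    for f in design.factors:
        if f.name in sig:
            calls.append(
                CriticalityCall(
                    f.name, "critical_significant", p_value=pv_by_factor[f.name]
                )
            )
            continue
        power = retro.per_parameter_power.get(f.name)
        if power is not None and power >= power_cutoff:
            calls.append(
                CriticalityCall(f.name, "non_critical_powered", power=power)
            )
        else:
            calls.append(
                CriticalityCall(
                    f.name,
                    "potentially_overlooked",
                    power=power,
                    mitigation=" | ".join(MITIGATION_OPTIONS),
                )
            )
    return {
        "cqa": cqa.name,
        "threshold": threshold,
        "direction": cqa.direction,
        "setpoint_mean": sp_sample.mean,
        "sigma_sp": sp_sample.sd,
        "critical_gap_setpoint": cg_sp.value,
        "apriori": apriori.to_report(),
        "model": model.to_report(),
        "sigma_ratio": sd_ratio,
        "retrospective": retro.to_report(),
        "power_cutoff": power_cutoff,
        "calls": [c.to_dict() for c in calls],
    }


def run_workflow(config: Mapping, base_dir=None, seed: int | None = None) -> dict:
    """Run the full criticality assessment from a file-based configuration.

    Config keys: ``design`` (CSV path), ``factors`` (JSON path),
    ``cqas`` (JSON path), ``responses`` (CSV, run_id + one column per CQA),
    ``setpoints`` (CSV, one column per CQA), optional ``alpha``,
    ``power_cutoff``, ``include_quadratic``, ``include_interactions``,
    ``apriori_step_count`` and a ``retro`` block mirroring
    :class:`RetroPowerConfig`.  Relative paths resolve against ``base_dir``.
    ``seed`` overrides the retro block's seed.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")

    def _path(key: str) -> Path:
        p = Path(config[key])
        return p if p.is_absolute() else base / p

    factors = factors_from_json(str(_path("factors")))
    design = load_design(_path("design"), factors)
    cqas = cqas_from_json(str(_path("cqas")))
    retro_kwargs = dict(config.get("retro", {}))
    if seed is not None:
        retro_kwargs["seed"] = seed
    retro_kwargs.setdefault("alpha", config.get("alpha", 0.05))
    retro_config = RetroPowerConfig(**retro_kwargs)

    results = []
    for cqa in cqas:
        response = load_response(
            _path("responses"), cqa.name, expected_runs=design.n_runs
        )
        sp = load_setpoint(_path("setpoints"), cqa.name)
        results.append(
            assess_cqa(
                design,
                response,
                sp,
                cqa,
                alpha=config.get("alpha", 0.05),
                power_cutoff=config.get("power_cutoff", 0.8),
                retro_config=retro_config,
                include_quadratic=config.get("include_quadratic", True),
                include_interactions=config.get("include_interactions", False),
                apriori_step_count=config.get("apriori_step_count", 100),
            )
        )
    return {
        "design": {"n_runs": design.n_runs, "factors": list(design.factor_names)},
        "alpha": config.get("alpha", 0.05),
        "power_cutoff": config.get("power_cutoff", 0.8),
        "seed": retro_config.seed,
        "cqas": results,
    }
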