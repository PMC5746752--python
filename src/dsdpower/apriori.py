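"""A priori (pre-experiment) power of a design to detect critical effects.

With p factors there are infinitely many ways the critical gap can be split
among parameter effects.  The approach taken here sweeps a grid of weight
vectors: one parameter carries a fraction ``a`` of the gap and the remaining
``1 - a`` is spread evenly over the others, for ``a`` in steps of
``1/step_count`` and each parameter in turn — ``C = p * step_count``
combinations.  For each combination the critical effects define a noiseless
response over the design; its total sum of squares is compared to the
residual sum of squares expected from set-point noise,

    SSres = (n - 1) * sigma_SP^2,

giving an expected coefficient of determination, Cohen's f^2, and the
noncentrality lambda = f^2 * nu of the overall-model F test (u = p numerator
and nu = n - p - 1 denominator degrees of freedom).  The design's a priori
power is the mean of the per-combination powers.

Uncertainty in lambda (it is estimated from a finite set-point sample) is
propagated through chi-square percentile scaling, giving a per-combination
power interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .design import DesignMatrix, FactorSpec
from .thresholds import CriticalGap, critical_effect

__all__ = [
    "PowerError",
    "weight_grid",
    "expected_ss_res",
    "apriori_power_combination",
    "apriori_power",
    "CombinationPower",
    "AprioriPowerResult",
]


class PowerError(ValueError):
    """Invalid power-analysis input."""


def weight_grid(p: int, step_count: int = 100) -> np.ndarray:
    """The ``C = p * step_count`` effect-weight combinations.

    Row c assigns weight ``a`` in {1/step_count, ..., 1} to one indexed
    parameter and ``(1 - a)/(p - 1)`` to each of the others; rows are ordered
    parameter-major with ``a`` ascending.  Every row sums to 1.  For p = 1
    the only admissible weight vector is (1,), repeated so the row count
    stays ``p * step_count``.
    """
    if p < 1:
        raise PowerError(f"parameter count must be >= 1, got {p}")
    if step_count < 1:
        raise PowerError(f"step_count must be >= 1, got {step_count}")
    a = np.arange(1, step_count + 1) / step_count
    if p == 1:
        return np.ones((step_count, 1))
    grid = np.empty((p * step_count, p))
    for i in range(p):
        block = np.repeat(((1.0 - a) / (p - 1))[:, None], p, axis=1)
        block[:, i] = a
        grid[i * step_count : (i + 1) * step_count] = block
    return grid


def expected_ss_res(n: int, sigma_sp: float) -> float:
    """Expected residual sum of squares of an n-run DoE, from set-point noise."""
    if n < 2:
        raise PowerError(f"need at least 2 DoE runs, got n={n}")
    if sigma_sp <= 0:
        raise PowerError(f"sigma_sp must be > 0, got {sigma_sp}")
    return (n - 1) * sigma_sp**2


@dataclass(frozen=True)
class CombinationPower:
    power: float
    ci: tuple[float, float]
    lam: float
    flag: str | None = None


def _ncf_power(fcrit: float, u: int, nu: int, lam: float, alpha: float) -> float:
    if lam <= 0:
        return alpha  # central F: P(F > Fcrit) = alpha exactly
    return float(1.0 - stats.ncf.cdf(fcrit, u, nu, lam))


def apriori_power_combination(
    X: np.ndarray | DesignMatrix,
    beta_crit: Sequence[float],
    ss_res: float,
    alpha: float = 0.05,
    ci_alpha: float | None = None,
    conventional_r2: bool = False,
) -> CombinationPower:
    """Power of the overall-model F test against one critical-effect vector.

    ``X`` holds the main-effect columns of the design (n x p).  The expected
    signal is the noiseless response ``X @ beta_crit``; ``ss_res`` is the
    expected residual sum of squares.  By default the expected R^2 is
    ``1 - ss_res / ss_tot`` (clamped at 0 when noise exceeds the critical
    signal, flagged); ``conventional_r2=True`` uses
    ``ss_tot / (ss_tot + ss_res)`` instead.
    """
    if isinstance(X, DesignMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    beta_crit = np.asarray(beta_crit, dtype=float)
    n, p = X.shape
    if beta_crit.shape != (p,):
        raise PowerError(f"beta_crit has shape {beta_crit.shape}, expected ({p},)")
    u, nu = p, n - p - 1
    if nu < 1:
        raise PowerError(f"n={n} runs leave no residual df for p={p} parameters")
    if ss_res <= 0:
        raise PowerError("ss_res must be > 0")
    if not 0 < alpha < 1:
        raise PowerError(f"alpha must be in (0, 1), got {alpha}")

    y = X @ beta_crit
    ss_tot = float(((y - y.mean()) ** 2).sum())
    flag = None
    if ss_tot == 0.0:
        if np.any(beta_crit != 0.0):
            raise PowerError(
                "critical effects produce no response variation over the "
                "design; the design cannot carry these effects (degenerate)"
            )
        flag = "zero critical effect; power equals the significance level"
        lam = 0.0
    else:
        if conventional_r2:
            r2 = ss_tot / (ss_tot + ss_res)
        else:
            r2 = 1.0 - ss_res / ss_tot
        if r2 <= 0.0:
            flag = "noise exceeds critical signal; power floored at alpha"
            r2 = 0.0
        f2 = r2 / (1.0 - r2)
        lam = f2 * nu

    fcrit = float(stats.f.ppf(1.0 - alpha, u, nu))
    power = _ncf_power(fcrit, u, nu, lam, alpha)
    ca = alpha if ci_alpha is None else ci_alpha
    lam_low = lam * float(stats.chi2.ppf(ca, nu)) / nu
    lam_upp = lam * float(stats.chi2.ppf(1.0 - ca, nu)) / nu
    ci = (
        _ncf_power(fcrit, u, nu, lam_low, alpha),
        _ncf_power(fcrit, u, nu, lam_upp, alpha),
    )
    return CombinationPower(power=power, ci=ci, lam=lam, flag=flag)


@dataclass(frozen=True)
class AprioriPowerResult:
    """Per-combination and mean a priori power of a design."""

    mean_power: float
    per_combination: np.ndarray = field(repr=False)
    ci_low: np.ndarray = field(repr=False)
    ci_high: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    inputs: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def per_parameter_mean(self) -> dict[str, float]:
        """Mean power over the block of combinations indexing each parameter."""
        names = self.inputs.get("factor_names")
        steps = self.per_combination.size // len(names)
        return {
            name: float(self.per_combination[i * steps : (i + 1) * steps].mean())
            for i, name in enumerate(names)
        }

    def to_report(self) -> dict:
        return {
            "mean_power": self.mean_power,
            "n_combinations": int(self.per_combination.size),
            "per_parameter_mean": self.per_parameter_mean(),
            "inputs": self.inputs,
            "flags": list(self.flags),
        }


def apriori_power(
    design: DesignMatrix,
    cg: CriticalGap,
    sigma_sp: float,
    alpha: float = 0.05,
    step_count: int = 100,
    ci_alpha: float | None = None,
    conventional_r2: bool = False,
) -> AprioriPowerResult:
    """Mean a priori power of a design over the effect-weight grid.

    ``cg`` is the set-point critical gap of the CQA; per-factor critical
    effects are derived from each weight vector and the factor NORs.
    """
    factors = design.factors
    p = design.n_factors
    grid = weight_grid(p, step_count)
    ss_res = expected_ss_res(design.n_runs, sigma_sp)
    powers = np.empty(grid.shape[0])
    lo = np.empty_like(powers)
    hi = np.empty_like(powers)
    flags: list[str] = []
    for c, w in enumerate(grid):
        beta = [critical_effect(wi, cg, f) for wi, f in zip(w, factors)]
        res = apriori_power_combination(
            design.values, beta, ss_res, alpha, ci_alpha, conventional_r2
        )
        powers[c], (lo[c], hi[c]) = res.power, res.ci
        if res.flag and res.flag not in flags:
            flags.append(res.flag)
    return AprioriPowerResult(
        mean_power=float(powers.mean()),
        per_combination=powers,
        ci_low=lo,
        ci_high=hi,
        weights=grid,
        inputs={
            "n": design.n_runs,
            "p": p,
            "alpha": alpha,
            "sigma_sp": sigma_sp,
            "critical_gap": cg.value,
            "cg_basis": cg.basis,
            "step_count": step_count,
            "factor_names": list(design.factor_names),
        },
        flags=tuple(flags),
    )
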