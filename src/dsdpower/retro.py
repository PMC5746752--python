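"""Retrospective power by residual permutation.

After a DoE has been evaluated and a significant model selected, the factors
that did *not* enter the model are not thereby proven harmless: their effect
estimates merely failed to clear the significance bar against the realized
residual noise.  This module estimates, for each non-significant factor, the
probability that an effect of *critical* size — one large enough that, at
its NOR excursion, it would consume its share of the critical gap — would
have been detected in this experiment.

The estimate is a permutation test.  For each effect-weight combination c
over the non-significant factors:

1. critical effects beta_crit(c) are computed from the worst-case critical
   gap (threshold minus the extreme model prediction over the NOR box);
2. the model residuals are randomly permuted;
3. an alternative-hypothesis response is synthesized,
       y* = b0 + Xs bs + Z beta_crit(c) + R*,
   where Xs are the selected terms and Z the main-effect columns of the
   non-significant factors;
4. one OLS model on [1 | Xs | Z] is fit to y* and the two-sided significance
   of each beta_crit coefficient is recorded.

The fraction of significant outcomes over all iterations is the power for
that combination; a parameter's retrospective power is the mean over all
combinations.  Because the permuted residuals are reused rather than drawn
from a parametric model, no normality assumption is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .apriori import weight_grid
from .design import DesignError, DesignMatrix, FactorSpec, ResponseVector
from .stepwise import FittedModel
from .thresholds import (
    CQASpec,
    CriticalGap,
    ThresholdError,
    critical_effect,
    critical_gap_worstcase,
)

__all__ = [
    "RetroPowerConfig",
    "RetroPowerResult",
    "permute_residuals",
    "synthesize_alternative",
    "assess_significance",
    "retrospective_power",
    "nor_scan",
]


@dataclass(frozen=True)
class RetroPowerConfig:
    """Settings of the permutation test.

    ``n_iterations`` is the permutation count per weight combination under
    the default ``combination_strategy="per_combination"``; under
    ``"sampled"`` each iteration draws one combination uniformly and
    ``n_iterations`` is the total count (faster, noisier).  At least ~100
    iterations should back any reported power value.
    """

    alpha: float = 0.05
    n_iterations: int = 1000
    step_count: int = 100
    seed: int = 0
    combination_strategy: str = "per_combination"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.step_count < 1:
            raise ValueError("step_count must be >= 1")
        if self.combination_strategy not in ("per_combination", "sampled"):
            raise ValueError(
                f"unknown combination_strategy {self.combination_strategy!r}"
            )


@dataclass(frozen=True)
class RetroPowerResult:
    """Per-parameter retrospective power and the per-combination detail."""

    parameter_names: tuple[str, ...]
    per_parameter_power: dict[str, float]
    per_combination: np.ndarray = field(repr=False)  # (C, p_ns) or (1, p_ns)
    weights: np.ndarray = field(repr=False)
    cg_used: CriticalGap | None = None
    config: RetroPowerConfig | None = None
    notices: tuple[str, ...] = ()

    @property
    def is_empty(self) -> bool:
        return not self.parameter_names

    def per_combination_frame(self) -> pd.DataFrame:
        """Long-form table (parameter, weight, power) for NOR-scan plots."""
        rows = []
        for c in range(self.per_combination.shape[0]):
            for j, name in enumerate(self.parameter_names):
                rows.append(
                    {
                        "combination": c,
                        "parameter": name,
                        "weight": self.weights[c, j],
                        "power": self.per_combination[c, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_report(self) -> dict:
        return {
            "per_parameter_power": dict(self.per_parameter_power),
            "critical_gap": None if self.cg_used is None else self.cg_used.value,
            "cg_basis": None if self.cg_used is None else self.cg_used.basis,
            "alpha": None if self.config is None else self.config.alpha,
            "n_iterations": None if self.config is None else self.config.n_iterations,
            "strategy": None
            if self.config is None
            else self.config.combination_strategy,
            "seed": None if self.config is None else self.config.seed,
            "notices": list(self.notices),
        }


def permute_residuals(residuals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random permutation of the residual vector."""
    return rng.permutation(np.asarray(residuals, dtype=float))


def synthesize_alternative(
    intercept: float,
    beta_s: np.ndarray,
    X_s: np.ndarray,
    beta_crit: np.ndarray,
    Z: np.ndarray,
    permuted_residuals: np.ndarray,
) -> np.ndarray:
    """Alternative-hypothesis response: fitted part + injected critical
    effects + permuted residuals."""
    X_s = np.asarray(X_s, dtype=float)
    Z = np.asarray(Z, dtype=float)
    beta_s = np.asarray(beta_s, dtype=float).ravel()
    beta_crit = np.asarray(beta_crit, dtype=float).ravel()
    r = np.asarray(permuted_residuals, dtype=float).ravel()
    if X_s.ndim != 2 or Z.ndim != 2:
        raise DesignError("X_s and Z must be 2-d arrays")
    n = r.size
    if X_s.shape != (n, beta_s.size) or Z.shape != (n, beta_crit.size):
        raise DesignError(
            f"shape mismatch: X_s {X_s.shape} vs beta_s {beta_s.shape}, "
            f"Z {Z.shape} vs beta_crit {beta_crit.shape}, n={n}"
        )
    return intercept + X_s @ beta_s + Z @ beta_crit + r


class _SignificanceEngine:
    """Batched two-sided t-tests for the Z coefficients of [1 | Xs | Z].

    The injected effects and the refitted base model lie in the column space
    of the full design, so across permutations only the residual vector
    varies; the QR factorization, the coefficient-extraction rows of the
    pseudo-inverse and the coefficient variances are computed once.
    """

    def __init__(self, X_s: np.ndarray, Z: np.ndarray):
        n = Z.shape[0]
        A = np.column_stack([np.ones(n), X_s, Z])
        s = np.linalg.svd(A, compute_uv=False)
        if s[-1] <= 1e-10 * max(s[0], 1.0):
            raise DesignError(
                "design [1 | X_s | Z] is rank deficient; significant-term "
                "and non-significant-parameter columns are collinear"
            )
        self.n, self.k = A.shape
        self.df = self.n - self.k
        if self.df < 1:
            raise DesignError(
                f"{self.n} runs leave no residual df for {self.k} coefficients"
            )
        self.A = A
        self.z_slice = slice(1 + X_s.shape[1], self.k)
        self.q, _ = np.linalg.qr(A)
        pinv = np.linalg.pinv(A)
        self.h_z = pinv[self.z_slice]  # rows mapping y -> beta_hat_z
        xtx_inv = pinv @ pinv.T
        self.v_z = np.diag(xtx_inv)[self.z_slice]

    def pvalues_for_noise(
        self, noise: np.ndarray, beta_crit: np.ndarray
    ) -> np.ndarray:
        """p-values of the Z coefficients for y* = base + Z beta_crit + noise.

        ``noise`` is (n, B); returns (n_z, B).  The base fitted part cancels
        out of both the coefficient perturbation and the residual SS.
        """
        coef = beta_crit[:, None] + self.h_z @ noise
        proj = self.q.T @ noise
        sse = np.einsum("ij,ij->j", noise, noise) - np.einsum(
            "ij,ij->j", proj, proj
        )
        s2 = np.maximum(sse, 0.0) / self.df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = coef / np.sqrt(s2[None, :] * self.v_z[:, None])
        t = np.where(np.isfinite(t), t, np.inf * np.sign(coef))
        return 2.0 * stats.t.sf(np.abs(t), self.df)


def assess_significance(
    y_star: np.ndarray,
    X_s: np.ndarray,
    Z: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Fit one OLS model on [1 | X_s | Z] and test each Z coefficient.

    Returns a boolean array: two-sided p < alpha per non-significant
    parameter.
    """
    X_s = np.asarray(X_s, dtype=float)
    Z = np.asarray(Z, dtype=float)
    y_star = np.asarray(y_star, dtype=float).ravel()
    eng = _SignificanceEngine(X_s, Z)
    # run the batched path with B=1; beta_crit folded into y_star already
    beta_full = np.linalg.pinv(eng.A) @ y_star
    resid = y_star - eng.A @ beta_full
    coef_z = beta_full[eng.z_slice]
    sse = float(resid @ resid)
    s2 = sse / eng.df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef_z / np.sqrt(s2 * eng.v_z)
    t = np.where(np.isfinite(t), t, np.inf * np.sign(coef_z))
    p = 2.0 * stats.t.sf(np.abs(t), eng.df)
    return p < alpha


def _permutation_matrix(
    residuals: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """n x B matrix whose columns are independent permutations of the
    residual vector."""
    tiled = np.tile(residuals, (B, 1))
    return rng.permuted(tiled, axis=1).T


def retrospective_power(
    design: DesignMatrix,
    response,
    model: FittedModel,
    cqa: CQASpec | float,
    config: RetroPowerConfig | None = None,
) -> RetroPowerResult:
    """Retrospective power of every non-significant factor.

    ``cqa`` may be a :class:`CQASpec` or a bare upper threshold.  The
    critical gap is re-derived from the worst-case model prediction over the
    *current* factor NORs in ``design.factors``, so passing a design with
    tightened NORs re-scales the critical effects (and, when a significant
    term's NOR shrank, enlarges the gap itself).

    The response the model was fitted to is accepted for validation; the
    permutation loop itself only needs the model's fitted values and
    residuals.
    """
    config = config or RetroPowerConfig()
    if isinstance(cqa, CQASpec):
        threshold, direction = cqa.threshold, cqa.direction
    else:
        threshold, direction = float(cqa), "upper"
    if response is not None:
        yv = response.values if isinstance(response, ResponseVector) else (
            np.asarray(response, dtype=float).ravel()
        )
        if yv.size != design.n_runs:
            raise DesignError("response length does not match the design")
        if not np.allclose(model.fitted + model.residuals, yv):
            raise DesignError(
                "model residuals do not reconstruct the response; the model "
                "was not fitted to this data"
            )
    if model.n_runs != design.n_runs:
        raise DesignError("model was fitted on a different run count")

    sig = model.significant_factor_names()
    ns_factors = tuple(f for f in design.factors if f.name not in sig)
    if not ns_factors:
        return RetroPowerResult(
            parameter_names=(),
            per_parameter_power={},
            per_combination=np.empty((0, 0)),
            weights=np.empty((0, 0)),
            cg_used=None,
            config=config,
            notices=("all factors are in the selected model; nothing to assess",),
        )

    cg = critical_gap_worstcase(threshold, model, design.factors, direction)
    sign = 1.0 if direction == "upper" else -1.0
    excursions = np.array([f.max_excursion for f in ns_factors])
    if np.any(excursions <= 0):
        raise ThresholdError("a non-significant factor has a degenerate NOR")

    X_s = model.design_columns(design)
    Z = np.column_stack([design.column(f.name) for f in ns_factors])
    engine = _SignificanceEngine(X_s, Z)
    rng = np.random.default_rng(config.seed)
    grid = weight_grid(len(ns_factors), config.step_count)
    res = model.residuals

    if config.combination_strategy == "per_combination":
        per_comb = np.empty((grid.shape[0], len(ns_factors)))
        for c, w in enumerate(grid):
            beta_crit = sign * w * cg.value / excursions
            noise = _permutation_matrix(res, config.n_iterations, rng)
            p = engine.pvalues_for_noise(noise, beta_crit)
            per_comb[c] = (p < config.alpha).mean(axis=1)
        power = per_comb.mean(axis=0)
        weights = grid
    else:  # sampled: each iteration draws one combination uniformly
        idx = rng.integers(0, grid.shape[0], size=config.n_iterations)
        beta_mat = (sign * cg.value / excursions)[:, None] * grid[idx].T
        noise = _permutation_matrix(res, config.n_iterations, rng)
        coef = beta_mat + engine.h_z @ noise
        proj = engine.q.T @ noise
        sse = np.einsum("ij,ij->j", noise, noise) - np.einsum(
            "ij,ij->j", proj, proj
        )
        s2 = np.maximum(sse, 0.0) / engine.df
        t = coef / np.sqrt(s2[None, :] * engine.v_z[:, None])
        p = 2.0 * stats.t.sf(np.abs(t), engine.df)
        power = (p < config.alpha).mean(axis=1)
        per_comb = power[None, :]
        weights = np.full((1, len(ns_factors)), np.nan)

    names = tuple(f.name for f in ns_factors)
    return RetroPowerResult(
        parameter_names=names,
        per_parameter_power={n: float(v) for n, v in zip(names, power)},
        per_combination=per_comb,
        weights=weights,
        cg_used=cg,
        config=config,
    )


def nor_scan(
    design: DesignMatrix,
    response,
    model: FittedModel,
    cqa: CQASpec | float,
    config: RetroPowerConfig,
    target_factor: str,
    shrink_fractions: Sequence[float],
) -> list[tuple[float, RetroPowerResult]]:
    """Retrospective power as a function of tightening one factor's NOR.

    Each fraction shrinks the target factor's NOR symmetrically about its
    set point and re-runs the permutation test under the same seed policy,
    so fraction 0 reproduces the baseline bit for bit.  Tightening a
    non-significant factor raises only its own power (its critical effect
    grows); tightening a factor in the model raises everyone's power through
    a larger worst-case critical gap.
    """
    if target_factor not in design.factor_names:
        raise DesignError(f"no factor named {target_factor!r} in design")
    out = []
    for frac in shrink_fractions:
        factors = tuple(
            f.shrink_nor(frac) if f.name == target_factor else f
            for f in design.factors
        )
        scan_design = design.with_factors(factors)
        out.append(
            (float(frac), retrospective_power(scan_design, response, model, cqa, config))
        )
    return out
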