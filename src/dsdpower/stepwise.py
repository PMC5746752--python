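"""Stepwise multiple linear regression for DoE evaluation.

Candidate terms are main effects, pure quadratics of numeric factors, and
(optionally) pairwise interactions.  Selection alternates an entry step —
add the candidate with the smallest partial p-value if it is below
``p_enter`` — with an exit step — drop the included term with the largest
p-value if it is above ``p_exit`` — until a full cycle leaves the model
unchanged.  The intercept is always retained.  Partial p-values are
two-sided t-test p-values of a coefficient within the model it is (or would
be) part of, the standard stepwise semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .design import DesignError, DesignMatrix, FactorSpec, ResponseVector, SetPointSample

__all__ = [
    "SelectionError",
    "ModelTerm",
    "FittedModel",
    "term_from_name",
    "build_candidates",
    "fit_terms",
    "stepwise_select",
    "residual_sd_ratio",
]

_RANK_RTOL = 1e-10


class SelectionError(ValueError):
    """Stepwise selection failed (non-convergence, bad inputs)."""


@dataclass(frozen=True)
class ModelTerm:
    """One regression term: a main effect x_i, quadratic x_i^2, or
    interaction x_i * x_j."""

    kind: str
    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        expected = {"main": 1, "quadratic": 1, "interaction": 2}
        if self.kind not in expected:
            raise SelectionError(f"unknown term kind {self.kind!r}")
        if len(self.factors) != expected[self.kind]:
            raise SelectionError(
                f"{self.kind} term takes {expected[self.kind]} factor(s), "
                f"got {self.factors}"
            )
        if self.kind == "interaction" and self.factors[0] == self.factors[1]:
            raise SelectionError("interaction factors must be distinct")

    @property
    def name(self) -> str:
        if self.kind == "main":
            return self.factors[0]
        if self.kind == "quadratic":
            return f"{self.factors[0]}^2"
        return f"{self.factors[0]}:{self.factors[1]}"

    def build_column(self, design: DesignMatrix) -> np.ndarray:
        if self.kind == "main":
            return design.column(self.factors[0])
        if self.kind == "quadratic":
            return design.column(self.factors[0]) ** 2
        return design.column(self.factors[0]) * design.column(self.factors[1])


def term_from_name(name: str) -> ModelTerm:
    """Parse ``"A"``, ``"A^2"`` or ``"A:B"`` into a ModelTerm."""
    if ":" in name:
        a, b = name.split(":")
        return ModelTerm("interaction", (a, b))
    if name.endswith("^2"):
        return ModelTerm("quadratic", (name[:-2],))
    return ModelTerm("main", (name,))


def build_candidates(
    factors: Sequence[FactorSpec],
    include_quadratic: bool = True,
    include_interactions: bool = False,
) -> tuple[ModelTerm, ...]:
    """Deterministic, ordered candidate list: mains, quadratics, interactions.

    Quadratic terms are only generated for numeric factors (a two-level
    categorical factor has no curvature to estimate).
    """
    factors = tuple(factors)
    if not factors:
        raise SelectionError("need at least one factor")
    terms = [ModelTerm("main", (f.name,)) for f in factors]
    if include_quadratic:
        terms += [
            ModelTerm("quadratic", (f.name,))
            for f in factors
            if f.kind == "numeric"
        ]
    if include_interactions:
        names = [f.name for f in factors]
        terms += [
            ModelTerm("interaction", (a, b))
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
    return tuple(terms)


@dataclass(frozen=True)
class FittedModel:
    """A least-squares fit of selected terms, with the audit trail.

    ``sigma_residuals`` follows the raw-residual convention (denominator
    sqrt(n-1)); ``residual_sd(denominator="df")`` gives the model-df
    alternative sqrt(SSE / (n - q - 1)).
    """

    factors: tuple[FactorSpec, ...]
    terms: tuple[ModelTerm, ...]
    intercept: float
    coefs: np.ndarray = field(repr=False)
    pvalues: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    trace: tuple[str, ...] = ()

    @property
    def n_runs(self) -> int:
        return self.residuals.size

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    @property
    def sigma_residuals(self) -> float:
        return self.residual_sd("raw")

    def residual_sd(self, denominator: str = "raw") -> float:
        sse = float(self.residuals @ self.residuals)
        if denominator == "raw":
            return float(np.sqrt(sse / (self.n_runs - 1)))
        if denominator == "df":
            df = self.n_runs - len(self.terms) - 1
            if df < 1:
                raise SelectionError("no residual degrees of freedom")
            return float(np.sqrt(sse / df))
        raise SelectionError(f"denominator must be 'raw' or 'df', got {denominator!r}")

    def significant_factor_names(self) -> frozenset[str]:
        """Factors appearing in any selected term.

        A factor whose quadratic (or interaction) term was selected counts as
        significant even if its main effect was not: its influence on the
        worst-case prediction is already modelled.
        """
        return frozenset(n for t in self.terms for n in t.factors)

    def design_columns(self, design: DesignMatrix) -> np.ndarray:
        """The n x q matrix of selected-term columns over ``design``."""
        if not self.terms:
            return np.empty((design.n_runs, 0))
        return np.column_stack([t.build_column(design) for t in self.terms])

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Predict at coded points ``values`` (k x p, factor order)."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != len(self.factors):
            raise SelectionError(
                f"points have {values.shape[1]} columns, model has "
                f"{len(self.factors)} factors"
            )
        design = DesignMatrix.__new__(DesignMatrix)  # bypass level checks
        object.__setattr__(design, "factors", self.factors)
        object.__setattr__(design, "values", values)
        out = np.full(values.shape[0], self.intercept)
        for term, coef in zip(self.terms, self.coefs):
            out += coef * term.build_column(design)
        return out

    def to_report(self) -> dict:
        return {
            "intercept": self.intercept,
            "terms": [
                {"term": t.name, "coef": float(c), "p_value": float(p)}
                for t, c, p in zip(self.terms, self.coefs, self.pvalues)
            ],
            "sigma_residuals": self.sigma_residuals,
            "trace": list(self.trace),
        }


def _response_array(y) -> np.ndarray:
    if isinstance(y, ResponseVector):
        return y.values
    return np.asarray(y, dtype=float).ravel()


def _full_rank(X: np.ndarray) -> bool:
    if X.shape[1] == 0:
        return True
    s = np.linalg.svd(X, compute_uv=False)
    return s[-1] > _RANK_RTOL * max(s[0], 1.0)


def fit_terms(
    design: DesignMatrix,
    y,
    terms: Sequence[ModelTerm],
    factors: Sequence[FactorSpec] | None = None,
    trace: Sequence[str] = (),
) -> FittedModel:
    """Ordinary least squares with an intercept on the given terms."""
    yv = _response_array(y)
    if yv.size != design.n_runs:
        raise DesignError(
            f"response has {yv.size} values but the design has "
            f"{design.n_runs} runs"
        )
    terms = tuple(terms)
    cols = (
        np.column_stack([t.build_column(design) for t in terms])
        if terms
        else np.empty((design.n_runs, 0))
    )
    X = sm.add_constant(cols, has_constant="add")
    if design.n_runs - X.shape[1] < 1:
        raise SelectionError(
            f"{design.n_runs} runs cannot support {len(terms)} terms plus an "
            "intercept with residual degrees of freedom"
        )
    if not _full_rank(X):
        raise SelectionError(
            f"design columns for terms {[t.name for t in terms]} are "
            "collinear"
        )
    fit = sm.OLS(yv, X).fit()
    return FittedModel(
        factors=tuple(factors) if factors is not None else design.factors,
        terms=terms,
        intercept=float(fit.params[0]),
        coefs=np.asarray(fit.params[1:], dtype=float),
        pvalues=np.asarray(fit.pvalues[1:], dtype=float),
        residuals=np.asarray(fit.resid, dtype=float),
        fitted=np.asarray(fit.fittedvalues, dtype=float),
        trace=tuple(trace),
    )


def stepwise_select(
    design: DesignMatrix,
    y,
    candidates: Sequence[ModelTerm] | None = None,
    p_enter: float = 0.05,
    p_exit: float = 0.10,
    max_cycles: int = 50,
    min_resid_df: int = 2,
    include_quadratic: bool = True,
    include_interactions: bool = False,
) -> FittedModel:
    """Stepwise enter/exit selection over the candidate terms.

    Entry: among candidates not in the model, fit each alongside the current
    terms and take the one with the smallest partial p-value; enter it if
    p < ``p_enter`` (ties resolved by candidate order).  Exit: refit and drop
    the included term with the largest p-value if p > ``p_exit``.  Repeat
    until a full entry+exit cycle changes nothing.  A candidate is skipped
    (with a trace notice) if adding it would make the design collinear or
    leave fewer than ``min_resid_df`` residual degrees of freedom.
    """
    if candidates is None:
        candidates = build_candidates(
            design.factors, include_quadratic, include_interactions
        )
    candidates = tuple(candidates)
    yv = _response_array(y)
    if yv.size != design.n_runs:
        raise DesignError(
            f"response has {yv.size} values but the design has "
            f"{design.n_runs} runs"
        )
    if not 0 < p_enter < 1 or not 0 < p_exit < 1:
        raise SelectionError("p_enter and p_exit must be in (0, 1)")

    n = design.n_runs
    col = {t.name: t.build_column(design) for t in candidates}
    selected: list[ModelTerm] = []
    trace: list[str] = []

    def _fit(terms: Sequence[ModelTerm]):
        X = sm.add_constant(
            np.column_stack([col[t.name] for t in terms])
            if terms
            else np.empty((n, 0)),
            has_constant="add",
        )
        return sm.OLS(yv, X).fit()

    y_scale = float(max(yv @ yv, 1.0))
    for cycle in range(max_cycles):
        changed = False
        # --- entry step; skipped once the fit is numerically perfect
        # (p-values degenerate to floating-point noise at zero residual SS)
        sse_now = float(_fit(selected).ssr)
        if sse_now <= 1e-20 * y_scale:
            trace.append("stop: residual sum of squares at machine zero")
            break
        best: tuple[float, int] | None = None
        for idx, cand in enumerate(candidates):
            if any(cand.name == t.name for t in selected):
                continue
            if n - (len(selected) + 2) < min_resid_df:
                trace.append(
                    f"skip {cand.name}: would leave < {min_resid_df} residual df"
                )
                continue
            trial = selected + [cand]
            Xt = np.column_stack([col[t.name] for t in trial])
            if not _full_rank(sm.add_constant(Xt, has_constant="add")):
                trace.append(f"skip {cand.name}: collinear with current model")
                continue
            p = float(_fit(trial).pvalues[-1])
            if best is None or p < best[0]:  # strict: ties keep first
                best = (p, idx)
        if best is not None and best[0] < p_enter:
            entering = candidates[best[1]]
            selected.append(entering)
            trace.append(f"enter {entering.name} (p={best[0]:.4g})")
            changed = True
        # --- exit step
        if selected:
            pv = _fit(selected).pvalues[1:]
            worst = int(np.argmax(pv))
            if pv[worst] > p_exit:
                leaving = selected.pop(worst)
                trace.append(f"exit {leaving.name} (p={float(pv[worst]):.4g})")
                changed = True
        if not changed:
            break
    else:
        raise SelectionError(
            f"stepwise selection did not converge within {max_cycles} cycles"
        )
    return fit_terms(design, yv, selected, trace=trace)


def residual_sd_ratio(model: FittedModel, sp: SetPointSample) -> float:
    """Observed-vs-expected noise: sigma of raw model residuals over the
    set-point sigma.  Ratios well above 1 flag DoE noise the a priori power
    analysis did not anticipate."""
    return model.sigma_residuals / sp.sd
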