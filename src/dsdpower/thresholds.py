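"""Threshold algebra: intermediate-stage limits, critical gaps, critical effects.

The specification a CQA must meet is set at drug substance (DS), the last
process stage.  For an intermediate unit operation the acceptable level is
back-calculated through the mean specific clearance of every downstream unit
operation.  The *critical gap* (CG) is the distance from current performance
— the set-point mean before experiments, or the worst-case model prediction
over the normal operating ranges after — to that threshold.  A parameter's
*critical effect* is the regression slope just large enough that its NOR
excursion consumes its weighted share of the gap:

    beta_crit_i = w_i * CG / max(NOR_high_i - sp_i, sp_i - NOR_low_i)

dividing by the longest admissible excursion from the set point (the
risk-conservative choice, valid for asymmetric NORs).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .design import DesignError, FactorSpec

__all__ = [
    "ThresholdError",
    "ThresholdExceededError",
    "DegenerateNorError",
    "CQASpec",
    "CriticalGap",
    "specific_clearance",
    "threshold_from_usl",
    "critical_gap_setpoint",
    "worst_case_prediction",
    "critical_gap_worstcase",
    "critical_effect",
    "cqas_from_json",
]


class ThresholdError(ValueError):
    """Invalid threshold configuration."""


class ThresholdExceededError(ThresholdError):
    """Current performance already at or beyond the threshold (CG <= 0).

    The criticality workflow presumes a positive gap to protect; a
    non-positive gap means the process is out of specification at its
    nominal (or worst-case predicted) state and must be fixed, not powered.
    """


class DegenerateNorError(ThresholdError):
    """NOR collapsed onto the set point; no excursion to scale an effect by."""


@dataclass(frozen=True)
class CQASpec:
    """Response metadata: threshold chain and criticality direction.

    Exactly one of ``usl_ds`` (drug-substance upper specification limit, to
    be propagated through ``clearances``) or ``threshold_direct`` (an
    intermediate-stage threshold given directly) must be supplied.
    ``direction="upper"`` means the response must stay below the threshold;
    ``"lower"`` is the mirrored case.
    """

    name: str
    usl_ds: float | None = None
    threshold_direct: float | None = None
    clearances: tuple[float, ...] = ()
    direction: str = "upper"

    def __post_init__(self) -> None:
        object.__setattr__(self, "clearances", tuple(self.clearances))
        if (self.usl_ds is None) == (self.threshold_direct is None):
            raise ThresholdError(
                f"CQA {self.name!r}: provide exactly one of usl_ds / "
                "threshold_direct"
            )
        if self.direction not in ("upper", "lower"):
            raise ThresholdError(f"direction must be 'upper' or 'lower'")
        if any(sc <= 0 for sc in self.clearances):
            raise ThresholdError(f"CQA {self.name!r}: clearances must be > 0")
        if self.usl_ds is not None and not self.clearances:
            raise ThresholdError(
                f"CQA {self.name!r}: usl_ds given but no clearance factors; "
                "supply the specific clearances of all downstream unit "
                "operations or use threshold_direct"
            )
        if self.threshold_direct is not None and self.clearances:
            raise ThresholdError(
                f"CQA {self.name!r}: clearances are only used with usl_ds"
            )

    @property
    def threshold(self) -> float:
        if self.threshold_direct is not None:
            return float(self.threshold_direct)
        return threshold_from_usl(self.usl_ds, self.clearances)


@dataclass(frozen=True)
class CriticalGap:
    """Distance from current performance to the threshold, in CQA units."""

    value: float
    basis: str  # "set_point" or "worst_case"

    def __post_init__(self) -> None:
        if self.basis not in ("set_point", "worst_case"):
            raise ThresholdError(f"unknown critical-gap basis {self.basis!r}")
        if not np.isfinite(self.value):
            raise ThresholdError("critical gap must be finite")


def specific_clearance(c_load: float, c_pool: float) -> float:
    """Specific clearance of a unit operation: SC = c_load / c_pool.

    Both arguments are specific concentrations (amount of CQA per amount of
    product) before and after the unit operation.
    """
    if c_pool <= 0:
        raise ThresholdError(f"pool concentration must be > 0, got {c_pool}")
    if c_load < 0:
        raise ThresholdError(f"load concentration must be >= 0, got {c_load}")
    return c_load / c_pool


def threshold_from_usl(usl_ds: float, clearances: Sequence[float]) -> float:
    """Intermediate-stage threshold: USL times the downstream clearances.

    ``clearances`` are the mean specific clearance factors of the unit
    operations between the studied stage and drug substance (inclusive).
    """
    clearances = tuple(clearances)
    if not clearances:
        raise ThresholdError(
            "usl_ds requires at least one downstream clearance factor"
        )
    if any(sc <= 0 for sc in clearances):
        raise ThresholdError("clearance factors must be > 0")
    return float(usl_ds) * float(np.prod(clearances))


def _signed_gap(threshold: float, current: float, direction: str) -> float:
    if direction == "upper":
        return float(threshold) - float(current)
    if direction == "lower":
        return float(current) - float(threshold)
    raise ThresholdError(f"direction must be 'upper' or 'lower', got {direction!r}")


def critical_gap_setpoint(
    threshold: float, y_sp_mean: float, direction: str = "upper"
) -> CriticalGap:
    """Critical gap before experiments: threshold minus set-point mean."""
    if not (np.isfinite(threshold) and np.isfinite(y_sp_mean)):
        raise ThresholdError("threshold and set-point mean must be finite")
    gap = _signed_gap(threshold, y_sp_mean, direction)
    if gap <= 0:
        raise ThresholdExceededError(
            f"set-point mean {y_sp_mean} is already at or beyond the "
            f"threshold {threshold} (direction={direction}); there is no gap "
            "to protect"
        )
    return CriticalGap(gap, basis="set_point")


def _model_coefficients(model, names: Sequence[str]):
    """Split a fitted model into main / quadratic / interaction coefficients."""
    mains = dict.fromkeys(names, 0.0)
    quads = dict.fromkeys(names, 0.0)
    inters: dict[tuple[str, str], float] = {}
    for term, coef in zip(model.terms, model.coefs):
        if term.kind == "main":
            mains[term.factors[0]] += float(coef)
        elif term.kind == "quadratic":
            quads[term.factors[0]] += float(coef)
        elif term.kind == "interaction":
            a, b = term.factors
            key = (a, b) if names.index(a) < names.index(b) else (b, a)
            inters[key] = inters.get(key, 0.0) + float(coef)
        else:  # pragma: no cover - guarded by ModelTerm
            raise ThresholdError(f"unknown term kind {term.kind!r}")
    return mains, quads, inters


def _line_max(b: float, q: float, lo: float, hi: float) -> tuple[float, float]:
    """Maximize b*x + q*x^2 over [lo, hi]; returns (x*, value)."""
    cands = [lo, hi]
    if q != 0.0:
        stat = -b / (2.0 * q)
        if lo < stat < hi:
            cands.append(stat)
    vals = [b * x + q * x * x for x in cands]
    i = int(np.argmax(vals))
    return cands[i], vals[i]


def worst_case_prediction(
    model, factors: Sequence[FactorSpec], direction: str = "upper"
) -> tuple[float, np.ndarray]:
    """Extreme model prediction over the NOR box.

    Returns the maximum prediction (``direction="upper"``) or minimum
    (``"lower"``) of the fitted response surface over the box
    ``prod_i [nor_low_i, nor_high_i]``, together with the coded point
    attaining it.  Additive models (main + pure quadratic terms) are solved
    coordinate-wise in closed form; models with interaction terms use exact
    coordinate ascent started from every box vertex and the box midpoint,
    which is deterministic and matches a dense-grid search for the small
    factor counts of screening designs.

    Coordinates the model does not use are reported at the NOR midpoint.
    """
    factors = tuple(factors)
    names = [f.name for f in factors]
    model_names = {n for t in model.terms for n in t.factors}
    unknown = model_names - set(names)
    if unknown:
        raise ThresholdError(f"model uses factors {sorted(unknown)} not in spec list")
    sign = 1.0 if direction == "upper" else -1.0
    if direction not in ("upper", "lower"):
        raise ThresholdError(f"direction must be 'upper' or 'lower'")
    mains, quads, inters = _model_coefficients(model, names)
    lo = np.array([f.nor_low for f in factors])
    hi = np.array([f.nor_high for f in factors])
    mid = (lo + hi) / 2.0

    if not inters:
        point = mid.copy()
        total = float(model.intercept) * sign
        for j, f in enumerate(factors):
            b, q = sign * mains[f.name], sign * quads[f.name]
            if b == 0.0 and q == 0.0:
                continue
            x, v = _line_max(b, q, lo[j], hi[j])
            point[j] = x
            total += v
        return sign * total, point

    # interaction terms couple coordinates: exact coordinate ascent from all
    # vertices (2^p starts, p <= 8) plus the midpoint
    b_vec = sign * np.array([mains[n] for n in names])
    q_vec = sign * np.array([quads[n] for n in names])
    imat = np.zeros((len(names), len(names)))
    for (a, b), coef in inters.items():
        ia, ib = names.index(a), names.index(b)
        imat[ia, ib] += sign * coef
        imat[ib, ia] += sign * coef

    def objective(x: np.ndarray) -> float:
        return float(b_vec @ x + q_vec @ (x * x) + 0.5 * x @ imat @ x)

    best_val, best_x = -np.inf, mid
    starts = [np.array(v) for v in itertools.product(*zip(lo, hi))] + [mid.copy()]
    for x in starts:
        x = x.astype(float).copy()
        for _ in range(100):
            moved = False
            for j in range(len(names)):
                slope = b_vec[j] + imat[j] @ x - imat[j, j] * x[j]
                xj, _ = _line_max(slope, q_vec[j], lo[j], hi[j])
                if xj != x[j]:
                    x[j] = xj
                    moved = True
            if not moved:
                break
        val = objective(x)
        if val > best_val + 1e-15:
            best_val, best_x = val, x
    # unused coordinates stay where the ascent left them; pin to midpoint
    used = {names.index(n) for n in model_names}
    point = np.array([best_x[j] if j in used else mid[j] for j in range(len(names))])
    return float(model.intercept) + sign * best_val, point


def critical_gap_worstcase(
    threshold: float,
    model,
    factors: Sequence[FactorSpec],
    direction: str = "upper",
) -> CriticalGap:
    """Critical gap after experiments: threshold minus the worst-case
    prediction of the selected model within the NOR box."""
    y_worst, _ = worst_case_prediction(model, factors, direction)
    gap = _signed_gap(threshold, y_worst, direction)
    if gap <= 0:
        raise ThresholdExceededError(
            f"worst-case model prediction {y_worst:.6g} already at or beyond "
            f"the threshold {threshold:.6g} (direction={direction})"
        )
    return CriticalGap(gap, basis="worst_case")


def critical_effect(w: float, cg: CriticalGap, factor: FactorSpec) -> float:
    """Critical effect of one factor: its weighted share of the gap per unit
    of its longest NOR excursion (CQA units per coded unit, magnitude only)."""
    if not 0.0 <= w <= 1.0:
        raise ThresholdError(f"weight must be in [0, 1], got {w}")
    if cg.value <= 0:
        raise ThresholdExceededError("critical gap must be > 0")
    d = factor.max_excursion
    if d <= 0:
        raise DegenerateNorError(
            f"factor {factor.name!r}: NOR collapsed onto the set point"
        )
    return w * cg.value / d


def cqas_from_json(source) -> tuple[CQASpec, ...]:
    """Parse CQA metadata from a JSON string, path, or parsed list.

    Schema per entry:
    ``{"name", "usl_ds" | "threshold_direct", "clearances": [...], "direction"}``.
    """
    if isinstance(source, (list, tuple)):
        items = source
    else:
        text = source
        if hasattr(source, "read"):
            text = source.read()
        elif isinstance(source, str) and not source.lstrip().startswith("["):
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        items = json.loads(text)
    out = []
    for d in items:
        d = dict(d)
        d["clearances"] = tuple(d.get("clearances", ()))
        out.append(CQASpec(**d))
    return tuple(out)
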