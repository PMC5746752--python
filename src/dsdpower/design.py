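"""Coded-unit screening designs and DoE dataset I/O.

Everything downstream of this module works in *coded units*: each factor's
screening range is mapped onto [-1, +1], and normal operating ranges (NORs)
are expressed on that same scale (a NOR bound may lie outside [-1, 1] when
the operating range exceeds the screened range).  Mapping physical units to
coded units is the caller's responsibility.

The design generator builds definitive screening designs (DSDs) from
conference-matrix fold-over: for ``m`` factors the design is ``[C; -C; 0]``
where ``C`` is an ``m x m`` matrix with zero diagonal and +/-1 off-diagonal
entries, so every non-center run has exactly one factor at its mid level and
the design contains the mirror image of every run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "UnsupportedSizeError",
    "FactorSpec",
    "DesignMatrix",
    "ResponseVector",
    "SetPointSample",
    "generate_dsd",
    "load_design",
    "write_design",
    "load_response",
    "write_response",
    "load_setpoint",
    "factors_from_json",
    "factors_to_json",
]


class DesignError(ValueError):
    """Invalid design, factor specification or DoE data file."""


class UnsupportedSizeError(DesignError):
    """Requested design size is outside the supported range."""


@dataclass(frozen=True)
class FactorSpec:
    """One DoE factor in coded units.

    Parameters
    ----------
    name
        Factor label; must match the design CSV column header.
    kind
        ``"numeric"`` (3-level, screened on [-1, +1]) or ``"categorical2"``
        (two levels coded -1/+1, treated numerically downstream, quadratic
        terms disallowed).
    set_point
        Nominal operating condition in coded units (default 0, the center).
    nor_low, nor_high
        Normal operating range bounds in coded units.  May exceed +/-1 when
        the NOR is wider than the screening range; must bracket the set
        point.
    """

    name: str
    kind: str = "numeric"
    set_point: float = 0.0
    nor_low: float = -1.0
    nor_high: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical2"):
            raise DesignError(f"unknown factor kind {self.kind!r}")
        if not np.isfinite([self.set_point, self.nor_low, self.nor_high]).all():
            raise DesignError(f"factor {self.name!r}: non-finite NOR/set point")
        if not self.nor_low < self.nor_high:
            raise DesignError(
                f"factor {self.name!r}: nor_low ({self.nor_low}) must be < "
                f"nor_high ({self.nor_high})"
            )
        if not self.nor_low <= self.set_point <= self.nor_high:
            raise DesignError(
                f"factor {self.name!r}: set point {self.set_point} outside "
                f"NOR [{self.nor_low}, {self.nor_high}]"
            )

    @property
    def max_excursion(self) -> float:
        """Longest distance from the set point to a NOR bound.

        This is the denominator of the per-factor critical effect: from a
        risk perspective the coefficient only needs to reach the threshold at
        the farthest admissible excursion.
        """
        return max(self.nor_high - self.set_point, self.set_point - self.nor_low)

    def shrink_nor(self, fraction: float) -> "FactorSpec":
        """Tighten the NOR symmetrically about the set point.

        Both distances from the set point to the bounds are scaled by
        ``1 - fraction``; ``fraction=0.5`` halves the operating range.
        """
        if not 0.0 <= fraction < 1.0:
            raise DesignError(f"shrink fraction must be in [0, 1), got {fraction}")
        keep = 1.0 - fraction
        return replace(
            self,
            nor_low=self.set_point - (self.set_point - self.nor_low) * keep,
            nor_high=self.set_point + (self.nor_high - self.set_point) * keep,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class DesignMatrix:
    """A coded DoE design: ``n`` runs of ``p`` factors, column order fixed."""

    factors: tuple[FactorSpec, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape[1] != len(self.factors):
            raise DesignError(
                f"design values have shape {vals.shape}; expected "
                f"(n, {len(self.factors)})"
            )
        if not np.isfinite(vals).all():
            raise DesignError("design contains non-finite levels")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate factor names in {names}")
        for j, f in enumerate(self.factors):
            col = vals[:, j]
            if f.kind == "categorical2":
                if not np.isin(col, (-1.0, 1.0)).all():
                    raise DesignError(
                        f"categorical factor {f.name!r} has levels outside "
                        "{-1, +1}"
                    )
            elif np.abs(col).max(initial=0.0) > 1.0 + 1e-12:
                raise DesignError(
                    f"numeric factor {f.name!r} has screening levels outside "
                    "[-1, +1]"
                )

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_factors(self) -> int:
        return self.values.shape[1]

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.factor_names.index(name)
        except ValueError:
            raise DesignError(f"no factor named {name!r} in design") from None
        return self.values[:, j]

    def with_factors(self, factors: Sequence[FactorSpec]) -> "DesignMatrix":
        """Same runs, new factor metadata (e.g. tightened NORs)."""
        if tuple(f.name for f in factors) != self.factor_names:
            raise DesignError("replacement factors must match names and order")
        return DesignMatrix(tuple(factors), self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.factor_names))


@dataclass(frozen=True)
class ResponseVector:
    """One CQA response measured over the runs of a design."""

    cqa_name: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", vals)
        if vals.size == 0 or not np.isfinite(vals).all():
            raise DesignError(
                f"response {self.cqa_name!r} must be non-empty and finite"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SetPointSample:
    """Replicate responses measured at set-point conditions.

    Provides the pre-experiment noise estimate sigma_SP used by the a priori
    power analysis; at least two replicates are needed for a standard
    deviation.
    """

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", vals)
        if vals.size < 2:
            raise DesignError(
                "at least 2 set-point replicates required to estimate sigma_SP"
            )
        if not np.isfinite(vals).all():
            raise DesignError("set-point replicates must be finite")
        if np.std(vals, ddof=1) <= 0:
            raise DesignError("set-point replicates are constant; sigma_SP = 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


# --------------------------------------------------------------------------
# definitive screening designs
# --------------------------------------------------------------------------

def _quadratic_character(q: int):
    residues = {(i * i) % q for i in range(1, q)}

    def chi(a: int) -> int:
        a %= q
        if a == 0:
            return 0
        return 1 if a in residues else -1

    return chi


def _conference_matrix(order: int) -> np.ndarray:
    """Paley conference matrix of the given (even) order.

    Orders 4 and 8 use the skew Paley construction (q = order-1 = 3 mod 4),
    order 6 the symmetric one (q = 1 mod 4).  The defining property
    C'C = (order-1) I is asserted.
    """
    q = order - 1
    chi = _quadratic_character(q)
    core = np.array([[chi(i - j) for j in range(q)] for i in range(q)], dtype=float)
    c = np.zeros((order, order))
    c[0, 1:] = 1.0
    c[1:, 1:] = core
    c[1:, 0] = -1.0 if q % 4 == 3 else 1.0
    if not np.array_equal(c.T @ c, (order - 1) * np.eye(order)):
        raise AssertionError(f"conference matrix construction failed, order {order}")
    return c


_SUPPORTED_M = range(4, 9)


def generate_dsd(
    m: int,
    extra_center_runs: int = 0,
    factors: Sequence[FactorSpec] | None = None,
) -> DesignMatrix:
    """Generate a definitive screening design for ``m`` numeric factors.

    Even ``m``: the conference-matrix fold-over ``[C; -C; 0]`` with
    ``2m + 1`` runs — ``m`` fold-over run pairs, each with one factor at its
    mid level, plus one all-center run.  Odd ``m``: the ``(m+1)``-factor
    design with one column dropped (the standard construction; an odd-order
    conference matrix does not exist, and removing the dropped column's run
    pair as well would leave a singular main-effect matrix), giving
    ``2m + 3`` runs of which one fold-over pair has no mid-level entry.
    Main-effect columns are exactly orthogonal for every supported ``m``,
    and the design contains the mirror image of every run.

    Parameters
    ----------
    m
        Number of factors, 4..8.
    extra_center_runs
        Additional replicated center runs appended after the design.
    factors
        Optional factor metadata; defaults to ``x1..xm`` with set point 0
        and NOR [-1, 1].
    """
    if m not in _SUPPORTED_M:
        raise UnsupportedSizeError(
            f"definitive screening design supported for m in "
            f"[{_SUPPORTED_M.start}, {_SUPPORTED_M.stop - 1}]; got m={m}"
        )
    if extra_center_runs < 0:
        raise DesignError("extra_center_runs must be >= 0")
    order = m if m % 2 == 0 else m + 1
    c = _conference_matrix(order)
    if m % 2 == 1:
        c = np.delete(c, order - 1, axis=1)  # drop one column, keep all runs
    half = np.vstack([c, -c])
    values = np.vstack([half, np.zeros((1 + extra_center_runs, m))])
    if factors is None:
        factors = tuple(FactorSpec(f"x{i + 1}") for i in range(m))
    else:
        factors = tuple(factors)
        if len(factors) != m:
            raise DesignError(f"{len(factors)} factor specs given for m={m}")
    return DesignMatrix(factors, values)


# --------------------------------------------------------------------------
# CSV / JSON IO
# --------------------------------------------------------------------------
# Dialect: comma-separated, header row, period decimal separator, UTF-8.
# Design file: one column per factor.  Response file: `run_id` + one column
# per CQA.  Factor metadata: JSON list of FactorSpec dicts.

def write_design(design: DesignMatrix, path) -> None:
    design.to_frame().to_csv(path, index=False)


def load_design(path, factor_specs: Sequence[FactorSpec]) -> DesignMatrix:
    """Load a design CSV, aligning columns to ``factor_specs`` by name."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [f.name for f in factor_specs if f.name not in df.columns]
    if missing:
        raise DesignError(f"design file {path} missing factor columns {missing}")
    cols = df[[f.name for f in factor_specs]]
    try:
        values = cols.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DesignError(f"non-numeric cell in design file {path}: {exc}") from exc
    return DesignMatrix(tuple(factor_specs), values)


def write_response(response: ResponseVector, path) -> None:
    pd.DataFrame(
        {"run_id": np.arange(1, len(response) + 1), response.cqa_name: response.values}
    ).to_csv(path, index=False)


def load_response(
    path, cqa_name: str | None = None, expected_runs: int | None = None
) -> ResponseVector:
    """Load one CQA column from a response CSV (``run_id`` + CQA columns)."""
    df = pd.read_csv(path, float_precision="round_trip")
    data_cols = [c for c in df.columns if c != "run_id"]
    if cqa_name is None:
        if len(data_cols) != 1:
            raise DesignError(
                f"response file {path} has columns {data_cols}; specify cqa_name"
            )
        cqa_name = data_cols[0]
    if cqa_name not in df.columns:
        raise DesignError(f"response file {path} has no column {cqa_name!r}")
    try:
        values = df[cqa_name].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DesignError(f"non-numeric cell in {path}:{cqa_name}: {exc}") from exc
    if expected_runs is not None and len(values) != expected_runs:
        raise DesignError(
            f"response {cqa_name!r} has {len(values)} rows but the design has "
            f"{expected_runs} runs"
        )
    return ResponseVector(cqa_name, values)


def load_setpoint(path, cqa_name: str | None = None) -> SetPointSample:
    """Load set-point replicate responses (one column per CQA)."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c for c in df.columns if c != "run_id"]
    if cqa_name is None:
        if len(cols) != 1:
            raise DesignError(
                f"set-point file {path} has columns {cols}; specify cqa_name"
            )
        cqa_name = cols[0]
    if cqa_name not in df.columns:
        raise DesignError(f"set-point file {path} has no column {cqa_name!r}")
    return SetPointSample(df[cqa_name].to_numpy(dtype=float))


def factors_to_json(factors: Iterable[FactorSpec], path=None) -> str:
    payload = json.dumps([f.to_dict() for f in factors], indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(payload + "\n")
    return payload


def _factor_from_dict(d: Mapping) -> FactorSpec:
    known = {f.name for f in dataclasses.fields(FactorSpec)}
    extra = set(d) - known
    if extra:
        raise DesignError(f"unknown factor metadata keys {sorted(extra)}")
    return FactorSpec(**d)


def factors_from_json(source) -> tuple[FactorSpec, ...]:
    """Parse factor metadata from a JSON string, path, or parsed list."""
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
    return tuple(_factor_from_dict(d) for d in items)
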