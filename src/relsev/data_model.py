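"""Typed containers for longitudinal welfare-readout cohorts.

The canonical on-disk layout is a tidy long table — one row per (animal, day,
variable) measurement — with animal id, model, subgroup, day, variable and
value columns.  A wide per-variable layout (one column per readout) is
accepted on input and melted to long form.

Continuous readouts (body weight, burrowing activity) are expressed as
percent of each animal's own baseline (day −1 by default) via
:func:`standardize_to_baseline`; ordinal scores (nesting quality 1–6,
clinical distress score) stay on their native scale, because a ratio to a
zero-valued healthy baseline is meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BaselineError, IntegrityError, SchemaError

__all__ = [
    "VariableSpec",
    "AnimalSeries",
    "Cohort",
    "ValidationFinding",
    "DEFAULT_SCHEMA",
    "load_cohort",
    "write_cohort",
    "cohort_to_frame",
    "standardize_to_baseline",
    "standardize_cohort",
    "validate_cohort",
]

#: default column-name mapping for the tidy long layout
DEFAULT_SCHEMA: dict[str, str] = {
    "animal": "animal",
    "model": "model",
    "subgroup": "subgroup",
    "day": "day",
    "variable": "variable",
    "value": "value",
}


@dataclass(frozen=True)
class VariableSpec:
    """Semantics of one welfare readout.

    Parameters
    ----------
    name
        Variable identifier used in tables and reference sets.
    adverse_direction
        ``"down"`` if distress lowers the value (body weight, burrowing,
        nesting), ``"up"`` if distress raises it (distress score).
    scale
        ``"percent_of_baseline"`` for continuous readouts standardized to
        100% at baseline, ``"native_ordinal"`` for integer scores.
    valid_range
        Closed interval of admissible values (after standardization for
        percent variables).
    max_score
        Upper bound of an ordinal scale; required for ordinal variables.
    """

    name: str
    adverse_direction: str
    scale: str
    valid_range: tuple[float, float]
    max_score: int | None = None

    def __post_init__(self) -> None:
        if self.adverse_direction not in ("down", "up"):
            raise ValueError(f"adverse_direction must be 'down' or 'up', got {self.adverse_direction!r}")
        if self.scale not in ("percent_of_baseline", "native_ordinal"):
            raise ValueError(f"unknown scale {self.scale!r}")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must be a non-empty interval")
        if self.scale == "native_ordinal" and self.max_score is None:
            raise ValueError("ordinal variables require max_score")

    @property
    def is_percent(self) -> bool:
        return self.scale == "percent_of_baseline"

    def healthy_baseline(self) -> float:
        """Default baseline: 100 for percent scales, the benign bound of an
        ordinal scale (upper bound if distress lowers the score, lower bound
        otherwise)."""
        if self.is_percent:
            return 100.0
        lo, hi = self.valid_range
        return hi if self.adverse_direction == "down" else lo


@dataclass
class AnimalSeries:
    """One animal's per-day readouts.

    ``values`` maps variable name to a float array aligned with ``days``;
    missing measurements are ``nan``.
    """

    animal_id: str
    model: str
    subgroup: str
    days: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        if np.any(np.diff(self.days) <= 0):
            raise IntegrityError(f"animal {self.animal_id}: days must be strictly increasing")
        for var, arr in list(self.values.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.days.shape:
                raise IntegrityError(
                    f"animal {self.animal_id}: variable {var!r} has {arr.size} values for {self.days.size} days"
                )
            self.values[var] = arr

    def value_at(self, variable: str, day: int) -> float:
        """Measured value of ``variable`` on ``day``; ``nan`` if absent."""
        idx = np.flatnonzero(self.days == day)
        if idx.size == 0 or variable not in self.values:
            return math.nan
        return float(self.values[variable][idx[0]])

    def variables(self) -> list[str]:
        return list(self.values)


@dataclass
class Cohort:
    """A collection of animals with shared variable specifications."""

    animals: list[AnimalSeries]
    specs: dict[str, VariableSpec]
    provenance: str = ""
    baseline_day: int = -1

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a in self.animals:
            if a.animal_id in seen:
                raise IntegrityError(f"duplicate animal_id {a.animal_id!r} in cohort")
            seen.add(a.animal_id)
            undeclared = set(a.values) - set(self.specs)
            if undeclared:
                raise IntegrityError(
                    f"animal {a.animal_id} carries undeclared variables {sorted(undeclared)}"
                )

    def __len__(self) -> int:
        return len(self.animals)

    def variables(self) -> list[str]:
        return list(self.specs)

    def subgroups(self) -> list[str]:
        out: list[str] = []
        for a in self.animals:
            if a.subgroup not in out:
                out.append(a.subgroup)
        return out

    def subset(self, subgroup: str) -> "Cohort":
        kept = [a for a in self.animals if a.subgroup == subgroup]
        return Cohort(kept, self.specs, self.provenance, self.baseline_day)


# ---------------------------------------------------------------------------
# IO


def _resolve_schema(columns: Iterable[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    cols = set(columns)
    # variable/value may be absent in the wide layout
    missing = [k for k, v in mapping.items() if k not in ("variable", "value") and v not in cols]
    if missing:
        raise SchemaError(
            f"cannot resolve required columns {missing} (mapping {mapping}) in table columns {sorted(cols)}"
        )
    return mapping


def load_cohort(
    path,
    specs: Mapping[str, VariableSpec],
    schema: Mapping[str, str] | None = None,
    provenance: str = "",
    baseline_day: int = -1,
) -> Cohort:
    """Read a cohort from a delimited text table.

    Accepts the canonical long layout (``variable``/``value`` columns) or a
    wide layout whose extra columns are variable names; the wide form is
    melted to long before validation.  Unparseable numeric values raise
    :class:`IntegrityError` naming the offending rows; duplicated
    (animal, day, variable) cells are an integrity error.
    """
    df = pd.read_csv(path)
    mapping = _resolve_schema(df.columns, schema)
    id_cols = [mapping["animal"], mapping["model"], mapping["subgroup"], mapping["day"]]
    if mapping["variable"] in df.columns and mapping["value"] in df.columns:
        long = df.rename(
            columns={v: k for k, v in mapping.items()}
        )[["animal", "model", "subgroup", "day", "variable", "value"]]
    else:
        var_cols = [c for c in df.columns if c not in id_cols]
        known = [c for c in var_cols if c in specs]
        if not known:
            raise SchemaError(
                f"no variable/value columns and no columns matching declared variables {sorted(specs)}"
            )
        long = df.melt(id_vars=id_cols, value_vars=known, var_name="variable", value_name="value")
        long = long.rename(columns={mapping[k]: k for k in ("animal", "model", "subgroup", "day")})

    unknown_vars = set(long["variable"].unique()) - set(specs)
    if unknown_vars:
        raise SchemaError(f"table contains undeclared variables {sorted(unknown_vars)}")

    values = pd.to_numeric(long["value"], errors="coerce")
    raw_na = long["value"].isna() | long["value"].astype(str).str.strip().str.upper().isin(
        ["NA", "NAN", ""]
    )
    bad = ~raw_na & values.isna()
    if bad.any():
        rows = long.loc[bad].head(5).to_dict("records")
        raise IntegrityError(f"{int(bad.sum())} unparseable value(s); first offenders: {rows}")
    long = long.assign(value=values)

    dup = long.duplicated(subset=["animal", "day", "variable"], keep=False)
    if dup.any():
        first = long.loc[dup, ["animal", "day", "variable"]].iloc[0].to_dict()
        raise IntegrityError(f"duplicate (animal, day, variable) measurement, e.g. {first}")

    animals: list[AnimalSeries] = []
    for animal_id, adf in long.groupby("animal", sort=False):
        days = np.array(sorted(adf["day"].unique()), dtype=int)
        model = str(adf["model"].iloc[0])
        subgroup = str(adf["subgroup"].iloc[0])
        vals: dict[str, np.ndarray] = {}
        for var, vdf in adf.groupby("variable", sort=False):
            arr = np.full(days.size, np.nan)
            pos = np.searchsorted(days, vdf["day"].to_numpy(dtype=int))
            arr[pos] = vdf["value"].to_numpy(dtype=float)
            vals[str(var)] = arr
        animals.append(AnimalSeries(str(animal_id), model, subgroup, days, vals))
    return Cohort(animals, dict(specs), provenance=provenance, baseline_day=baseline_day)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-form DataFrame of all non-missing measurements."""
    rows = []
    for a in cohort.animals:
        for var, arr in a.values.items():
            for d, v in zip(a.days, arr):
                if not math.isnan(v):
                    rows.append((a.animal_id, a.model, a.subgroup, int(d), var, float(v)))
    return pd.DataFrame(rows, columns=["animal", "model", "subgroup", "day", "variable", "value"])


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical long CSV layout."""
    cohort_to_frame(cohort).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Standardization


def standardize_to_baseline(
    series: AnimalSeries, variable: str, baseline_day: int = -1
) -> AnimalSeries:
    """Rescale one percent-of-baseline variable to 100% at ``baseline_day``.

    value(day) → 100 · value(day) / value(baseline_day).  Idempotent once the
    baseline is exactly 100, and invariant to the raw measurement unit.
    """
    if variable not in series.values:
        raise BaselineError(f"animal {series.animal_id}: variable {variable!r} not measured")
    base = series.value_at(variable, baseline_day)
    if math.isnan(base):
        raise BaselineError(
            f"animal {series.animal_id}: no baseline (day {baseline_day}) value for {variable!r}"
        )
    if base == 0:
        raise BaselineError(f"animal {series.animal_id}: zero baseline for {variable!r}")
    new_values = dict(series.values)
    new_values[variable] = 100.0 * series.values[variable] / base
    return replace(series, values=new_values)


def standardize_cohort(cohort: Cohort) -> Cohort:
    """Standardize every percent-of-baseline variable of every animal."""
    out = []
    for a in cohort.animals:
        for var, spec in cohort.specs.items():
            if spec.is_percent and var in a.values:
                a = standardize_to_baseline(a, var, cohort.baseline_day)
        out.append(a)
    return Cohort(out, cohort.specs, cohort.provenance, cohort.baseline_day)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationFinding:
    animal_id: str
    variable: str
    kind: str  # range | missing_baseline | non_integer
    detail: str


def validate_cohort(cohort: Cohort) -> list[ValidationFinding]:
    """Check every animal/variable against its spec; empty list iff clean.

    Reported findings: values outside ``valid_range``, percent variables with
    no baseline-day measurement, non-integer ordinal values.
    """
    findings: list[ValidationFinding] = []
    for a in cohort.animals:
        for var, arr in a.values.items():
            spec = cohort.specs[var]
            lo, hi = spec.valid_range
            finite = arr[~np.isnan(arr)]
            n_out = int(np.sum((finite < lo) | (finite > hi)))
            if n_out:
                findings.append(
                    ValidationFinding(a.animal_id, var, "range", f"{n_out} value(s) outside [{lo}, {hi}]")
                )
            if spec.is_percent and math.isnan(a.value_at(var, cohort.baseline_day)):
                findings.append(
                    ValidationFinding(
                        a.animal_id, var, "missing_baseline", f"no day {cohort.baseline_day} value"
                    )
                )
            if spec.scale == "native_ordinal":
                n_frac = int(np.sum(finite != np.round(finite)))
                if n_frac:
                    findings.append(
                        ValidationFinding(a.animal_id, var, "non_integer", f"{n_frac} non-integer value(s)")
                    )
    return findings
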