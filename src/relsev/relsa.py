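"""Reference-scaled composite severity scoring (RELSA).

The score maps an animal's multivariate adverse deviations from baseline onto
a scale on which 1 equals the maximal adverse deviation pattern of a defined
reference experiment (here a transmitter-implantation cohort of established
moderate severity).  For each observation day t and variable v,

    w_v(t) = delta_v(t) / delta_ref_v

where delta_v(t) is the adverse deviation from baseline (clipped at zero in
the beneficial direction) and delta_ref_v is the reference cohort's maximal
adverse deviation for v.  The per-day composite is the root-mean-square of
the available weights,

    RELSA(t) = sqrt( sum_v w_v(t)^2 / n_used(t) ),

which emphasises large deviations over small ones, equals 1 whenever every
available variable sits exactly at its reference extreme, and is free to
exceed 1 for animals worse than the reference.  The per-animal summary
RELSA_max is the maximum of the curve; values above 1 flag animals that
experienced more severe distress than the reference model.

Missing measurements shrink n_used rather than being imputed: absence of a
measurement is not absence of distress.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .data_model import AnimalSeries, Cohort, VariableSpec, standardize_cohort
from .errors import (
    DegenerateReferenceError,
    EmptyCurveError,
    IncompatibleReferenceError,
)

__all__ = [
    "ReferenceSet",
    "RelsaCurve",
    "RelsaMax",
    "adverse_deviation",
    "build_reference",
    "relsa_timeseries",
    "relsa_max",
    "score_cohort",
    "rms_combiner",
]


def adverse_deviation(value: float, baseline: float, spec: VariableSpec) -> float:
    """Deviation from baseline in the adverse direction, clipped at zero.

    ``nan`` values propagate as ``nan`` (missing deviation, not an error).
    Beneficial deviations (weight gain, above-baseline burrowing) clip to 0
    so that improvement on one readout cannot mask distress on another.
    """
    if math.isnan(value):
        return math.nan
    if spec.adverse_direction == "down":
        return max(0.0, baseline - value)
    return max(0.0, value - baseline)


@dataclass(frozen=True)
class ReferenceSet:
    """Per-variable maximal adverse deviations of a reference cohort.

    ``extremes`` maps variable name to delta_ref_v > 0 (percentage points for
    percent variables, native units for ordinal ones); ``mode`` records the
    aggregation that produced them; ``source`` is a provenance label.
    """

    extremes: dict[str, float]
    mode: str
    source: str = ""

    def __post_init__(self) -> None:
        for var, d in self.extremes.items():
            if not d > 0:
                raise DegenerateReferenceError(f"reference extreme for {var!r} is {d}; must be > 0")

    def variables(self) -> list[str]:
        return list(self.extremes)

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {"extremes": self.extremes, "mode": self.mode, "source": self.source}, indent=2
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, path_or_text) -> "ReferenceSet":
        try:
            doc = json.loads(path_or_text)
        except (json.JSONDecodeError, TypeError):
            with open(path_or_text) as fh:
                doc = json.load(fh)
        return cls(dict(doc["extremes"]), doc["mode"], doc.get("source", ""))


def build_reference(
    reference_cohort: Cohort,
    variables: Sequence[str] | None = None,
    mode: str = "cohort_median_extreme",
    standardize: bool = True,
) -> ReferenceSet:
    """Derive the scaling denominators delta_ref_v from a reference cohort.

    Parameters
    ----------
    mode
        ``"cohort_median_extreme"`` (default): per post-baseline day take the
        cohort median of each variable, then the maximal adverse deviation of
        that median trajectory — robust to single outlier animals.
        ``"per_animal_extreme"``: the maximum over animals of each animal's
        own maximal adverse deviation — a sensitivity-analysis alternative.
    standardize
        Standardize percent variables to baseline first (skip only if the
        cohort is already on the percent scale).

    A variable whose reference deviation is zero everywhere would make the
    scale degenerate and raises :class:`DegenerateReferenceError`.
    """
    if mode not in ("cohort_median_extreme", "per_animal_extreme"):
        raise ValueError(f"unknown reference mode {mode!r}")
    cohort = standardize_cohort(reference_cohort) if standardize else reference_cohort
    if variables is None:
        variables = cohort.variables()
    extremes: dict[str, float] = {}
    for var in variables:
        spec = cohort.specs[var]
        baseline = spec.healthy_baseline()
        per_animal_max: list[float] = []
        day_values: dict[int, list[float]] = {}
        measured = False
        for a in cohort.animals:
            if var not in a.values:
                continue
            devs = []
            for d, v in zip(a.days, a.values[var]):
                if d <= cohort.baseline_day or math.isnan(v):
                    continue
                measured = True
                day_values.setdefault(int(d), []).append(float(v))
                devs.append(adverse_deviation(v, baseline, spec))
            if devs:
                per_animal_max.append(max(devs))
        if not measured:
            raise DegenerateReferenceError(
                f"variable {var!r} has no post-baseline measurement in the reference cohort"
            )
        if mode == "cohort_median_extreme":
            delta = max(
                adverse_deviation(float(np.median(vals)), baseline, spec)
                for vals in day_values.values()
            )
        else:
            delta = max(per_animal_max)
        if not delta > 0:
            raise DegenerateReferenceError(
                f"variable {var!r} shows no adverse deviation in the reference cohort"
            )
        extremes[var] = float(delta)
    return ReferenceSet(extremes, mode, source=cohort.provenance)


def rms_combiner(weights: np.ndarray) -> float:
    """Root-mean-square of the available per-variable weights."""
    return float(np.sqrt(np.mean(np.square(weights))))


@dataclass
class RelsaCurve:
    """Per-day composite severity for one animal.

    ``relsa`` is ``nan`` on days where no variable was measured; ``weights``
    holds the per-variable scaled deviations (nan where missing); ``n_used``
    counts contributing variables per day.
    """

    animal_id: str
    days: np.ndarray
    relsa: np.ndarray
    weights: dict[str, np.ndarray]
    n_used: np.ndarray


@dataclass(frozen=True)
class RelsaMax:
    """Maximal composite severity of one animal and the earliest day it
    occurred."""

    animal_id: str
    value: float
    day_achieved: int


def relsa_timeseries(
    animal: AnimalSeries,
    reference: ReferenceSet,
    specs: Mapping[str, VariableSpec],
    variables: Sequence[str] | None = None,
    baseline_day: int = -1,
    combiner: Callable[[np.ndarray], float] = rms_combiner,
) -> RelsaCurve:
    """Map one animal's deviations onto the reference scale, day by day.

    ``variables`` must intersect the reference set; percent variables are
    expected already standardized (weights are deviation / reference extreme).
    Baseline and pre-intervention days are scored like any other day — a
    healthy day simply scores 0.
    """
    if variables is None:
        variables = [v for v in animal.variables() if v in reference.extremes]
    used = [v for v in variables if v in reference.extremes and v in animal.values]
    if not used:
        raise IncompatibleReferenceError(
            f"animal {animal.animal_id}: no overlap between requested variables "
            f"{list(variables)} and reference variables {reference.variables()}"
        )
    n_days = animal.days.size
    weights = {v: np.full(n_days, np.nan) for v in used}
    relsa = np.full(n_days, np.nan)
    n_used = np.zeros(n_days, dtype=int)
    for i in range(n_days):
        ws = []
        for v in used:
            spec = specs[v]
            dev = adverse_deviation(float(animal.values[v][i]), spec.healthy_baseline(), spec)
            if not math.isnan(dev):
                w = dev / reference.extremes[v]
                weights[v][i] = w
                ws.append(w)
        n_used[i] = len(ws)
        if ws:
            relsa[i] = combiner(np.asarray(ws))
    return RelsaCurve(animal.animal_id, animal.days.copy(), relsa, weights, n_used)


def relsa_max(curve: RelsaCurve) -> RelsaMax:
    """Maximum of the curve; ties break to the earliest day."""
    ok = ~np.isnan(curve.relsa)
    if not ok.any():
        raise EmptyCurveError(f"animal {curve.animal_id}: all days missing")
    vals = curve.relsa[ok]
    days = curve.days[ok]
    best = float(np.max(vals))
    day = int(days[np.flatnonzero(vals == best)[0]])
    return RelsaMax(curve.animal_id, best, day)


def score_cohort(
    cohort: Cohort,
    reference: ReferenceSet,
    variables: Sequence[str] | None = None,
    standardize: bool = True,
):
    """Per-animal RELSA_max for a whole cohort.

    Returns a pandas DataFrame with columns animal, model, subgroup,
    relsa_max, day_achieved.
    """
    import pandas as pd

    scored = standardize_cohort(cohort) if standardize else cohort
    rows = []
    for a in scored.animals:
        curve = relsa_timeseries(a, reference, scored.specs, variables, scored.baseline_day)
        rm = relsa_max(curve)
        rows.append((a.animal_id, a.model, a.subgroup, rm.value, rm.day_achieved))
    return pd.DataFrame(rows, columns=["animal", "model", "subgroup", "relsa_max", "day_achieved"])
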