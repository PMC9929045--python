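"""Orchestration of the three severity analyses.

* :func:`run_within_model` — per-subgroup composite-severity estimates inside
  one disease model, each compared against the reference line at 1.0, plus a
  branch-selected omnibus test and Holm-adjusted pairwise comparisons.
* :func:`run_between_models` — pooled per-model estimates, severity ordering
  with equivalence marks, omnibus and pairwise tests; swapping the reference
  set (e.g. a 3-variable laboratory-A yardstick for a 2-variable
  laboratory-B one) is an input change only.
* :func:`run_single_readout` — per-day bootstrapped medians of one raw
  readout, per-day between-subgroup tests, and time-dependent tests where
  complete blocks exist.

Reports are plain dataclasses with ``to_dict`` for JSON export and carry the
provenance needed to reproduce them (seed, B, branch decisions, reference
mode and variables, Holm family definitions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Cohort, standardize_cohort
from .errors import IncompatibleReferenceError, SampleSizeError
from .relsa import ReferenceSet, score_cohort
from .stats import (
    BootstrapEstimate,
    TestResult,
    bootstrap_median,
    choose_branch,
    friedman_test,
    kruskal_wallis,
    pairwise_t,
    pairwise_wmw,
    parametric_branch,
)

__all__ = [
    "DEFAULT_RELSA_VARIABLES",
    "WithinModelReport",
    "BetweenModelReport",
    "SingleReadoutReport",
    "run_within_model",
    "run_between_models",
    "run_single_readout",
]

#: composite-score inputs used by default: body weight, burrowing activity and
#: the distress score; nesting stays a single-readout variable.
DEFAULT_RELSA_VARIABLES: tuple[str, ...] = ("body_weight", "burrowing", "distress_score")

REFERENCE_LINE = 1.0


def _spawn_seeds(seed: int, k: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=k)]


def _verdict(est: BootstrapEstimate, line: float = REFERENCE_LINE) -> str:
    if est.ci_high < line:
        return "below"
    if est.ci_low > line:
        return "above"
    return "straddling"


def _relsa_variables(
    cohort: Cohort, reference: ReferenceSet, variables: Sequence[str] | None
) -> list[str]:
    wanted = list(variables) if variables is not None else [
        v for v in DEFAULT_RELSA_VARIABLES if v in cohort.specs
    ]
    shared = [v for v in wanted if v in reference.extremes and v in cohort.specs]
    if not shared:
        raise IncompatibleReferenceError(
            f"no shared variables between cohort {cohort.variables()} and "
            f"reference {reference.variables()}"
        )
    return shared


def _estimates_to_dict(estimates: Mapping[str, BootstrapEstimate]) -> dict:
    return {k: v.to_dict() for k, v in estimates.items()}


@dataclass
class WithinModelReport:
    model: str
    estimates: dict[str, BootstrapEstimate]
    verdicts: dict[str, str]
    branch: str
    normality: list[TestResult]
    omnibus: TestResult | None
    pairwise: list[TestResult]
    variables: list[str]
    reference_line: float = REFERENCE_LINE
    reference_source: str = ""
    seed: int = 0
    B: int = 10_000
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "analysis": "within_model",
            "model": self.model,
            "variables": self.variables,
            "reference_line": self.reference_line,
            "reference_source": self.reference_source,
            "seed": self.seed,
            "B": self.B,
            "branch": self.branch,
            "estimates": _estimates_to_dict(self.estimates),
            "verdicts": self.verdicts,
            "normality": [r.to_dict() for r in self.normality],
            "omnibus": self.omnibus.to_dict() if self.omnibus else None,
            "pairwise": [r.to_dict() for r in self.pairwise],
            "holm_family": "all subgroup pairs within this model",
            "notes": self.notes,
        }


def run_within_model(
    cohort: Cohort,
    reference: ReferenceSet,
    variables: Sequence[str] | None = None,
    B: int = 10_000,
    conf: float = 0.95,
    seed: int = 0,
    alpha: float = 0.05,
) -> WithinModelReport:
    """Subgroup-level severity robustness analysis for one disease model.

    Per-animal maxima of the composite score are grouped by subgroup; each
    subgroup median is bootstrapped and compared against the reference line
    at 1.0 (CI entirely below / straddling / entirely above).  With >= 2
    subgroups, a normality branch selects Kruskal–Wallis plus pairwise
    Wilcoxon–Mann–Whitney (Holm family: all subgroup pairs) or one-way ANOVA
    plus pairwise Welch t tests.
    """
    shared = _relsa_variables(cohort, reference, variables)
    scores = score_cohort(cohort, reference, shared)
    groups = {
        sg: scores.loc[scores["subgroup"] == sg, "relsa_max"].to_numpy()
        for sg in cohort.subgroups()
    }
    seeds = _spawn_seeds(seed, len(groups))
    estimates = {
        sg: bootstrap_median(vals, B=B, conf=conf, seed=s)
        for (sg, vals), s in zip(groups.items(), seeds)
    }
    verdicts = {sg: _verdict(est) for sg, est in estimates.items()}
    notes: list[str] = []
    if len(groups) < 2:
        return WithinModelReport(
            model=cohort.animals[0].model if cohort.animals else "",
            estimates=estimates, verdicts=verdicts, branch="none",
            normality=[], omnibus=None, pairwise=[], variables=shared,
            reference_source=reference.source, seed=seed, B=B,
            notes=["single subgroup: omnibus and pairwise tests skipped"],
        )
    branch, normality = choose_branch(groups, alpha=alpha)
    if branch == "nonparametric":
        omnibus = kruskal_wallis(groups)
        pairwise = pairwise_wmw(groups)
    else:
        omnibus = parametric_branch(groups, design="between")[0]
        pairwise = pairwise_t(groups)
    return WithinModelReport(
        model=cohort.animals[0].model if cohort.animals else "",
        estimates=estimates, verdicts=verdicts, branch=branch,
        normality=normality, omnibus=omnibus, pairwise=pairwise,
        variables=shared, reference_source=reference.source, seed=seed, B=B,
        notes=notes,
    )


@dataclass
class BetweenModelReport:
    estimates: dict[str, BootstrapEstimate]
    ordering: list[str]
    equivalent_pairs: list[tuple[str, str]]
    ordering_label: str
    branch: str
    normality: list[TestResult]
    omnibus: TestResult | None
    pairwise: list[TestResult]
    variables: list[str]
    reference_source: str = ""
    reference_mode: str = ""
    seed: int = 0
    B: int = 10_000
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "analysis": "between_models",
            "variables": self.variables,
            "reference_source": self.reference_source,
            "reference_mode": self.reference_mode,
            "seed": self.seed,
            "B": self.B,
            "branch": self.branch,
            "estimates": _estimates_to_dict(self.estimates),
            "ordering": self.ordering,
            "equivalent_pairs": [list(p) for p in self.equivalent_pairs],
            "ordering_label": self.ordering_label,
            "normality": [r.to_dict() for r in self.normality],
            "omnibus": self.omnibus.to_dict() if self.omnibus else None,
            "pairwise": [r.to_dict() for r in self.pairwise],
            "holm_family": "all model pairs",
            "notes": self.notes,
        }


def run_between_models(
    cohorts: Mapping[str, Cohort],
    reference: ReferenceSet,
    variables: Sequence[str] | None = None,
    B: int = 10_000,
    conf: float = 0.95,
    seed: int = 0,
    alpha: float = 0.05,
) -> BetweenModelReport:
    """Pooled severity ranking across disease models.

    Subgroups are pooled within each model (the per-animal maxima already
    ignore subgroup structure, so pre-pooled input gives identical results).
    Models are ordered by bootstrapped median; two models adjacent in the
    ordering are marked equivalent (~) iff their Holm-adjusted pairwise
    p-value exceeds alpha.
    """
    if len(cohorts) < 2:
        raise SampleSizeError("run_between_models needs >= 2 model cohorts")
    groups: dict[str, np.ndarray] = {}
    shared: list[str] | None = None
    for name, cohort in cohorts.items():
        sh = _relsa_variables(cohort, reference, variables)
        shared = sh if shared is None else [v for v in shared if v in sh]
        scores = score_cohort(cohort, reference, sh)
        groups[name] = scores["relsa_max"].to_numpy()
    assert shared
    seeds = _spawn_seeds(seed, len(groups))
    estimates = {
        name: bootstrap_median(vals, B=B, conf=conf, seed=s)
        for (name, vals), s in zip(groups.items(), seeds)
    }
    branch, normality = choose_branch(groups, alpha=alpha)
    if branch == "nonparametric":
        omnibus = kruskal_wallis(groups)
        pairwise = pairwise_wmw(groups)
    else:
        omnibus = parametric_branch(groups, design="between")[0]
        pairwise = pairwise_t(groups)
    ordering = sorted(estimates, key=lambda m: estimates[m].median_hat)
    padj = {frozenset(r.groups): r.p_adj for r in pairwise}
    equivalent = [
        (a, b)
        for a, b in zip(ordering, ordering[1:])
        if (padj.get(frozenset((a, b))) or 0.0) > alpha
    ]
    eq = {frozenset(p) for p in equivalent}
    parts = [ordering[0]]
    for a, b in zip(ordering, ordering[1:]):
        parts.append(" ~ " if frozenset((a, b)) in eq else " < ")
        parts.append(b)
    return BetweenModelReport(
        estimates=estimates, ordering=ordering, equivalent_pairs=equivalent,
        ordering_label="".join(parts), branch=branch, normality=normality,
        omnibus=omnibus, pairwise=pairwise, variables=shared,
        reference_source=reference.source, reference_mode=reference.mode,
        seed=seed, B=B,
    )


@dataclass
class SingleReadoutReport:
    variable: str
    estimates: pd.DataFrame  # columns: subgroup, day, median_hat, ci_low, ci_high, n
    per_day_tests: list[TestResult]
    time_tests: list[TestResult]
    branch: str
    seed: int = 0
    B: int = 10_000
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "analysis": "single_readout",
            "variable": self.variable,
            "seed": self.seed,
            "B": self.B,
            "branch": self.branch,
            "estimates": self.estimates.to_dict(orient="records"),
            "per_day_tests": [r.to_dict() for r in self.per_day_tests],
            "time_tests": [r.to_dict() for r in self.time_tests],
            "notes": self.notes,
        }


def run_single_readout(
    cohort: Cohort,
    variable: str,
    B: int = 10_000,
    conf: float = 0.95,
    seed: int = 0,
    alpha: float = 0.05,
) -> SingleReadoutReport:
    """Per-day bootstrapped medians of one readout with subgroup comparisons.

    Percent variables are baseline-standardized first.  Between-subgroup
    tests run per day (branch selected on the pooled-over-days subgroup
    samples); the time-dependent test (Friedman, or sphericity-corrected
    repeated-measures ANOVA on the parametric branch) runs per subgroup on
    animals with complete day blocks, and is skipped with a notice where no
    complete block exists.
    """
    if variable not in cohort.specs:
        raise KeyError(f"variable {variable!r} not declared in cohort")
    working = standardize_cohort(cohort) if cohort.specs[variable].is_percent else cohort
    frames = []
    for a in working.animals:
        if variable not in a.values:
            continue
        frames.append(
            pd.DataFrame(
                {"animal": a.animal_id, "subgroup": a.subgroup, "day": a.days,
                 "value": a.values[variable]}
            )
        )
    if not frames:
        raise KeyError(f"variable {variable!r} not measured in cohort")
    long = pd.concat(frames, ignore_index=True).dropna(subset=["value"])
    subgroups = sorted(long["subgroup"].unique())
    days = sorted(long["day"].unique())
    seed_iter = iter(_spawn_seeds(seed, len(subgroups) * len(days)))
    rows = []
    for sg in subgroups:
        for day in days:
            vals = long.loc[(long["subgroup"] == sg) & (long["day"] == day), "value"].to_numpy()
            if vals.size < 2:
                continue
            est = bootstrap_median(vals, B=B, conf=conf, seed=next(seed_iter))
            rows.append((sg, int(day), est.median_hat, est.ci_low, est.ci_high, est.n))
    estimates = pd.DataFrame(
        rows, columns=["subgroup", "day", "median_hat", "ci_low", "ci_high", "n"]
    )
    notes: list[str] = []
    pooled = {sg: long.loc[long["subgroup"] == sg, "value"].to_numpy() for sg in subgroups}
    per_day_tests: list[TestResult] = []
    branch = "none"
    if len(subgroups) >= 2:
        branch, _ = choose_branch(pooled, alpha=alpha)
        for day in days:
            day_groups = {
                sg: long.loc[(long["subgroup"] == sg) & (long["day"] == day), "value"].to_numpy()
                for sg in subgroups
            }
            if any(v.size == 0 for v in day_groups.values()):
                continue
            if branch == "nonparametric":
                r = kruskal_wallis(day_groups)
            else:
                r = parametric_branch(day_groups, design="between")[0]
            per_day_tests.append(
                TestResult(r.test_name, r.statistic, r.df, r.p_raw, groups=r.groups,
                           note=f"day {int(day)}")
            )
    else:
        notes.append("single subgroup: between-subgroup tests skipped")
    time_tests: list[TestResult] = []
    for sg in subgroups:
        wide = long[long["subgroup"] == sg].pivot(index="animal", columns="day", values="value")
        complete = wide.dropna()
        if complete.shape[0] < 2 or complete.shape[1] < 2:
            notes.append(f"subgroup {sg!r}: no complete day blocks, time-dependent test skipped")
            continue
        if branch == "parametric":
            r = parametric_branch(complete, design="within")[0]
        else:
            r = friedman_test(complete.to_numpy())
        time_tests.append(
            TestResult(r.test_name, r.statistic, r.df, r.p_raw, groups=(sg,), note=r.note)
        )
    return SingleReadoutReport(
        variable=variable, estimates=estimates, per_day_tests=per_day_tests,
        time_tests=time_tests, branch=branch, seed=seed, B=B, notes=notes,
    )
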