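"""Bootstrap median estimation and the rank-based comparison battery.

The estimation backbone is assumption-free: group medians are summarised by
the median of B bootstrap resample medians with a percentile confidence
interval (BCa available as an opt-in through scipy).  Hypothesis testing
follows a normality branch: Shapiro–Wilk per group decides between the
non-parametric battery (Kruskal–Wallis omnibus, pairwise Wilcoxon–
Mann–Whitney, Friedman for complete blocks, Dunn vs control) and the
parametric one (one-way / repeated-measures ANOVA with sphericity
correction, Dunnett vs control).  All families of pairwise p-values are
Holm-adjusted to control the family-wise error rate.

Tie handling uses mid-ranks with tie-corrected statistics throughout; the
Wilcoxon–Mann–Whitney p-value is exact for small untied samples and a
continuity-corrected normal approximation otherwise (scipy's automatic
policy).  Constant samples are routed to the non-parametric branch rather
than erroring the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import SampleSizeError

__all__ = [
    "BootstrapEstimate",
    "TestResult",
    "significance_stars",
    "bootstrap_median",
    "shapiro_wilk",
    "kruskal_wallis",
    "pairwise_wmw",
    "holm_adjust",
    "friedman_test",
    "dunn_posthoc",
    "parametric_branch",
    "choose_branch",
    "results_to_frame",
]


def significance_stars(p: float) -> str:
    """Conventional significance labels: *p<=0.05 ... ****p<=0.0001."""
    if math.isnan(p):
        return "na"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


@dataclass(frozen=True)
class BootstrapEstimate:
    """Bootstrapped median with percentile CI bounds."""

    median_hat: float
    ci_low: float
    ci_high: float
    B: int
    n: int
    seed: int
    conf: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median_hat <= self.ci_high):
            raise ValueError("CI bounds must bracket the estimate")

    def to_dict(self) -> dict:
        return {
            "median_hat": self.median_hat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "B": self.B,
            "n": self.n,
            "seed": self.seed,
            "conf": self.conf,
        }


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome with raw and adjusted p-values."""

    test_name: str
    statistic: float
    df: float
    p_raw: float
    p_adj: float | None = None
    groups: tuple[str, ...] = ()
    note: str = ""

    @property
    def stars(self) -> str:
        p = self.p_adj if self.p_adj is not None else self.p_raw
        return significance_stars(p)

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "groups": list(self.groups),
            "statistic": self.statistic,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "stars": self.stars,
            "note": self.note,
        }


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Flat-table export of a list of test results."""
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_median(
    values: Sequence[float],
    B: int = 10_000,
    conf: float = 0.95,
    seed: int = 0,
    method: str = "percentile",
) -> BootstrapEstimate:
    """Median of B resample medians with a percentile (or BCa) CI.

    The estimator is the median of the bootstrap distribution of the sample
    median; the interval is the (alpha/2, 1 - alpha/2) percentile interval of
    that distribution.  Deterministic under a fixed seed.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise SampleSizeError(f"bootstrap_median needs n >= 2 non-missing values, got {n}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    if method == "bca":
        res = sps.bootstrap(
            (x,), np.median, n_resamples=B, confidence_level=conf, method="BCa", rng=rng
        )
        meds = res.bootstrap_distribution
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
        med = float(np.median(meds))
        med = min(max(med, lo), hi)
        return BootstrapEstimate(med, lo, hi, B, n, seed, conf)
    if method != "percentile":
        raise ValueError(f"unknown CI method {method!r}")
    idx = rng.integers(0, n, size=(B, n))
    meds = np.median(x[idx], axis=1)
    alpha = 1.0 - conf
    lo, hi = np.quantile(meds, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapEstimate(float(np.median(meds)), float(lo), float(hi), B, n, seed, conf)


# ---------------------------------------------------------------------------
# Normality branch


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro–Wilk normality test; constant samples report p = nan and are
    treated downstream as evidence against the parametric branch."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise SampleSizeError(f"shapiro_wilk needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        return TestResult("shapiro_wilk", math.nan, x.size, math.nan, note="constant sample")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(w), x.size, float(p))


def choose_branch(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> tuple[str, list[TestResult]]:
    """Select the test battery: non-parametric iff any group is non-normal
    (Shapiro–Wilk p <= alpha), degenerate (constant), or too small to test.

    Returns the branch name and the per-group normality results for the
    report.
    """
    details: list[TestResult] = []
    branch = "parametric"
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 3 or np.ptp(x) == 0:
            details.append(
                TestResult("shapiro_wilk", math.nan, x.size, math.nan,
                           groups=(name,), note="degenerate or n < 3")
            )
            branch = "nonparametric"
            continue
        r = shapiro_wilk(x)
        details.append(TestResult(r.test_name, r.statistic, r.df, r.p_raw, groups=(name,)))
        if r.p_raw <= alpha:
            branch = "nonparametric"
    return branch, details


# ---------------------------------------------------------------------------
# Non-parametric battery


def _clean_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        out[name] = x[~np.isnan(x)]
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H with mid-rank tie correction, df = k - 1."""
    g = _clean_groups(groups)
    if len(g) < 2:
        raise SampleSizeError("kruskal_wallis needs >= 2 groups")
    if any(v.size == 0 for v in g.values()):
        raise SampleSizeError("kruskal_wallis: empty group")
    arrays = list(g.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: H = 0 by symmetry, p = 1
        return TestResult("kruskal_wallis", 0.0, len(g) - 1, 1.0, groups=tuple(g))
    h, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), len(g) - 1, float(p), groups=tuple(g))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def pairwise_wmw(groups: Mapping[str, Sequence[float]]) -> list[TestResult]:
    """Two-sided Wilcoxon–Mann–Whitney for every unordered pair, Holm-adjusted
    across the full pair family.  Exact p for small untied samples, otherwise
    the continuity-corrected normal approximation."""
    g = _clean_groups(groups)
    if len(g) < 2:
        raise SampleSizeError("pairwise_wmw needs >= 2 groups")
    for name, x in g.items():
        if x.size == 0:
            raise SampleSizeError(f"pairwise_wmw: group {name!r} is empty")
    pairs = list(combinations(g, 2))
    raw: list[TestResult] = []
    for a, b in pairs:
        u, p = sps.mannwhitneyu(g[a], g[b], alternative="two-sided", method="auto")
        raw.append(TestResult("wilcoxon_mann_whitney", float(u), math.nan, float(p), groups=(a, b)))
    adj = holm_adjust([r.p_raw for r in raw])
    return [
        TestResult(r.test_name, r.statistic, r.df, r.p_raw, p_adj=float(pa), groups=r.groups)
        for r, pa in zip(raw, adj)
    ]


def friedman_test(blocked: np.ndarray) -> TestResult:
    """Friedman rank-sum chi-square on a complete subjects x conditions
    matrix; df = T - 1.  Missing cells are the caller's problem (subset
    first)."""
    m = np.asarray(blocked, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise SampleSizeError("friedman_test needs a 2-D matrix with >= 2 subjects and >= 2 conditions")
    if np.isnan(m).any():
        raise SampleSizeError("friedman_test requires complete blocks (no missing cells)")
    if np.all(np.ptp(m, axis=1) == 0):
        return TestResult("friedman", 0.0, m.shape[1] - 1, 1.0)
    stat, p = sps.friedmanchisquare(*[m[:, j] for j in range(m.shape[1])])
    return TestResult("friedman", float(stat), m.shape[1] - 1, float(p))


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], control: str
) -> list[TestResult]:
    """Dunn's rank-based z comparisons of each group against a control,
    Holm-adjusted.

    Pooled mid-ranks with tie correction:

        z = (Rbar_i - Rbar_c) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_c) )

    with T = sum over tie groups of (t^3 - t); two-sided normal p-values.
    """
    g = _clean_groups(groups)
    if control not in g:
        raise KeyError(f"control group {control!r} not among {list(g)}")
    pooled = np.concatenate(list(g.values()))
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for name, x in g.items():
        mean_ranks[name] = float(np.mean(ranks[start : start + x.size]))
        start += x.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    raw: list[TestResult] = []
    for name, x in g.items():
        if name == control:
            continue
        se = math.sqrt(var_core * (1.0 / x.size + 1.0 / g[control].size))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[name] - mean_ranks[control]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        raw.append(TestResult("dunn", float(z), math.nan, float(min(p, 1.0)), groups=(name, control)))
    adj = holm_adjust([r.p_raw for r in raw])
    return [
        TestResult(r.test_name, r.statistic, r.df, r.p_raw, p_adj=float(pa), groups=r.groups)
        for r, pa in zip(raw, adj)
    ]


def pairwise_t(groups: Mapping[str, Sequence[float]]) -> list[TestResult]:
    """Welch t-test for every unordered pair, Holm-adjusted — the parametric
    counterpart of :func:`pairwise_wmw`."""
    g = _clean_groups(groups)
    if len(g) < 2:
        raise SampleSizeError("pairwise_t needs >= 2 groups")
    raw: list[TestResult] = []
    for a, b in combinations(g, 2):
        if np.ptp(np.concatenate([g[a], g[b]])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(g[a], g[b], equal_var=False)
        raw.append(TestResult("welch_t", float(t), math.nan, float(p), groups=(a, b)))
    adj = holm_adjust([r.p_raw for r in raw])
    return [
        TestResult(r.test_name, r.statistic, r.df, r.p_raw, p_adj=float(pa), groups=r.groups)
        for r, pa in zip(raw, adj)
    ]


# ---------------------------------------------------------------------------
# Parametric battery


def parametric_branch(
    data,
    design: str,
    control: str | None = None,
) -> list[TestResult]:
    """Parametric omnibus plus vs-control comparisons, Holm-adjusted.

    ``design="between"`` expects a mapping of group name -> sample: one-way
    ANOVA F, then Dunnett's test of every group against ``control``.
    ``design="within"`` expects a complete subjects x conditions DataFrame
    (columns are conditions): repeated-measures ANOVA with Greenhouse–Geisser
    sphericity correction, then paired t-tests of each condition against the
    ``control`` column, Holm-adjusted.
    """
    results: list[TestResult] = []
    if design == "between":
        g = _clean_groups(data)
        if len(g) < 2:
            raise SampleSizeError("between design needs >= 2 groups")
        arrays = list(g.values())
        if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
            results.append(TestResult("anova_oneway", 0.0, len(g) - 1, 1.0, groups=tuple(g)))
        else:
            f, p = sps.f_oneway(*arrays)
            results.append(TestResult("anova_oneway", float(f), len(g) - 1, float(p), groups=tuple(g)))
        if control is not None:
            if control not in g:
                raise KeyError(f"control group {control!r} not among {list(g)}")
            others = [name for name in g if name != control]
            res = sps.dunnett(*[g[name] for name in others], control=g[control])
            adj = holm_adjust(list(np.atleast_1d(res.pvalue)))
            for name, stat, praw, padj in zip(
                others, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue), adj
            ):
                results.append(
                    TestResult("dunnett", float(stat), math.nan, float(praw),
                               p_adj=float(padj), groups=(name, control))
                )
        return results

    if design != "within":
        raise ValueError(f"unknown design {design!r}")

    df = pd.DataFrame(data)
    if df.isna().any().any():
        raise SampleSizeError("within design requires complete blocks")
    wide = df
    if np.allclose(wide.to_numpy(), wide.to_numpy()[:, [0]]):
        results.append(TestResult("rm_anova", 0.0, wide.shape[1] - 1, 1.0))
    else:
        import pingouin as pg

        long = wide.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="value"
        )
        aov = pg.rm_anova(
            data=long, dv="value", within="condition", subject="subject", correction=True
        )
        row = aov.iloc[0]
        gg_cols = [c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns]
        p_col = next(
            (c for c in gg_cols if not math.isnan(row[c])),
            "p_unc" if "p_unc" in aov.columns else "p-unc",
        )
        results.append(
            TestResult("rm_anova", float(row["F"]), float(row["ddof1"]), float(row[p_col]),
                       note="Greenhouse-Geisser corrected" if "GG" in p_col else "")
        )
    if control is not None:
        if control not in wide.columns:
            raise KeyError(f"control condition {control!r} not among {list(wide.columns)}")
        raw = []
        for col in wide.columns:
            if col == control:
                continue
            diff = wide[col].to_numpy(dtype=float) - wide[control].to_numpy(dtype=float)
            if np.ptp(diff) == 0 and diff[0] == 0:
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(wide[col], wide[control])
            raw.append(TestResult("paired_t_vs_control", float(t), wide.shape[0] - 1,
                                  float(p), groups=(str(col), str(control))))
        adj = holm_adjust([r.p_raw for r in raw])
        results.extend(
            TestResult(r.test_name, r.statistic, r.df, r.p_raw, p_adj=float(pa), groups=r.groups)
            for r, pa in zip(raw, adj)
        )
    return results
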