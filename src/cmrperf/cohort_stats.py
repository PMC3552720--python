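"""Cohort statistics: Welch and paired t-tests, Fisher's exact test,
two-group sample-size computation and group summary tables.

Continuous comparisons use Student's t machinery without assuming equal
variances (Welch-Satterthwaite degrees of freedom); within-group
comparisons are paired.  Categorical 2x2 comparisons use Fisher's exact
test with the two-sided point-probability rule.  All p-values are
two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    InputError,
    InsufficientDataError,
    ParameterError,
    UndefinedStatisticError,
)


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: n, mean, sample sd."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("group summary needs n >= 2")
        if self.sd < 0:
            raise ParameterError("sd must be >= 0")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)))


@dataclass(frozen=True)
class TestResult:
    """A test statistic with (possibly fractional) df and two-sided p."""

    method: str
    statistic: float
    df: float | None
    p_value: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def _as_summary(x) -> GroupSummary:
    return x if isinstance(x, GroupSummary) else GroupSummary.from_sample(x)


def _welch_from_moments(mean_a, var_a, n_a, mean_b, var_b, n_b):
    """Vectorized Welch t, df and two-sided p from group moments."""
    sa, sb = var_a / n_a, var_b / n_b
    se2 = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (n_a - 1) + sb**2 / (n_b - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, p


def welch_t(a, b) -> TestResult:
    """Two-sample t-test not assuming equal variances.

    ``a`` and ``b`` may be samples or :class:`GroupSummary` objects;
    summary mode allows testing printed group statistics directly.
    """
    a, b = _as_summary(a), _as_summary(b)
    if a.sd == 0 and b.sd == 0:
        raise UndefinedStatisticError("zero variance in both groups")
    t, df, p = _welch_from_moments(a.mean, a.sd**2, a.n, b.mean, b.sd**2, b.n)
    return TestResult("welch_t", float(t), float(df), float(min(p, 1.0)))


def paired_t(differences: Sequence[float]) -> TestResult:
    """One-sample t-test of per-subject differences against zero."""
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise InsufficientDataError("paired test needs n >= 2 differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise UndefinedStatisticError("differences have zero variance")
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TestResult("paired_t", t, float(n - 1), min(p, 1.0))


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test on a 2x2 table, two-sided point-probability rule.

    The p-value sums the hypergeometric probabilities (margins fixed) of
    every table whose point probability does not exceed that of the
    observed table.  Computed in exact rational arithmetic, so no floating
    tolerance enters the comparison.
    """
    tab = np.asarray(table, dtype=object)
    if tab.shape != (2, 2):
        raise InputError("table must be 2x2")
    a, b, c, d = (int(tab[0, 0]), int(tab[0, 1]), int(tab[1, 0]), int(tab[1, 1]))
    if min(a, b, c, d) < 0:
        raise InputError("counts must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise InputError("grand total must be >= 1")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def weight(k: int) -> int:
        return math.comb(r1, k) * math.comb(n - r1, c1 - k)

    total = math.comb(n, c1)
    observed = weight(a)
    tail = sum(w for k in range(lo, hi + 1) if (w := weight(k)) <= observed)
    p = float(Fraction(tail, total))
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = a * d / (b * c)
    return TestResult("fisher_exact", odds, None, p)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Two-group design: detect a relative difference from a reference mean."""

    mean: float
    sd: float
    relative_difference: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not (self.mean > 0 and self.sd > 0):
            raise ParameterError("mean and sd must be positive")
        if not (0 < self.relative_difference <= 1):
            raise ParameterError("relative difference must be in (0, 1]")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ParameterError("alpha and power must be in (0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    per_group: int
    total: int
    method: str


def sample_size_two_group(spec: SampleSizeSpec, exact: bool = False) -> SampleSizeResult:
    """Total subjects to detect a relative mean difference between two groups.

    Default is the two-sided normal-approximation formula with equal
    allocation, ``n = 2*sd^2*(z_{1-a/2} + z_{power})^2 / delta^2`` per
    group, rounded up.  ``exact=True`` solves the noncentral-t power
    equation instead (statsmodels), which returns at least the
    approximation's value.
    """
    delta = spec.relative_difference * spec.mean
    if delta <= 0:
        raise ParameterError("effect size is zero")
    if exact:
        from statsmodels.stats.power import TTestIndPower

        n_float = TTestIndPower().solve_power(
            effect_size=delta / spec.sd, alpha=spec.alpha, power=spec.power,
            ratio=1.0, alternative="two-sided",
        )
        per_group = math.ceil(n_float - 1e-9)
        method = "noncentral_t"
    else:
        z = sps.norm.ppf(1 - spec.alpha / 2) + sps.norm.ppf(spec.power)
        per_group = math.ceil(2 * spec.sd**2 * z**2 / delta**2 - 1e-12)
        method = "normal_approximation"
    return SampleSizeResult(per_group=per_group, total=2 * per_group, method=method)


# ---------------------------------------------------------------------------
# Cohort summary tables

#: Continuous metrics summarized per group and compared between groups.
SUMMARY_METRICS = (
    "rest", "stress", "recovery", "mpri_rest", "mpri_recov",
    "pct_reduction", "recovery_to_rest",
)

#: Within-group paired comparisons: (label, column_a, column_b).
PAIRED_COMPARISONS = (
    ("recovery_vs_rest", "recovery", "rest"),
    ("recovery_vs_stress", "recovery", "stress"),
    ("mpri_recov_vs_mpri_rest", "mpri_recov", "mpri_rest"),
)

REQUIRED_COLUMNS = ("subject_id", "group") + SUMMARY_METRICS[:5] + (
    "pct_reduction", "recovery_to_rest", "delayed",
)


@dataclass
class CohortSummary:
    """Group summary table plus all within/between-group test results."""

    table: pd.DataFrame
    within_group: dict[str, dict[str, TestResult | None]]
    between_group: dict[str, TestResult | None]
    delayed_fisher: TestResult | None

    def tests_to_dict(self) -> dict:
        return {
            "within_group": {
                g: {k: (t.to_dict() if t else None) for k, t in d.items()}
                for g, d in self.within_group.items()
            },
            "between_group": {
                k: (t.to_dict() if t else None) for k, t in self.between_group.items()
            },
            "delayed_fisher": self.delayed_fisher.to_dict() if self.delayed_fisher else None,
        }


def _maybe_paired(a: np.ndarray, b: np.ndarray) -> TestResult | None:
    try:
        return paired_t(a - b)
    except UndefinedStatisticError:
        return None  # rendered as n/a (e.g. jitter-free synthetic cohorts)


def _maybe_welch(a, b) -> TestResult | None:
    try:
        return welch_t(a, b)
    except UndefinedStatisticError:
        return None


def summarize_cohort(cohort: pd.DataFrame) -> CohortSummary:
    """Per-group mean (SD) of every perfusion metric plus all test p-values.

    ``cohort`` has one row per subject with the columns written by the
    per-subject analysis (`subject_id`, `group`, rest/stress/recovery
    up-slopes, MPRi columns, `pct_reduction`, `recovery_to_rest`,
    `delayed`).  Within each group, paired t-tests compare recovery vs rest
    and vs stress up-slopes and MPRi-recov vs MPRi-rest; between groups,
    Welch tests compare every metric and Fisher's exact test compares
    delayed-hyperemia counts.  Undefined statistics (zero variance) are
    reported as ``None`` and rendered "n/a".
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise InputError(f"cohort table missing column(s): {', '.join(missing)}")
    if cohort["subject_id"].duplicated().any():
        dups = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].tolist()
        raise InputError(f"duplicated subject id(s): {dups}")
    groups = list(dict.fromkeys(cohort["group"]))
    for g in groups:
        if (cohort["group"] == g).sum() < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 subjects")

    rows = []
    within: dict[str, dict[str, TestResult | None]] = {}
    for g in groups:
        sub = cohort[cohort["group"] == g]
        row: dict = {"group": g, "n": len(sub), "n_delayed": int(sub["delayed"].sum())}
        for m in SUMMARY_METRICS:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_sd"] = float(sub[m].std(ddof=1))
        rows.append(row)
        within[g] = {
            label: _maybe_paired(sub[ca].to_numpy(float), sub[cb].to_numpy(float))
            for label, ca, cb in PAIRED_COMPARISONS
        }

    between: dict[str, TestResult | None] = {}
    delayed_fisher: TestResult | None = None
    if len(groups) >= 2:
        g0 = cohort[cohort["group"] == groups[0]]
        g1 = cohort[cohort["group"] == groups[1]]
        for m in SUMMARY_METRICS:
            between[m] = _maybe_welch(g0[m].to_numpy(float), g1[m].to_numpy(float))
        tab = [
            [int(g0["delayed"].sum()), int(len(g0) - g0["delayed"].sum())],
            [int(g1["delayed"].sum()), int(len(g1) - g1["delayed"].sum())],
        ]
        delayed_fisher = fisher_exact_2x2(tab)

    return CohortSummary(
        table=pd.DataFrame(rows),
        within_group=within,
        between_group=between,
        delayed_fisher=delayed_fisher,
    )


def format_report(summary: CohortSummary, decimals: int = 3) -> str:
    """Aligned-text report of the summary table and all p-values."""

    def fmt_p(t: TestResult | None) -> str:
        return "n/a" if t is None else f"{t.p_value:.{decimals}f}"

    lines = ["Cohort perfusion summary", "=" * 24, ""]
    tbl = summary.table
    for _, row in tbl.iterrows():
        lines.append(f"Group {row['group']} (n={row['n']}, delayed={row['n_delayed']})")
        for m in SUMMARY_METRICS:
            lines.append(
                f"  {m:<18} {row[f'{m}_mean']:8.{decimals}f} ({row[f'{m}_sd']:.{decimals}f})"
            )
        lines.append("  paired tests:")
        for label, *_ in PAIRED_COMPARISONS:
            lines.append(f"    {label:<26} p = {fmt_p(summary.within_group[row['group']][label])}")
        lines.append("")
    if summary.between_group:
        lines.append("Between-group Welch tests")
        for m in SUMMARY_METRICS:
            lines.append(f"  {m:<18} p = {fmt_p(summary.between_group.get(m))}")
        lines.append(f"  delayed (Fisher)   p = {fmt_p(summary.delayed_fisher)}")
    else:
        lines.append("Between-group comparisons: absent (single group)")
    lines.append("")
    return "\n".join(lines)
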