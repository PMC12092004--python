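"""Group statistics for per-neuron measurements.

Two-group comparisons use the unpaired two-tailed Student's t-test
(pooled variance by default, Welch by flag); multi-group designs use
one-way ANOVA followed by Sidak-adjusted pairwise comparisons on the
pooled within-group error, over an explicit list of requested pairs
(Prism-style "selected comparisons"): p_adj = 1 - (1 - p)^m with m the
number of requested comparisons.  The unit of analysis is the neuron,
matching per-neuron vesicle counts; per-mouse aggregation is the
caller's responsibility and treats neurons as independent otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "AnovaResult",
    "Adjustment",
    "significance_stars",
    "unpaired_t_test",
    "sidak_adjust",
    "anova_sidak",
    "summarize_groups",
]


class Adjustment(str, enum.Enum):
    NONE = "NONE"
    SIDAK = "SIDAK"


@dataclass
class GroupSample:
    """One experimental group's measurements on a stated unit of analysis."""

    label: str
    values: np.ndarray
    unit: str = "neuron"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).ravel()

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.n else float("nan")


@dataclass
class TestResult:
    """One comparison: statistic, df, raw and adjusted p, significance stars."""

    comparison: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    adjustment: Adjustment = Adjustment.NONE
    mean_difference: float = float("nan")  # second group minus first
    note: str = ""

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def significance_stars(p: float) -> str:
    """GraphPad-style star convention used in the figure legends."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _require_n(group: GroupSample, n_min: int = 2) -> None:
    if group.n < n_min:
        raise ValueError(f"group '{group.label}' needs n >= {n_min}, got {group.n}")


def unpaired_t_test(a: GroupSample, b: GroupSample, welch: bool = False) -> TestResult:
    """Two-sided unpaired t-test (pooled Student by default).

    The degenerate all-constant case (zero variance in both groups, equal
    means) is reported as t = 0, p = 1 with a note rather than NaN.
    """
    _require_n(a)
    _require_n(b)
    note = ""
    if np.var(a.values) == 0 and np.var(b.values) == 0 and a.mean == b.mean:
        stat, p, df = 0.0, 1.0, a.n + b.n - 2
        note = "zero variance in both groups with equal means; p = 1 by convention"
    else:
        res = sps.ttest_ind(a.values, b.values, equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return TestResult(
        comparison=f"{a.label} vs {b.label}",
        statistic=stat,
        df=df,
        p_raw=p,
        p_adjusted=p,
        adjustment=Adjustment.NONE,
        mean_difference=b.mean - a.mean,
        note=note,
    )


def sidak_adjust(p_raw: float, m: int) -> float:
    """Sidak family-wise adjustment over m comparisons: 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must lie in [0, 1]")
    if m == 1:
        return float(p_raw)  # identity, exactly
    return float(1.0 - (1.0 - p_raw) ** m)


def anova_sidak(
    groups: Sequence[GroupSample],
    comparisons: Sequence[tuple[str, str]] = (),
) -> tuple[AnovaResult, list[TestResult]]:
    """One-way ANOVA, then Sidak-adjusted pairwise tests on requested pairs.

    Pairwise comparisons use the pooled within-group mean square with
    N - k degrees of freedom; the adjustment multiplicity m is the number
    of requested comparisons (an empty list returns the ANOVA alone).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        _require_n(g)
    by_label = {g.label: g for g in groups}
    if len(by_label) != len(groups):
        raise ValueError("group labels must be unique")

    arrays = [g.values for g in groups]
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    df_within = n_total - k
    # Pooled within-group variance (the ANOVA error term).
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_within = ss_within / df_within if df_within > 0 else float("nan")
    if ss_within == 0:
        grand = np.concatenate(arrays).mean()
        if all(a.mean() == grand for a in arrays):
            anova = AnovaResult(0.0, k - 1, df_within, 1.0)
        else:
            anova = AnovaResult(float("inf"), k - 1, df_within, 0.0)
    else:
        f_res = sps.f_oneway(*arrays)
        anova = AnovaResult(float(f_res.statistic), k - 1, df_within, float(f_res.pvalue))

    results: list[TestResult] = []
    m = len(comparisons)
    for label_a, label_b in comparisons:
        ga, gb = by_label[label_a], by_label[label_b]
        diff = gb.mean - ga.mean
        if ms_within == 0:
            stat = 0.0 if diff == 0 else float(np.sign(-diff)) * float("inf")
            p = 1.0 if diff == 0 else 0.0
        else:
            se = float(np.sqrt(ms_within * (1.0 / ga.n + 1.0 / gb.n)))
            stat = (ga.mean - gb.mean) / se
            p = float(2.0 * sps.t.sf(abs(stat), df_within))
        results.append(
            TestResult(
                comparison=f"{label_a} vs {label_b}",
                statistic=stat,
                df=df_within,
                p_raw=p,
                p_adjusted=sidak_adjust(p, m),
                adjustment=Adjustment.SIDAK,
                mean_difference=diff,
                note=f"pooled within-group error; Sidak m={m}",
            )
        )
    return anova, results


def summarize_groups(samples: Sequence[GroupSample]) -> pd.DataFrame:
    """Mean +/- SEM summary table (SEM = sd / sqrt(n), ddof = 1).

    A single-value group has undefined SEM (reported as NaN); a constant
    group has SEM 0.
    """
    rows = []
    for g in samples:
        sem = float(np.std(g.values, ddof=1) / np.sqrt(g.n)) if g.n >= 2 else float("nan")
        rows.append({"group": g.label, "unit": g.unit, "n": g.n, "mean": g.mean, "sem": sem})
    return pd.DataFrame(rows, columns=["group", "unit", "n", "mean", "sem"])


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": r.comparison,
                "statistic": r.statistic,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "adjustment": r.adjustment.value,
                "mean_difference": r.mean_difference,
                "stars": r.stars,
                "note": r.note,
            }
            for r in results
        ],
        columns=[
            "comparison",
            "statistic",
            "df",
            "p_raw",
            "p_adjusted",
            "adjustment",
            "mean_difference",
            "stars",
            "note",
        ],
    )
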