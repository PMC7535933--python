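"""Cohort statistics and report generation.

The three tests used throughout the analysis are the two-sample Student's
t-test (pooled variance by default, Welch optional), the 2x2 chi-square
test of independence *without* continuity correction (the closed form
``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``), and one-way ANOVA.
Percentages are reported to one decimal with round-half-up, matching the
convention of the printed summaries (e.g. 17 of 28 -> 60.7%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "TestResult",
    "CohortSummary",
    "ttest_two_sample",
    "chisq_2x2",
    "fisher_exact_2x2",
    "anova_oneway",
    "percent",
    "cohort_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 non-negative integer counts with labels."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2) or np.any(arr < 0):
            raise ValueError("counts must be a 2x2 non-negative table")
        if arr.sum() == 0:
            raise ValueError("table total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    test: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    inputs: dict = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def ttest_two_sample(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variant: str = "student",
) -> TestResult:
    """Two-sided two-sample t-test (pooled Student's by default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return TestResult(
            test=f"t-{variant}",
            statistic=0.0,
            df=len(a) + len(b) - 2,
            p_value=1.0,
            inputs={"n_a": len(a), "n_b": len(b)},
            degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return TestResult(
        test=f"t-{variant}",
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        inputs={"n_a": len(a), "n_b": len(b)},
    )


def chisq_2x2(
    table: ContingencyTable, continuity: str = "none"
) -> TestResult:
    """2x2 chi-square test of independence.

    Uncorrected by default: ``chi2 = N (ad - bc)^2 / (row and column
    marginal products)`` with df = 1; ``continuity='yates'`` applies the
    Yates correction.
    """
    (a, b), (c, d) = table.counts
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined: a marginal total is zero")
    if continuity == "none":
        stat = n * (a * d - b * c) ** 2 / margins
    elif continuity == "yates":
        stat = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2 / margins
    else:
        raise ValueError("continuity must be 'none' or 'yates'")
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(
        test=f"chi2-{continuity}",
        statistic=float(stat),
        df=1.0,
        p_value=p,
        inputs={"counts": [list(r) for r in table.counts]},
    )


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table."""
    odds, p = sps.fisher_exact(np.asarray(table.counts))
    return TestResult(
        test="fisher-exact",
        statistic=float(odds),
        df=None,
        p_value=float(p),
        inputs={"counts": [list(r) for r in table.counts]},
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    within_var = sum(float(g.var(ddof=1)) for g in arrays)
    means = [g.mean() for g in arrays]
    if within_var == 0 and len(set(means)) == 1:
        k = len(arrays)
        n = sum(len(g) for g in arrays)
        return TestResult(
            test="anova-oneway",
            statistic=0.0,
            df=(k - 1, n - k),
            p_value=1.0,
            inputs={"group_sizes": [len(g) for g in arrays]},
            degenerate=True,
        )
    res = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    return TestResult(
        test="anova-oneway",
        statistic=float(res.statistic),
        df=(k - 1, n - k),
        p_value=float(res.pvalue),
        inputs={"group_sizes": [len(g) for g in arrays]},
    )


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage to ``decimals`` places, round-half-up (17/28 -> 60.7)."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Per-cell rows plus derived percentage tables and attached tests."""

    cells: pd.DataFrame
    percentages: pd.DataFrame
    contingency: ContingencyTable | None
    tests: dict[str, TestResult]
    params: dict


def cohort_report(
    cells: pd.DataFrame,
    condition_column: str = "condition",
    mode_column: str = "mode",
    reversal_label: str = "reversal",
    out_dir: str | Path | None = None,
    params: dict | None = None,
) -> CohortSummary:
    """Build the cohort summary with percentage tables and tests.

    ``cells`` carries one row per analysed cell.  When two conditions are
    present, a 2x2 contingency of condition x (reversal vs other) is built
    and tested with the uncorrected chi-square (Fisher's exact p attached
    alongside).  An empty cohort yields empty tables and no failure.
    Writes ``cohort.csv``, ``percentages.csv`` and ``report.json`` when
    ``out_dir`` is given.
    """
    params = dict(params or {})
    tests: dict[str, TestResult] = {}
    contingency = None

    if cells.empty or condition_column not in cells or mode_column not in cells:
        pct = pd.DataFrame(columns=["condition", "label", "count", "total", "pct"])
    else:
        rows = []
        for cond, grp in cells.groupby(condition_column, sort=True):
            total = len(grp)
            for lab, cnt in grp[mode_column].value_counts().items():
                rows.append(
                    {
                        "condition": cond,
                        "label": lab,
                        "count": int(cnt),
                        "total": total,
                        "pct": percent(int(cnt), total),
                    }
                )
        pct = pd.DataFrame(rows)

        conditions = sorted(cells[condition_column].unique())
        if len(conditions) == 2:
            counts = []
            for cond in conditions:
                grp = cells[cells[condition_column] == cond]
                rev = int((grp[mode_column] == reversal_label).sum())
                counts.append((len(grp) - rev, rev))
            contingency = ContingencyTable(
                counts=(tuple(counts[0]), tuple(counts[1])),
                row_labels=(str(conditions[0]), str(conditions[1])),
                col_labels=("other", reversal_label),
            )
            try:
                tests["chi2"] = chisq_2x2(contingency)
            except ValueError:
                pass
            tests["fisher"] = fisher_exact_2x2(contingency)

    summary = CohortSummary(
        cells=cells.copy(),
        percentages=pct,
        contingency=contingency,
        tests=tests,
        params=params,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cells.to_csv(out_dir / "cohort.csv", index=False)
        pct.to_csv(out_dir / "percentages.csv", index=False)
        report = {
            "params": params,
            "n_cells": int(len(cells)),
            "tests": {
                name: {
                    "test": t.test,
                    "statistic": t.statistic,
                    "df": t.df,
                    "p_value": t.p_value,
                    "degenerate": t.degenerate,
                }
                for name, t in tests.items()
            },
            "contingency": (
                [list(r) for r in contingency.counts] if contingency else None
            ),
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return summary
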