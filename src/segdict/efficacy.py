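"""Treatment-efficacy arithmetic for four-category clinical outcomes.

Outcomes per group are counts of cured / markedly effective / effective
/ ineffective patients.  The total effective rate is the share of
patients in any of the first three categories.  Group comparison uses
the Pearson chi-square test on the effective-vs-ineffective dichotomy
(2x2, df=1, no continuity correction by default — matching the common
statistical-package default when all expected counts are at least 5);
a Yates-corrected variant and the full 4x2 test are available behind
flags.  Mean-comparison of summary statistics (mean, sd, n per group)
uses the pooled-variance two-sample t-test.

The standard tests are delegated to :mod:`scipy.stats`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats

__all__ = [
    "OutcomeTable",
    "EfficacyResult",
    "effective_rates",
    "chi_square_2x2",
    "chi_square_4x2",
    "two_sample_t",
    "compare_groups",
    "load_outcome_fixture",
]

CATEGORIES = ("cured", "markedly_effective", "effective", "ineffective")


@dataclass(frozen=True)
class OutcomeTable:
    """Outcome counts for one treatment group."""

    group_name: str
    cured: int
    markedly_effective: int
    effective: int
    ineffective: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("a group must contain at least one patient")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.cured, self.markedly_effective, self.effective, self.ineffective)

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def n_effective(self) -> int:
        """Patients in any category other than ineffective."""
        return self.n - self.ineffective


@dataclass(frozen=True)
class EfficacyResult:
    """Percentages for two groups plus their chi-square comparison."""

    per_category_pct: dict
    total_effective_pct: dict
    chi2_statistic: float
    p_value: float
    df: int


def effective_rates(table: OutcomeTable):
    """Per-category and total effective percentages of one group.

    Returns ``(per_category_pct, total_effective_pct)`` where the first
    is a dict over the four categories (values 100 * count / n) and the
    total is ``100 * (n - ineffective) / n``.
    """
    n = table.n
    per_category = {
        name: 100.0 * count / n for name, count in zip(CATEGORIES, table.counts)
    }
    total = 100.0 * table.n_effective / n
    return per_category, total


def chi_square_2x2(
    effective_a: int,
    ineffective_a: int,
    effective_b: int,
    ineffective_b: int,
    yates: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 effective/ineffective table (df=1)."""
    table = np.array([[effective_a, ineffective_a], [effective_b, ineffective_b]])
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square is undefined with a zero margin")
    result = stats.chi2_contingency(table, correction=yates)
    return float(result.statistic), float(result.pvalue)


def chi_square_4x2(table_a: OutcomeTable, table_b: OutcomeTable) -> tuple[float, float, int]:
    """Chi-square over the full four-category-by-two-group table (df=3)."""
    table = np.array([table_a.counts, table_b.counts])
    keep = table.sum(axis=0) > 0  # drop empty categories to keep E > 0
    table = table[:, keep]
    result = stats.chi2_contingency(table, correction=False)
    return float(result.statistic), float(result.pvalue), int(result.dof)


def two_sample_t(
    summary_a: tuple[float, float, int], summary_b: tuple[float, float, int]
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from (mean, sd, n) summaries.

    Degenerate cases: both sds zero with equal means gives (0, 1); zero
    pooled variance with unequal means gives (±inf, 0).
    """
    mean_a, sd_a, n_a = summary_a
    mean_b, sd_b, n_b = summary_b
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return 0.0, 1.0
        return float(np.sign(mean_a - mean_b) * np.inf), 0.0
    result = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return float(result.statistic), float(result.pvalue)


def compare_groups(table_a: OutcomeTable, table_b: OutcomeTable, yates: bool = False) -> EfficacyResult:
    """Full efficacy comparison of two groups.

    Percentages per group plus the 2x2 chi-square on the
    effective-vs-ineffective dichotomy (the comparison the total
    effective rates test).
    """
    per_a, total_a = effective_rates(table_a)
    per_b, total_b = effective_rates(table_b)
    statistic, p_value = chi_square_2x2(
        table_a.n_effective, table_a.ineffective,
        table_b.n_effective, table_b.ineffective,
        yates=yates,
    )
    return EfficacyResult(
        per_category_pct={table_a.group_name: per_a, table_b.group_name: per_b},
        total_effective_pct={table_a.group_name: total_a, table_b.group_name: total_b},
        chi2_statistic=statistic,
        p_value=p_value,
        df=1,
    )


def load_outcome_fixture() -> list[OutcomeTable]:
    """The packaged acupoint-application outcome tables (31 patients per
    group: an acupoint-application experimental group and a conventional
    diuretic control group)."""
    text = resources.files("segdict").joinpath("data/clinical_outcomes.csv").read_text()
    tables = []
    for row in csv.DictReader(text.splitlines()):
        tables.append(
            OutcomeTable(
                group_name=row["group"],
                cured=int(row["cured"]),
                markedly_effective=int(row["markedly_effective"]),
                effective=int(row["effective"]),
                ineffective=int(row["ineffective"]),
            )
        )
    return tables
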