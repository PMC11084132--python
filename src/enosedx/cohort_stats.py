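"""Demographic-table statistics for cohort comparisons.

Pearson chi-square (no continuity correction) for categorical variables,
two-sample t-tests for continuous ones, and one-way ANOVA for more than
two groups — the tests typically reported in a clinical Table 1. The
package ships the demographic counts of the two-site lung-cancer eNose
cohort it emulates (231 participants across training/validation/test) as a
CSV fixture; ``load_demographics()`` returns them as contingency tables.

The uncorrected Pearson test is deliberate: it reproduces the cohort's
published within- and cross-cohort p-values, while Yates-corrected
variants do not. Small expected counts trigger a logged warning, never a
silent switch of test; Fisher's exact test is available explicitly for
2x2 tables.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str


@dataclass
class ContingencyTable:
    """Integer count table: groups in rows, categories in columns."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InvalidArgumentError("counts must be a 2-D matrix")
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise InvalidArgumentError("need at least 2 rows and 2 columns")
        if (r, c) != (len(self.row_labels), len(self.col_labels)):
            raise InvalidArgumentError("labels must match the count matrix shape")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise InvalidArgumentError("counts must be nonnegative integers")
        if np.any(self.counts.sum(axis=1) == 0) or np.any(self.counts.sum(axis=0) == 0):
            raise InvalidArgumentError("table has an all-zero row or column")


def chisq_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    Expected counts come from the product of the margins over the grand
    total; df = (r-1)(c-1); the p-value is the upper chi-square tail.
    """
    res = stats.chi2_contingency(table.counts, correction=False)
    if np.any(res.expected_freq < 5):
        log.warning(
            "chi-square table has expected counts < 5 (min %.2f); "
            "consider fisher_exact for a 2x2 table",
            res.expected_freq.min(),
        )
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.dof),
        p_value=float(res.pvalue),
        method="pearson_chi_square",
    )


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Fisher's exact test, 2x2 only; offered alongside, never substituted."""
    if table.counts.shape != (2, 2):
        raise InvalidArgumentError("fisher_exact requires a 2x2 table")
    res = stats.fisher_exact(table.counts)
    return TestResult(statistic=float(res.statistic), df=1.0,
                      p_value=float(res.pvalue), method="fisher_exact")


def t_test(sample_a, sample_b, variant: str = "pooled") -> TestResult:
    """Two-sided two-sample t-test (pooled-variance or Welch)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("each sample needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise InvalidArgumentError("variant must be 'pooled' or 'welch'")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        method=f"t_test_{variant}",
    )


def one_way_anova(samples) -> TestResult:
    """One-way ANOVA across >= 2 groups.

    Degenerate all-identical input (zero between- and within-group
    variance) is reported as F=0, p=1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise InvalidArgumentError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InvalidArgumentError("every group needs n >= 2")
    k = len(groups)
    n = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult(statistic=0.0, df=float(k - 1), p_value=1.0, method="one_way_anova")
    res = stats.f_oneway(*groups)
    return TestResult(
        statistic=float(res.statistic),
        df=float(k - 1),
        p_value=float(res.pvalue),
        method="one_way_anova",
    )


def read_demographics_csv(fh) -> dict[str, ContingencyTable]:
    """Parse (table, group, category, count) rows into contingency tables."""
    raw: dict[str, dict[str, dict[str, int]]] = {}
    order: dict[str, tuple[list, list]] = {}
    for row in csv.DictReader(fh):
        t, g, c = row["table"], row["group"], row["category"]
        raw.setdefault(t, {}).setdefault(g, {})[c] = int(row["count"])
        rows, cols = order.setdefault(t, ([], []))
        if g not in rows:
            rows.append(g)
        if c not in cols:
            cols.append(c)
    tables = {}
    for t, groups in raw.items():
        rows, cols = order[t]
        counts = np.array([[groups[g].get(c, 0) for c in cols] for g in rows])
        tables[t] = ContingencyTable(tuple(rows), tuple(cols), counts)
    return tables


def load_demographics() -> dict[str, ContingencyTable]:
    """The packaged two-site cohort demographic tables (231 participants)."""
    ref = resources.files("enosedx.data").joinpath("cohort_demographics.csv")
    with ref.open() as fh:
        return read_demographics_csv(fh)
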