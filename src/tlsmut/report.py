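"""Per-genotype aggregation and comparison statistics.

Mutation counts per clone are summarised as mean with standard error of the
mean (SEM); genotypes are compared with an unpaired two-sided t-test (Welch
variant by default) or a Wilcoxon rank-sum test (exact for small samples).
No multiple-testing correction is applied: unadjusted p-values are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class ReportError(ValueError):
    pass


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float | None  # None when undefined (n = 1)
    values: tuple[float, ...]


def summarize_group(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean and SEM (sd / sqrt(n); missing for a single value)."""
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ReportError("empty group")
    n = len(vals)
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else None
    return GroupSummary(label=label, n=n, mean=mean, sem=sem, values=vals)


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "t",
    equal_var: bool = False,
    exact_cutoff: int = 25,
) -> ComparisonResult:
    """Unpaired two-sided comparison of two groups.

    ``test='t'`` runs the Welch t-test (``equal_var=True`` switches to the
    pooled-variance form); ``test='wilcoxon'`` runs the rank-sum test, exact
    below ``exact_cutoff`` observations per group (and without ties), normal
    approximation otherwise.  Two groups with zero variance and equal means
    are reported as p = 1 by convention.
    """
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    if test == "t":
        if len(a) < 2 or len(b) < 2:
            raise ReportError("t-test requires n >= 2 per group")
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                logger.info("both groups constant and equal; p = 1 by convention")
                return ComparisonResult("t", 0.0, 1.0)
            return ComparisonResult("t", math.copysign(math.inf, np.mean(a) - np.mean(b)), 0.0)
        stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
        return ComparisonResult("t", float(stat), float(p))
    if test == "wilcoxon":
        if not a or not b:
            raise ReportError("rank-sum test requires n >= 1 per group")
        if set(a) == set(b) and len(set(a)) == 1:
            logger.info("both groups constant and equal; p = 1 by convention")
            return ComparisonResult("wilcoxon", len(a) * len(b) / 2.0, 1.0)
        has_ties = len(set(a) | set(b)) < len(a) + len(b)
        method = "exact" if max(len(a), len(b)) <= exact_cutoff and not has_ties else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return ComparisonResult("wilcoxon", float(res.statistic), float(res.pvalue))
    raise ReportError(f"unknown test {test!r}")


def percent_change(mean_ref: float, mean_test: float) -> float:
    """Percentage reduction of ``mean_test`` relative to ``mean_ref``.

    Positive values mean fewer events in the test group (e.g. 71% fewer);
    negative values mean an increase.
    """
    if mean_ref <= 0:
        raise ReportError("reference mean must be > 0")
    return 100.0 * (mean_ref - mean_test) / mean_ref
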