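"""Per-condition stoichiometry statistics and cross-condition comparison.

Summaries follow the box-and-whisker convention of the experiment's
reporting: boxes span the 25th-75th percentiles with the median marked,
whiskers span the 10th-90th percentiles, and values outside the whiskers
are listed individually as outliers.  "Average" is the arithmetic mean of
included step counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import EmptyCohortError, InputError
from .steps import EXCLUSION_REASONS, StepCountResult

__all__ = ["ConditionSummary", "summarize_condition", "compare_conditions"]


@dataclass
class ConditionSummary:
    """Box-and-whisker statistics of step counts for one salt condition."""

    condition_label: str
    n_included: int
    n_excluded: Dict[str, int]
    mean: float
    median: float
    q25: float
    q75: float
    p10: float
    p90: float
    outliers: List[float] = field(default_factory=list)
    max_count: int = 0

    def to_dict(self) -> dict:
        return {
            "condition_label": self.condition_label,
            "n_included": self.n_included,
            "n_excluded": dict(self.n_excluded),
            "mean": self.mean,
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "p10": self.p10,
            "p90": self.p90,
            "outliers": list(self.outliers),
            "max_count": self.max_count,
        }


def summarize_condition(
    results: Sequence[StepCountResult], label: str
) -> ConditionSummary:
    """Summarize included step counts; percentiles by linear interpolation."""
    included = [r.k_steps for r in results if r.exclusion_reason is None]
    excluded: Dict[str, int] = {reason: 0 for reason in EXCLUSION_REASONS}
    for r in results:
        if r.exclusion_reason is not None:
            excluded[r.exclusion_reason] += 1
    if not included:
        raise EmptyCohortError(f"condition {label!r} has no included traces")
    counts = np.asarray(included, dtype=float)
    p10, q25, median, q75, p90 = np.percentile(
        counts, [10, 25, 50, 75, 90], method="linear"
    )
    outliers = sorted(float(c) for c in counts if c < p10 or c > p90)
    return ConditionSummary(
        condition_label=label,
        n_included=int(counts.size),
        n_excluded=excluded,
        mean=float(counts.mean()),
        median=float(median),
        q25=float(q25),
        q75=float(q75),
        p10=float(p10),
        p90=float(p90),
        outliers=outliers,
        max_count=int(counts.max()),
    )


def _ranksum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected normal-approximation z for the Wilcoxon rank-sum test."""
    combined = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float((r1 - mu) / math.sqrt(var))


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive permutation two-sided p for the rank-sum statistic."""
    combined = np.concatenate([a, b])
    n1 = a.size
    ranks = sps.rankdata(combined)
    observed = ranks[:n1].sum()
    mu = n1 * (ranks.size + 1) / 2.0
    dev = abs(observed - mu)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(ranks.size), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def compare_conditions(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 12
) -> Tuple[float, float]:
    """Distribution-free two-cohort comparison (Wilcoxon rank-sum).

    Returns (statistic, two-sided p-value).  The statistic is the
    tie-corrected normal-approximation z of cohort ``a``'s rank sum;
    swapping the cohorts flips its sign and leaves p unchanged.  For small
    cohorts (combined n <= ``exact_max_n``) the p-value is computed by
    exhaustive enumeration of all assignments, which is exact under ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InputError("each cohort needs at least 3 values")
    z = _ranksum_z(a, b)
    if a.size + b.size <= exact_max_n:
        p = _exact_two_sided_p(a, b)
    else:
        p = 2.0 * float(sps.norm.sf(abs(z)))
        p = min(p, 1.0)
    return z, p
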