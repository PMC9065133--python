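"""Exact change-point oracle for validating the step-count estimator.

Fits piecewise-constant models with m = 0..max_steps change points by exact
dynamic programming (globally minimal residual sum of squares for every m),
selects m by BIC, and reports the number of downward level transitions.
This is an independent route to the step count: it shares no machinery with
the pairwise-difference estimator and serves as its cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .errors import InputError, ParameterError
from .steps import TraceRecord

__all__ = ["oracle_step_count", "fit_piecewise_constant", "PiecewiseConstantFit"]


@dataclass
class PiecewiseConstantFit:
    """Selected piecewise-constant segmentation of a trace."""

    n_change_points: int
    change_points: np.ndarray  # frame indices where a new segment starts
    levels: np.ndarray  # mean of each segment, in time order
    rss: float
    bic: float

    @property
    def n_down_steps(self) -> int:
        return int(np.sum(np.diff(self.levels) < 0))


def _segment_cost_matrix(y: np.ndarray) -> np.ndarray:
    """cost[j, i] = RSS of fitting y[j:i] by its mean (inf for empty segments)."""
    n = y.size
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    idx = np.arange(n + 1, dtype=float)
    length = idx[None, :] - idx[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (s2[None, :] - s2[:, None]) - (s1[None, :] - s1[:, None]) ** 2 / length
    cost[length <= 0] = np.inf
    # Numerical noise can make tiny costs slightly negative.
    np.place(cost, (cost < 0) & np.isfinite(cost), 0.0)
    return cost


def fit_piecewise_constant(
    y: Sequence[float], max_steps: int = 20
) -> PiecewiseConstantFit:
    """Exact DP segmentation with BIC model selection.

    For each number of change points m the dynamic program finds the
    segmentation minimizing the residual sum of squares; the reported fit
    minimizes BIC(m) = n ln(RSS_m / n) + (2m + 1) ln(n), which charges one
    parameter per change-point location and per segment level plus one for
    the noise variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 2:
        raise InputError("segmentation needs a trace of length >= 2")
    if max_steps < 1:
        raise ParameterError("max_steps must be >= 1")
    if n < 2 * (max_steps + 1):
        reduced = max(1, n // 2 - 1)
        warnings.warn(
            f"trace of {n} frames too short for max_steps={max_steps}; "
            f"reducing to {reduced}",
            stacklevel=2,
        )
        max_steps = reduced

    cost = _segment_cost_matrix(y)
    n_models = max_steps + 1  # m = 0..max_steps change points
    # dp[s][i]: minimal cost of covering y[:i] with s+1 segments.
    dp = cost[0].copy()
    dp_by_m = [dp.copy()]
    backs = [np.zeros(n + 1, dtype=np.intp)]
    for s in range(1, n_models):
        cand = dp[:, None] + cost
        arg = np.argmin(cand, axis=0)
        dp = cand[arg, np.arange(n + 1)]
        backs.append(arg)
        dp_by_m.append(dp.copy())

    rss_floor = max(1e-12 * n * max(float(np.var(y)), 1e-12), 1e-300)
    best = None
    for m in range(n_models):
        rss = float(dp_by_m[m][n])
        if not np.isfinite(rss):
            continue
        bic = n * np.log(max(rss, rss_floor) / n) + (2 * m + 1) * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, m, rss)
    assert best is not None
    bic, m, rss = best

    # Backtrack segment boundaries for the selected model.
    bounds = [n]
    i = n
    for s in range(m, 0, -1):
        i = int(backs[s][i])
        bounds.append(i)
    bounds.append(0)
    bounds = np.array(bounds[::-1])
    levels = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    change_points = bounds[1:-1].copy()
    return PiecewiseConstantFit(
        n_change_points=m,
        change_points=change_points,
        levels=levels,
        rss=rss,
        bic=float(bic),
    )


def oracle_step_count(
    trace: Union[TraceRecord, Sequence[float]], max_steps: int = 20
) -> int:
    """Number of downward level transitions in the BIC-selected segmentation."""
    y = trace.intensity if isinstance(trace, TraceRecord) else trace
    return fit_piecewise_constant(y, max_steps=max_steps).n_down_steps
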