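"""Photobleaching step counting from single-spot intensity traces.

The estimator follows the pairwise-difference construction: for a trace
I(t_0..t_{n-1}) all n(n-1)/2 pairwise intensity differences between an
earlier and a later frame are pooled, a kernel density is formed over the
pooled differences, and the number of qualifying local maxima on the
positive axis is the step count.  For k equal-sized steps of unit size s the
pooled differences concentrate at 0, s, 2s, ..., ks, so the positive-side
peak count recovers k.

Sign convention: differences are stored as earlier-minus-later intensity,
so photobleaching (intensity loss over time) produces peaks on the positive
axis.  This is a pure relabeling of the later-minus-earlier expression.

Exclusion filters mirror the analysis cohort definition: spots brighter
than ``cy3_max`` (200 arb. units) in the Cy3 reference channel are dropped
as likely overlapping complexes, and traces with no photobleaching step or
an unstable bleaching profile are dropped after step estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import find_peaks

from .config import FilterParams
from .errors import InputError, ParameterError

__all__ = [
    "TraceRecord",
    "StepCountResult",
    "PairwiseDifferenceDensity",
    "pairwise_differences",
    "robust_noise_sd",
    "estimate_density",
    "estimate_step_count",
    "classify_unstable",
    "filter_trace",
    "evaluate_trace",
    "EXCLUSION_REASONS",
]

#: Valid exclusion reasons, in the order the filters are applied.
EXCLUSION_REASONS = ("edge_clipped", "bright_cy3", "unstable", "zero_steps")


@dataclass
class TraceRecord:
    """Per-spot Surf649 time series plus its Cy3 reference intensity.

    Parameters
    ----------
    spot_id : int
        Identifier of the detected spot within its field/cohort.
    t : ndarray
        Acquisition times in seconds, strictly increasing, uniformly spaced
        at 1/frame_rate.
    intensity : ndarray
        Background-subtracted Surf649 intensity I(t_i), arbitrary units.
    cy3_intensity : float
        Cy3 reference intensity of the spot (mean over the 5 initial Cy3
        frames), arbitrary units.
    condition_m : float or None
        NaCl molarity of the wash condition (0.2, 0.5 or 1.0 M).
    edge_clipped : bool
        True when the photometry aperture was clipped by the field edge.
    """

    spot_id: int
    t: np.ndarray
    intensity: np.ndarray
    cy3_intensity: float = 0.0
    condition_m: Optional[float] = None
    edge_clipped: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.ndim != 1 or self.intensity.ndim != 1:
            raise InputError("t and intensity must be 1-D arrays")
        if self.t.size != self.intensity.size:
            raise InputError("t and intensity must have equal length")
        if self.t.size < 2:
            raise InputError("trace must contain at least 2 frames")
        if not np.all(np.diff(self.t) > 0):
            raise InputError("t must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class StepCountResult:
    """Estimated bleaching-step count for one spot, with QC bookkeeping."""

    spot_id: int
    k_steps: int
    step_size_estimate: float = 0.0
    exclusion_reason: Optional[str] = None
    condition_m: Optional[float] = None
    cy3_intensity: float = 0.0
    peak_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_heights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.k_steps < 0:
            raise ParameterError("k_steps must be >= 0")
        if self.exclusion_reason is not None and self.exclusion_reason not in EXCLUSION_REASONS:
            raise ParameterError(f"unknown exclusion reason {self.exclusion_reason!r}")

    @property
    def included(self) -> bool:
        return self.exclusion_reason is None


@dataclass
class PairwiseDifferenceDensity:
    """Smoothed density of pooled pairwise differences plus its peak table."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    d_min: float
    peak_positions: np.ndarray
    peak_heights: np.ndarray
    peak_prominences: np.ndarray

    @property
    def n_peaks(self) -> int:
        return int(self.peak_positions.size)


def pairwise_differences(intensity: Sequence[float]) -> np.ndarray:
    """Pool all pairwise earlier-minus-later intensity differences.

    For a trace of length n returns exactly n(n-1)/2 values
    d = I(t_j) - I(t_i) for every frame pair with t_i > t_j, so that a loss
    of intensity over time (a bleaching step) yields positive differences.
    """
    x = np.asarray(intensity, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise InputError("pairwise differences need a trace of length >= 2")
    rows, cols = np.triu_indices(n, k=1)  # rows earlier, cols later
    return x[rows] - x[cols]


def robust_noise_sd(intensity: Sequence[float]) -> float:
    """Robust per-frame noise scale from successive differences.

    Uses median(|I_{i+1} - I_i|) / (sqrt(2) * 0.6745), which is insensitive
    to the (sparse) bleaching steps themselves.
    """
    x = np.asarray(intensity, dtype=float)
    if x.size < 2:
        raise InputError("noise estimate needs >= 2 frames")
    return float(np.median(np.abs(np.diff(x))) / (math.sqrt(2.0) * 0.6745))


def _merge_close_peaks(
    positions: np.ndarray, heights: np.ndarray, prominences: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedily cluster peaks closer than ``radius``; keep the tallest of each cluster."""
    if positions.size <= 1 or radius <= 0:
        return positions, heights, prominences
    order = np.argsort(positions)
    positions, heights, prominences = positions[order], heights[order], prominences[order]
    clusters: List[List[int]] = [[0]]
    for i in range(1, positions.size):
        if positions[i] - positions[clusters[-1][-1]] < radius:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    keep = [cluster[int(np.argmax(heights[cluster]))] for cluster in clusters]
    keep = np.asarray(keep)
    return positions[keep], heights[keep], prominences[keep]


def estimate_density(
    values: Sequence[float],
    noise_sd_hat: float,
    largest_drop: float = 0.0,
    *,
    prominence_frac: float = 0.002,
    merge_frac: float = 0.5,
    grid_points_per_bandwidth: int = 5,
) -> PairwiseDifferenceDensity:
    """Kernel density of pooled pairwise differences and its qualifying peaks.

    The Gaussian kernel bandwidth is h = max(noise_sd_hat, 0.05 * s_max)
    where ``largest_drop`` (s_max) is the largest single-frame intensity
    drop of the smoothed trace; the floor keeps the density non-degenerate
    for noiseless traces.  Candidate peaks are local maxima of the density
    restricted to d > d_min = max(3 * noise_sd_hat, 0.5 * h) (excluding the
    dominant zero-difference peak).  A candidate qualifies when its
    prominence is at least ``prominence_frac`` of the tallest positive-side
    peak; qualifying peaks closer than max(h, merge_frac * first-peak
    position) are merged to the taller one, since the pooled-difference
    construction cannot resolve sub-step spacings.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise InputError("estimate_density requires at least one value")
    if noise_sd_hat < 0:
        raise ParameterError("noise_sd_hat must be >= 0")
    if largest_drop < 0:
        largest_drop = 0.0

    h = max(float(noise_sd_hat), 0.05 * float(largest_drop))
    spread = float(np.ptp(vals))
    if h <= 0:
        h = 1e-3 * spread
    if h <= 0:
        # Fully degenerate input (all values identical): a single delta peak.
        center = float(vals[0])
        grid = np.array([center])
        density = np.array([np.inf])
        empty = np.empty(0)
        return PairwiseDifferenceDensity(grid, density, 0.0, 0.0, empty, empty, empty)

    d_min = max(3.0 * float(noise_sd_hat), 0.5 * h)

    step = h / float(grid_points_per_bandwidth)
    lo = float(vals.min()) - 4.0 * h
    hi = float(vals.max()) + 4.0 * h
    n_bins = int(math.ceil((hi - lo) / step))
    n_bins = max(n_bins, 8)
    if n_bins > 200_000:  # guard pathological bandwidths; widen the grid step
        n_bins = 200_000
        step = (hi - lo) / n_bins
    edges = lo + step * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    smoothed = gaussian_filter1d(counts.astype(float), sigma=h / step, mode="constant")
    density = smoothed / (vals.size * step)
    grid = 0.5 * (edges[:-1] + edges[1:])

    idx, props = find_peaks(density, prominence=0.0)
    if idx.size == 0:
        empty = np.empty(0)
        return PairwiseDifferenceDensity(grid, density, h, d_min, empty, empty, empty)
    positions = grid[idx]
    heights = density[idx]
    prominences = props["prominences"]

    positive = positions > d_min
    positions, heights, prominences = positions[positive], heights[positive], prominences[positive]
    if positions.size:
        ref_height = float(heights.max())
        qualify = prominences >= prominence_frac * ref_height
        positions, heights, prominences = (
            positions[qualify],
            heights[qualify],
            prominences[qualify],
        )
    if positions.size:
        merge_radius = max(h, merge_frac * float(positions.min()))
        positions, heights, prominences = _merge_close_peaks(
            positions, heights, prominences, merge_radius
        )
    return PairwiseDifferenceDensity(grid, density, h, d_min, positions, heights, prominences)


def smooth_trace(intensity: np.ndarray, window: int) -> np.ndarray:
    """Median-filter the trace; preserves step edges, suppresses outliers."""
    if window <= 1:
        return np.asarray(intensity, dtype=float)
    return median_filter(np.asarray(intensity, dtype=float), size=window, mode="nearest")


def estimate_step_count(
    trace: TraceRecord, params: Optional[FilterParams] = None
) -> StepCountResult:
    """Count photobleaching steps via the pairwise-difference density.

    Pipeline: median-smooth the trace -> robust noise estimate from raw
    successive differences -> pool pairwise differences of the smoothed
    trace -> kernel density -> count qualifying positive-side local maxima.
    The count is invariant to positive rescaling and additive offsets of the
    trace because every threshold is expressed relative to the trace's own
    noise and step scales.
    """
    params = params or FilterParams()
    smoothed = smooth_trace(trace.intensity, params.smoothing_window_frames)
    sd_hat = robust_noise_sd(trace.intensity)
    drops = -np.diff(smoothed)
    largest_drop = float(drops.max(initial=0.0))
    largest_drop = max(largest_drop, 0.0)

    if largest_drop <= 0 and float(np.ptp(smoothed)) <= 3.0 * sd_hat:
        # No intensity loss at all: constant (or monotonically rising) trace.
        return StepCountResult(
            spot_id=trace.spot_id,
            k_steps=0,
            step_size_estimate=0.0,
            condition_m=trace.condition_m,
            cy3_intensity=trace.cy3_intensity,
        )

    values = pairwise_differences(smoothed)
    dens = estimate_density(
        values,
        sd_hat,
        largest_drop,
        prominence_frac=params.peak_prominence_frac,
        merge_frac=params.peak_merge_frac,
    )
    k = dens.n_peaks
    step_size = float(dens.peak_positions[0]) if k else largest_drop
    return StepCountResult(
        spot_id=trace.spot_id,
        k_steps=k,
        step_size_estimate=step_size,
        condition_m=trace.condition_m,
        cy3_intensity=trace.cy3_intensity,
        peak_positions=dens.peak_positions,
        peak_heights=dens.peak_heights,
    )


def classify_unstable(
    trace: TraceRecord,
    step_size_estimate: float,
    params: Optional[FilterParams] = None,
) -> bool:
    """Flag unstable bleaching profiles.

    A trace is unstable when its median-smoothed profile contains an upward
    single-frame transition larger than ``instability_jump_factor`` times
    the estimated unit step (re-brightening), or when the mean of its final
    10% of frames exceeds ``incomplete_bleach_frac`` (default 20%) of the
    mean of its initial 10% (incomplete bleaching).
    """
    params = params or FilterParams()
    if step_size_estimate <= 0:
        # No bleaching step at all (constant trace): not "unstable" -- it
        # falls through to the zero-step exclusion instead.
        return False
    smoothed = smooth_trace(trace.intensity, params.smoothing_window_frames)
    sd_hat = robust_noise_sd(trace.intensity)

    rises = np.diff(smoothed)
    if float(rises.max(initial=0.0)) > params.instability_jump_factor * step_size_estimate:
        return True

    n = smoothed.size
    n10 = max(1, int(round(0.1 * n)))
    initial_mean = float(np.mean(smoothed[:n10]))
    final_mean = float(np.mean(smoothed[-n10:]))
    # Only meaningful when the trace actually starts above the noise floor.
    if initial_mean > 3.0 * sd_hat and final_mean > params.incomplete_bleach_frac * initial_mean:
        return True
    return False


def filter_trace(
    trace: TraceRecord,
    params: Optional[FilterParams] = None,
    result: Optional[StepCountResult] = None,
) -> Optional[str]:
    """Return the exclusion reason for a trace, or None if it passes.

    Checks are applied in a fixed order so every excluded trace carries
    exactly one reason: edge_clipped -> bright_cy3 -> unstable ->
    zero_steps.  The last two require a step-count ``result`` and are
    skipped when it is not supplied (pre-estimation screening).
    """
    params = params or FilterParams()
    if trace.edge_clipped:
        return "edge_clipped"
    if trace.cy3_intensity > params.cy3_max:
        return "bright_cy3"
    if result is not None:
        if classify_unstable(trace, result.step_size_estimate, params):
            return "unstable"
        if result.k_steps < params.require_steps_min:
            return "zero_steps"
    return None


def evaluate_trace(trace: TraceRecord, params: Optional[FilterParams] = None) -> StepCountResult:
    """Full per-trace evaluation: screening, step counting, post-filters."""
    params = params or FilterParams()
    pre_reason = filter_trace(trace, params)
    if pre_reason is not None:
        return StepCountResult(
            spot_id=trace.spot_id,
            k_steps=0,
            exclusion_reason=pre_reason,
            condition_m=trace.condition_m,
            cy3_intensity=trace.cy3_intensity,
        )
    result = estimate_step_count(trace, params)
    result.exclusion_reason = filter_trace(trace, params, result)
    return result
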