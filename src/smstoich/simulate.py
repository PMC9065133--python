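"""Synthetic two-channel TIRF data with known ground truth.

Emulates the acquisition the analysis was designed for: immobilized
intasomes carrying 0-16 Surf649-labeled LEDGF/p75 subunits are imaged on a
512 x 512 EMCCD field (160 nm pixels); a 5-frame Cy3 snapshot marks
intasome positions, then a 3-minute Surf649 movie at 5 Hz records stepwise
photobleaching.  Site occupancy is binomial over the sixteen binding sites,
bleaching is geometric in frames (discrete exponential), per-fluorophore
unit intensities are drawn once and held until bleaching, and camera noise
is additive Gaussian (optional Poisson shot noise at field level).

Reproducibility: every intasome draws from its own RNG substream derived
from ``SeedSequence(seed, spawn_key=(index,))``, so per-trace output is
independent of batch size and bit-identical under a fixed (config, seed).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import FieldConfig, SimulationConfig
from .errors import ParameterError
from .imaging import ImageStack
from .steps import TraceRecord
from .units import time_axis

__all__ = [
    "rng_for_complex",
    "simulate_occupancy",
    "simulate_trace",
    "simulate_cohort",
    "simulate_resolvable_trace",
    "simulate_field",
    "inject_jump",
    "N_CY3_SNAPSHOT_FRAMES",
]

#: Number of Cy3 snapshot frames flanking the Surf649 movie.
N_CY3_SNAPSHOT_FRAMES = 5

GROUND_TRUTH_COLUMNS = [
    "complex_id",
    "x_px",
    "y_px",
    "k_true",
    "n_labeled",
    "cy3_true",
    "bleach_frames",
    "overlap_flag",
]


def rng_for_complex(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-intasome RNG substream, independent of batch size."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_occupancy(
    config: SimulationConfig, n_complexes: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw labeled-subunit counts: Binomial(n_sites, occupancy_p * labeling_efficiency)."""
    if n_complexes < 1:
        raise ParameterError("n_complexes must be >= 1")
    p = config.occupancy_p * config.labeling_efficiency
    return rng.binomial(config.n_sites, p, size=int(n_complexes))


def _draw_unit_intensities(k: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-fluorophore unit intensities, Normal(mean, cv*mean) truncated > 0."""
    if k == 0:
        return np.empty(0)
    sd = config.unit_step_cv * config.unit_step_mean
    units = rng.normal(config.unit_step_mean, sd, size=k)
    while np.any(units <= 0):
        bad = units <= 0
        units[bad] = rng.normal(config.unit_step_mean, sd, size=int(bad.sum()))
    return units


def _draw_bleach_frames(k: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Last bright frame of each fluorophore: geometric(bleach_rate) - 1.

    A fluorophore is bright during frames 0..b inclusive and dark from
    b + 1 on, so every trace starts at full intensity and the mean bleach
    frame is 1/bleach_rate - 1.  Values >= n_frames mean the fluorophore
    survived the movie.
    """
    if k == 0:
        return np.empty(0, dtype=int)
    return rng.geometric(config.bleach_rate, size=k) - 1


def _draw_cy3(config: SimulationConfig, rng: np.random.Generator) -> float:
    """Single-intasome Cy3 reference intensity, Normal truncated > 0."""
    val = rng.normal(config.cy3_mean, config.cy3_sd)
    while val <= 0:
        val = rng.normal(config.cy3_mean, config.cy3_sd)
    return float(val)


def simulate_trace(
    k_true: int,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    spot_id: int = 0,
    cy3_intensity: Optional[float] = None,
) -> Tuple[TraceRecord, np.ndarray]:
    """Simulate one background-subtracted Surf649 photobleaching trace.

    Intensity at frame t is the sum of unit intensities of the fluorophores
    still active at t plus Gaussian read noise.  Returns the trace and the
    true bleach frames (one per labeled fluorophore).
    """
    if k_true < 0 or k_true > config.n_sites:
        raise ParameterError(f"k_true must be in [0, {config.n_sites}], got {k_true}")
    rng = rng or np.random.default_rng(config.seed)
    units = _draw_unit_intensities(k_true, config, rng)
    bleach = _draw_bleach_frames(k_true, config, rng)
    frames = np.arange(config.n_frames)
    active = frames[:, None] <= bleach[None, :] if k_true else np.zeros((config.n_frames, 0), bool)
    signal = active @ units if k_true else np.zeros(config.n_frames)
    noise = rng.normal(0.0, config.noise_sd, size=config.n_frames) if config.noise_sd > 0 else 0.0
    if cy3_intensity is None:
        cy3_intensity = _draw_cy3(config, rng)
    trace = TraceRecord(
        spot_id=spot_id,
        t=time_axis(config.n_frames, config.frame_rate_hz),
        intensity=signal + noise,
        cy3_intensity=cy3_intensity,
        condition_m=config.condition_m,
    )
    return trace, bleach


def simulate_resolvable_trace(
    config: SimulationConfig,
    k_true: int,
    rng: np.random.Generator,
    min_plateau_frames: int = 5,
    tail_frames: int = 25,
    max_attempts: int = 10_000,
    spot_id: int = 0,
) -> Tuple[TraceRecord, np.ndarray]:
    """Simulate a trace conditioned on containing k temporally resolved steps.

    Redraws until every fluorophore bleaches at least ``tail_frames`` before
    the end of the movie and consecutive bleach events (and the first one)
    are separated by at least ``min_plateau_frames`` frames, so each of the
    k intensity levels is long enough to survive median smoothing.  Used by
    benchmarks that quantify counting accuracy given resolvable steps.
    """
    for _ in range(max_attempts):
        trace, bleach = simulate_trace(k_true, config, rng, spot_id=spot_id)
        if k_true == 0:
            return trace, bleach
        b = np.sort(bleach)
        gaps = np.diff(b)
        if (
            b[-1] < config.n_frames - tail_frames
            and b[0] >= min_plateau_frames - 1
            and (gaps.size == 0 or gaps.min() >= min_plateau_frames)
        ):
            return trace, bleach
    raise RuntimeError(
        f"could not draw a resolvable k={k_true} trace in {max_attempts} attempts"
    )


def simulate_cohort(
    config: SimulationConfig, n_traces: int, seed: Optional[int] = None
) -> Tuple[List[TraceRecord], pd.DataFrame]:
    """Simulate a cohort of independent single-intasome traces.

    Each trace uses its own RNG substream keyed by (seed, index).  Returns
    the traces and a ground-truth table (one row per intasome).
    """
    if n_traces < 1:
        raise ParameterError("n_traces must be >= 1")
    seed = config.seed if seed is None else seed
    traces: List[TraceRecord] = []
    records = []
    for i in range(int(n_traces)):
        rng = rng_for_complex(seed, i)
        k = int(simulate_occupancy(config, 1, rng)[0])
        trace, bleach = simulate_trace(k, config, rng, spot_id=i)
        traces.append(trace)
        records.append(
            {
                "complex_id": i,
                "x_px": np.nan,
                "y_px": np.nan,
                "k_true": k,
                "n_labeled": k,
                "cy3_true": trace.cy3_intensity,
                "bleach_frames": list(map(int, bleach)),
                "overlap_flag": False,
            }
        )
    truth = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    return traces, truth


def inject_jump(trace: TraceRecord, frame: int, height: float) -> TraceRecord:
    """Artifact injector: add a persistent upward intensity jump at ``frame``.

    Emulates the unstable bleaching profiles (re-brightening) that the
    analysis excludes; used to exercise the instability filter with known
    ground truth.
    """
    if not 0 <= frame < len(trace):
        raise ParameterError("jump frame outside trace")
    intensity = trace.intensity.copy()
    intensity[frame:] += height
    return TraceRecord(
        spot_id=trace.spot_id,
        t=trace.t.copy(),
        intensity=intensity,
        cy3_intensity=trace.cy3_intensity,
        condition_m=trace.condition_m,
        edge_clipped=trace.edge_clipped,
    )


def _gaussian_patch(sigma_px: float) -> Tuple[np.ndarray, int]:
    """Unit-sum discrete 2-D Gaussian kernel and its half-width."""
    r = int(np.ceil(4.0 * sigma_px)) + 1
    ax = np.arange(-r, r + 1)
    g = np.exp(-0.5 * (ax / sigma_px) ** 2)
    kernel = np.outer(g, g)
    kernel /= kernel.sum()
    return kernel, r


def _render_spot(canvas: np.ndarray, x: float, y: float, flux: np.ndarray, kernel: np.ndarray, r: int) -> None:
    """Add flux[t] * kernel at (x, y) to every frame of ``canvas`` in place.

    ``canvas`` is (n_frames, h, w); ``flux`` is scalar-per-frame.  The
    kernel is placed at the nearest integer pixel with a subpixel shift
    folded into the kernel via bilinear interpolation of the center.
    """
    n, h, w = canvas.shape
    cx, cy = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - cx, y - cy
    # Bilinear split of the subpixel position over the four neighbor pixels.
    weights = [
        ((0, 0), (1 - fx) * (1 - fy)),
        ((1, 0), fx * (1 - fy)),
        ((0, 1), (1 - fx) * fy),
        ((1, 1), fx * fy),
    ]
    for (dx, dy), wgt in weights:
        if wgt == 0:
            continue
        px, py = cx + dx, cy + dy
        y0, y1 = py - r, py + r + 1
        x0, x1 = px - r, px + r + 1
        ky0, kx0 = max(0, -y0), max(0, -x0)
        ky1 = kernel.shape[0] - max(0, y1 - h)
        kx1 = kernel.shape[1] - max(0, x1 - w)
        if ky0 >= ky1 or kx0 >= kx1:
            continue
        sub = kernel[ky0:ky1, kx0:kx1] * wgt
        canvas[:, max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)] += (
            flux[:, None, None] * sub[None]
        )


def simulate_field(
    sim: SimulationConfig,
    field: FieldConfig,
    seed: Optional[int] = None,
    aperture_radius_px: float = 4.875,
    render_movie: bool = True,
) -> Tuple[ImageStack, Optional[ImageStack], pd.DataFrame]:
    """Render one two-channel field of view with ground truth.

    Returns (cy3_stack, surf_stack, ground_truth): a 5-frame Cy3 snapshot
    stack with one Gaussian spot per intasome, the Surf649 movie in which
    each spot's amplitude follows its photobleaching time course (or None
    when ``render_movie`` is False and only the Cy3 channel is needed, e.g.
    for detection-density studies), and the per-intasome truth table.  The
    spot count is Poisson with mean ``n_spots_mean``; positions are uniform
    and subpixel; ``overlap_flag`` marks intasomes with a neighbor closer
    than one detection-aperture radius.
    """
    seed = sim.seed if seed is None else seed
    field_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xF1E1D,)))
    n_spots = int(field_rng.poisson(field.n_spots_mean))
    h, w = field.height_px, field.width_px
    kernel, r = _gaussian_patch(field.psf_sigma_px)

    # Static additive background: level + linear gradient across x + offset.
    xg = np.arange(w, dtype=float)
    gradient = field.background_gradient * (xg / max(w - 1, 1))
    base = field.camera_offset + field.background_level + gradient[None, :]
    base = np.broadcast_to(base, (h, w)).astype(np.float32)

    records = []
    positions = np.empty((n_spots, 2))
    per_spot = []
    for i in range(n_spots):
        rng = rng_for_complex(seed, i + 1)
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        k_occ = int(rng.binomial(sim.n_sites, sim.occupancy_p))
        n_labeled = int(rng.binomial(k_occ, sim.labeling_efficiency)) if k_occ else 0
        units = _draw_unit_intensities(n_labeled, sim, rng)
        bleach = _draw_bleach_frames(n_labeled, sim, rng)
        cy3_true = _draw_cy3(sim, rng)
        positions[i] = (x, y)
        per_spot.append((units, bleach, cy3_true))
        records.append(
            {
                "complex_id": i,
                "x_px": x,
                "y_px": y,
                "k_true": k_occ,
                "n_labeled": n_labeled,
                "cy3_true": cy3_true,
                "bleach_frames": list(map(int, bleach)),
                "overlap_flag": False,
            }
        )
    truth = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    if n_spots > 1:
        d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        truth["overlap_flag"] = (d2.min(axis=1) < aperture_radius_px**2).tolist()

    def _noisy(canvas: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if field.shot_noise:
            canvas = rng.poisson(np.clip(canvas, 0, None)).astype(np.float32)
        if field.read_noise_sd > 0:
            noise = rng.standard_normal(canvas.shape, dtype=np.float32)
            canvas = canvas + field.read_noise_sd * noise
        return canvas

    # Cy3 snapshot stack: constant spot amplitude per intasome.
    cy3 = np.zeros((N_CY3_SNAPSHOT_FRAMES, h, w), dtype=np.float32)
    cy3 += base[None]
    flat = np.ones(N_CY3_SNAPSHOT_FRAMES)
    for (x, y), (units, bleach, cy3_true) in zip(positions, per_spot):
        _render_spot(cy3, x, y, cy3_true * flat, kernel, r)
    cy3 = _noisy(cy3, np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC73,))))
    cy3_stack = ImageStack(cy3, field.pixel_size_um, "Cy3", sim.frame_rate_hz)

    surf_stack = None
    if render_movie:
        movie = np.zeros((sim.n_frames, h, w), dtype=np.float32)
        movie += base[None]
        frames = np.arange(sim.n_frames)
        for (x, y), (units, bleach, _) in zip(positions, per_spot):
            if units.size == 0:
                continue
            flux = (frames[:, None] <= bleach[None, :]) @ units
            _render_spot(movie, x, y, flux, kernel, r)
        movie = _noisy(
            movie, np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x5A9F,)))
        )
        surf_stack = ImageStack(movie, field.pixel_size_um, "Surf649", sim.frame_rate_hz)
    return cy3_stack, surf_stack, truth
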