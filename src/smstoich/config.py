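"""Configuration dataclasses and the salt-series simulation presets.

Defaults mirror the printed acquisition and analysis settings of the
experiment: a 512 x 512 EMCCD field with 160 nm pixels, 5 Hz sampling of a
3-minute (900 frame) Surf649 movie flanked by 5-frame Cy3 snapshots, spot
detection at 0.78 um radius and contrast 14.5 after "advanced denoising" at
strength 5 and rolling-ball background subtraction with r = 0.48 um, and a
Cy3 brightness cutoff of 200 arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ParameterError, UnknownPresetError
from .units import DEFAULT_FRAME_RATE_HZ, DEFAULT_PIXEL_SIZE_UM


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for one immobilized intasome's fluorescence record.

    The intasome presents ``n_sites`` LEDGF/p75 binding sites (sixteen, one
    per integrase subunit).  Each site is independently occupied with
    probability ``occupancy_p``; an occupied site carries an active Surf649
    fluorophore with probability ``labeling_efficiency``.  Each active
    fluorophore contributes a constant unit intensity (drawn once, mean
    ``unit_step_mean`` with coefficient of variation ``unit_step_cv``) until
    it photobleaches; bleaching is geometric in frames with per-frame
    probability ``bleach_rate``, the discrete analogue of exponential-in-time
    photobleaching.  Gaussian read noise of standard deviation ``noise_sd``
    is added per frame.

    The default ``bleach_rate`` of 0.005/frame gives an expected bleaching
    completeness of 1 - 0.995**900 ~ 0.989 over the 900-frame movie,
    consistent with >95% photobleaching within the acquisition window.
    """

    n_sites: int = 16
    occupancy_p: float = 0.375
    labeling_efficiency: float = 1.0
    unit_step_mean: float = 50.0
    unit_step_cv: float = 0.15
    bleach_rate: float = 0.005
    noise_sd: float = 7.5  # 0.15 * unit_step_mean
    n_frames: int = 900
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    cy3_mean: float = 100.0
    cy3_sd: float = 25.0
    seed: int = 0
    condition_m: Optional[float] = None  # NaCl molarity label carried onto traces

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_p <= 1.0:
            raise ParameterError(f"occupancy_p must be in [0, 1], got {self.occupancy_p}")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise ParameterError(
                f"labeling_efficiency must be in [0, 1], got {self.labeling_efficiency}"
            )
        if self.n_sites < 0:
            raise ParameterError(f"n_sites must be >= 0, got {self.n_sites}")
        if self.n_frames < 2:
            raise ParameterError(f"n_frames must be >= 2, got {self.n_frames}")
        if not 0.0 < self.bleach_rate <= 1.0:
            raise ParameterError(f"bleach_rate must be in (0, 1], got {self.bleach_rate}")
        for name in ("unit_step_mean", "cy3_mean", "cy3_sd", "frame_rate_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.unit_step_cv < 0 or self.noise_sd < 0:
            raise ParameterError("unit_step_cv and noise_sd must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FieldConfig:
    """Rendering model for one two-channel field of view.

    ``width_px * pixel_size_um`` reproduces the acquisition field extent:
    512 px x 0.16 um = 81.92 um per edge.  Spots are rendered as 2-D Gaussian
    point-spread functions on an additive background (constant level plus a
    linear gradient), a constant camera offset, and per-pixel Gaussian read
    noise of standard deviation ``read_noise_sd``.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_spots_mean: float = 400.0
    psf_sigma_um: float = 0.13
    background_level: float = 10.0
    background_gradient: float = 5.0  # total additive ramp across the field width
    camera_offset: float = 100.0
    read_noise_sd: float = 1.0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ParameterError("field dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.n_spots_mean < 0:
            raise ParameterError("n_spots_mean must be >= 0")
        if self.psf_sigma_um <= 0:
            raise ParameterError("psf_sigma_um must be > 0")
        if self.read_noise_sd < 0:
            raise ParameterError("read_noise_sd must be >= 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um


@dataclass(frozen=True)
class DetectionParams:
    """Bright-spot detection settings (printed analysis constants).

    ``spot_radius_um`` = 0.78 um is the detection aperture radius (4.875 px at
    160 nm pixels, kept fractional); ``contrast_min`` = 14.5 is the minimum
    robust signal-to-noise contrast score; ``denoise_strength`` = 5 maps to a
    Gaussian blur of sigma = strength/5 px; ``rolling_ball_radius_um`` =
    0.48 um (3 px) sets the background structuring element.
    """

    spot_radius_um: float = 0.78
    contrast_min: float = 14.5
    denoise_strength: float = 5.0
    rolling_ball_radius_um: float = 0.48

    def __post_init__(self) -> None:
        if self.spot_radius_um <= 0 or self.rolling_ball_radius_um <= 0:
            raise ParameterError("radii must be > 0")
        if self.contrast_min < 0:
            raise ParameterError("contrast_min must be >= 0")
        if self.denoise_strength < 0:
            raise ParameterError("denoise_strength must be >= 0")

    def spot_radius_px(self, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
        return self.spot_radius_um / pixel_size_um


@dataclass(frozen=True)
class FilterParams:
    """Trace inclusion/exclusion settings and step-estimator knobs.

    ``cy3_max`` = 200 arb. units is the brightness cutoff above which a Cy3
    spot likely contains overlapping intasomes.  Traces with no detectable
    photobleaching step or an unstable bleaching profile (re-brightening
    jumps, incomplete bleaching) are excluded.  The estimator knobs
    (``peak_prominence_frac``, ``peak_merge_frac``) govern local-maxima
    qualification on the pairwise-difference density; see
    :mod:`smstoich.steps`.
    """

    cy3_max: float = 200.0
    require_steps_min: int = 1
    instability_jump_factor: float = 1.0
    smoothing_window_frames: int = 5
    incomplete_bleach_frac: float = 0.2
    peak_prominence_frac: float = 0.002
    peak_merge_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.cy3_max <= 0:
            raise ParameterError("cy3_max must be > 0")
        if self.smoothing_window_frames < 1 or self.smoothing_window_frames % 2 == 0:
            raise ParameterError("smoothing_window_frames must be odd and >= 1")
        if not 0 < self.peak_prominence_frac <= 1:
            raise ParameterError("peak_prominence_frac must be in (0, 1]")
        if self.peak_merge_frac < 0:
            raise ParameterError("peak_merge_frac must be >= 0")


#: Mean LEDGF/p75 subunits per intasome observed at each NaCl concentration,
#: used to calibrate per-site occupancy of the 16-site binomial model.
CONDITION_MEANS = {
    "salt_0.2M": (0.2, 6.0),
    "salt_0.5M": (0.5, 4.0),
    "salt_1.0M": (1.0, 2.0),
}


def condition_preset(name: str) -> SimulationConfig:
    """Return the simulation preset for one NaCl wash condition.

    The per-site occupancy probability is calibrated so the binomial mean
    ``n_sites * occupancy_p`` equals the observed per-condition average
    (6, 4 and 2 subunits at 0.2, 0.5 and 1.0 M NaCl).
    """
    try:
        molarity, mean_subunits = CONDITION_MEANS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown condition preset {name!r}; known: {sorted(CONDITION_MEANS)}"
        ) from None
    base = SimulationConfig()
    return base.with_(occupancy_p=mean_subunits / base.n_sites, condition_m=molarity)
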