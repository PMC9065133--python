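"""Physical-unit conversions used throughout the pipeline.

All micrometre <-> pixel and frame <-> second conversions funnel through this
module so the acquisition geometry (160 nm pixels, 5 Hz sampling) is applied
consistently everywhere.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

#: Camera pixel edge length of the EMCCD acquisition geometry (micrometres).
DEFAULT_PIXEL_SIZE_UM: float = 0.16

#: Continuous-sampling frame rate of the photobleaching movies (Hz).
DEFAULT_FRAME_RATE_HZ: float = 5.0


def um_to_px(length_um: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a physical length in micrometres to (fractional) pixels."""
    if pixel_size_um <= 0:
        raise ParameterError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return float(length_um) / float(pixel_size_um)


def px_to_um(length_px: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a length in pixels to micrometres."""
    if pixel_size_um <= 0:
        raise ParameterError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return float(length_px) * float(pixel_size_um)


def time_axis(n_frames: int, frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> np.ndarray:
    """Return the acquisition time of each frame in seconds, t_i = i / rate."""
    if frame_rate_hz <= 0:
        raise ParameterError(f"frame_rate_hz must be > 0, got {frame_rate_hz}")
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1, got {n_frames}")
    return np.arange(int(n_frames), dtype=float) / float(frame_rate_hz)
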