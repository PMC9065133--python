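"""File formats: multi-page TIFF stacks with YAML sidecars, CSV tables
(ground truth, long-format traces, per-spot counts), JSON summaries and
YAML config echoes."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InputError
from .imaging import ImageStack
from .stats import ConditionSummary
from .steps import StepCountResult, TraceRecord
from .units import DEFAULT_FRAME_RATE_HZ, DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "write_stack",
    "read_stack",
    "ground_truth_to_csv",
    "ground_truth_from_csv",
    "traces_to_dataframe",
    "traces_from_dataframe",
    "traces_from_csv",
    "write_traces_csv",
    "counts_to_dataframe",
    "write_counts_csv",
    "write_summary_json",
    "write_config_echo",
]


def _sidecar_path(path: Union[str, Path]) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".yaml")


def write_stack(stack: ImageStack, path: Union[str, Path]) -> Path:
    """Write a stack as 16-bit multi-page TIFF (frame order = time order).

    Pixel values are clipped to [0, 65535] and rounded; acquisition
    metadata (pixel size, frame rate, channel) goes to a YAML sidecar.
    """
    path = Path(path)
    frames = np.clip(np.round(np.asarray(stack.frames, dtype=float)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames)
    meta = {
        "pixel_size_um": float(stack.pixel_size_um),
        "frame_rate_hz": float(stack.frame_rate_hz),
        "channel_label": stack.channel_label,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))
    return path


def read_stack(
    path: Union[str, Path],
    pixel_size_um: Optional[float] = None,
    frame_rate_hz: Optional[float] = None,
    channel_label: Optional[str] = None,
) -> ImageStack:
    """Read a multi-page TIFF stack; metadata from the YAML sidecar or flags."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such stack: {path}")
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # malformed file or mixed frame shapes
        raise InputError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.dtype == object or frames.ndim not in (2, 3):
        raise InputError(f"stack {path} has inconsistent frame shapes")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    return ImageStack(
        frames=frames.astype(float),
        pixel_size_um=pixel_size_um or meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM),
        channel_label=channel_label or meta.get("channel_label", "Cy3"),
        frame_rate_hz=frame_rate_hz or meta.get("frame_rate_hz", DEFAULT_FRAME_RATE_HZ),
    )


def ground_truth_to_csv(truth: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write the ground-truth table; bleach frames semicolon-joined."""
    out = truth.copy()
    out["bleach_frames"] = out["bleach_frames"].apply(
        lambda frames: ";".join(str(int(f)) for f in frames)
    )
    out.to_csv(path, index=False)
    return Path(path)


def ground_truth_from_csv(path: Union[str, Path]) -> pd.DataFrame:
    truth = pd.read_csv(path)
    truth["bleach_frames"] = truth["bleach_frames"].apply(
        lambda s: [int(x) for x in str(s).split(";")] if isinstance(s, str) and s else []
    )
    return truth


def traces_to_dataframe(traces: Sequence[TraceRecord]) -> pd.DataFrame:
    """Long format: one row per spot-frame."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "spot_id": tr.spot_id,
                    "condition": tr.condition_m,
                    "frame": np.arange(len(tr)),
                    "time_s": tr.t,
                    "surf649_intensity": tr.intensity,
                    "cy3_intensity": tr.cy3_intensity,
                    "edge_clipped": tr.edge_clipped,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=[
                "spot_id",
                "condition",
                "frame",
                "time_s",
                "surf649_intensity",
                "cy3_intensity",
                "edge_clipped",
            ]
        )
    return pd.concat(parts, ignore_index=True)


def traces_from_dataframe(df: pd.DataFrame) -> List[TraceRecord]:
    """Rebuild TraceRecords from a long-format trace table."""
    traces: List[TraceRecord] = []
    if df.empty:
        return traces
    for (spot_id, condition), grp in df.groupby(["spot_id", "condition"], dropna=False, sort=True):
        grp = grp.sort_values("frame")
        traces.append(
            TraceRecord(
                spot_id=int(spot_id),
                t=grp["time_s"].to_numpy(),
                intensity=grp["surf649_intensity"].to_numpy(),
                cy3_intensity=float(grp["cy3_intensity"].iloc[0]),
                condition_m=None if pd.isna(condition) else float(condition),
                edge_clipped=bool(grp["edge_clipped"].iloc[0]) if "edge_clipped" in grp else False,
            )
        )
    return traces


def traces_from_csv(path: Union[str, Path]) -> List[TraceRecord]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such trace table: {path}")
    return traces_from_dataframe(pd.read_csv(path))


def write_traces_csv(traces: Sequence[TraceRecord], path: Union[str, Path]) -> Path:
    traces_to_dataframe(traces).to_csv(path, index=False)
    return Path(path)


def counts_to_dataframe(results: Sequence[StepCountResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot_id": [r.spot_id for r in results],
            "condition": [r.condition_m for r in results],
            "k_steps": [r.k_steps for r in results],
            "exclusion_reason": [r.exclusion_reason or "" for r in results],
            "step_size_estimate": [r.step_size_estimate for r in results],
            "cy3_intensity": [r.cy3_intensity for r in results],
        }
    )


def write_counts_csv(results: Sequence[StepCountResult], path: Union[str, Path]) -> Path:
    counts_to_dataframe(results).to_csv(path, index=False)
    return Path(path)


def write_summary_json(
    summaries: Dict[str, ConditionSummary], path: Union[str, Path]
) -> Path:
    payload = {label: s.to_dict() for label, s in summaries.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return Path(path)


def write_config_echo(config: object, path: Union[str, Path]) -> Path:
    """Echo any (nested) dataclass config as YAML for reproducibility."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    Path(path).write_text(yaml.safe_dump(convert(config), sort_keys=True))
    return Path(path)
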