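"""Reading and writing of frame stacks and fluorescence traces.

The pipeline's raw unit of video analysis is the :class:`FrameStack`: an
ordered set of equally shaped grayscale frames acquired at a fixed frame
interval. Timestamps always derive from ``index * frame_interval`` — never
from container metadata — mirroring fixed-rate extraction of video clips at
one frame every tenth of a second. Calcium recordings are represented as a
:class:`CalciumTrace` on a uniform time grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FrameStack",
    "CalciumTrace",
    "FormatError",
    "extract_frames",
    "load_frame_stack",
    "write_frame_stack",
    "mean_roi_fluorescence",
    "read_trace_csv",
    "write_trace_csv",
]

#: relative tolerance for declaring a time grid uniform
_GRID_RTOL = 1e-9


class FormatError(ValueError):
    """Raised when an on-disk source violates the expected layout."""


@dataclass(frozen=True)
class FrameStack:
    """Ordered grayscale frames with a fixed inter-frame interval.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``.
    frame_interval
        Seconds between consecutive frames (> 0).
    origin
        Free-text recording identifier carried through to outputs.
    """

    frames: np.ndarray
    frame_interval: float
    origin: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a (n>=1, h, w) array")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Timestamp of frame *k* is ``k * frame_interval`` seconds."""
        return np.arange(len(self)) * self.frame_interval

    @property
    def duration(self) -> float:
        return len(self) * self.frame_interval


@dataclass(frozen=True)
class CalciumTrace:
    """Fluorescence intensity (a.u.) sampled on a uniform time grid (s)."""

    time: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1 or t.size < 1:
            raise ValueError("time and fluorescence must be equal-length 1-D arrays")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > _GRID_RTOL * max(abs(dt[0]), 1.0):
                raise ValueError("time grid must be uniform")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)

    def __len__(self) -> int:
        return self.time.size

    @property
    def frame_interval(self) -> float:
        if len(self) < 2:
            raise ValueError("need >= 2 samples for a frame interval")
        return float(self.time[1] - self.time[0])


def _to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse a color frame to grayscale by unweighted channel mean."""
    if frame.ndim == 3:
        return frame.mean(axis=-1)
    return frame


def _load_native(source) -> np.ndarray:
    """Return raw frames (n, h, w) from an array, stack, TIFF or directory."""
    if isinstance(source, FrameStack):
        return source.frames
    if isinstance(source, np.ndarray):
        if source.ndim == 4:  # (n, h, w, channels)
            return np.stack([_to_grayscale(f) for f in source])
        if source.ndim != 3:
            raise FormatError("frame array must be 3-D (n, h, w)")
        return source
    path = Path(source)
    if path.is_dir():
        return _load_frame_dir(path)
    if not path.exists():
        raise FormatError(f"no such video source: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4:
            arr = np.stack([_to_grayscale(f) for f in arr])
        return arr
    # generic container via imageio (best effort; brightfield sources are TIFF)
    arr = np.asarray(iio.imread(path, index=None))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:
        arr = np.stack([_to_grayscale(f) for f in arr])
    return arr


def _load_frame_dir(path: Path) -> np.ndarray:
    exts = {".tif", ".tiff", ".png", ".jpg", ".jpeg", ".bmp"}
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in exts)
    if not files:
        raise FormatError(f"no frame images found in {path}")
    frames = [_to_grayscale(np.asarray(iio.imread(p))) for p in files]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"mixed frame shapes in {path}: {sorted(shapes)}")
    return np.stack(frames)


def extract_frames(
    source,
    frame_interval: float,
    *,
    source_interval: Optional[float] = None,
    origin: str = "",
) -> FrameStack:
    """Sample a recording at a fixed interval, one frame per time step.

    ``source`` may be an in-memory array, an existing :class:`FrameStack`
    (whose own interval supplies ``source_interval``), a multi-page TIFF, a
    directory of frames, or any container imageio can decode. The output
    holds ``floor(duration / frame_interval)`` frames, each the native frame
    nearest the requested timestamp; color input is converted to grayscale by
    channel averaging.
    """
    if not frame_interval > 0:
        raise ValueError("frame_interval must be > 0")
    if isinstance(source, FrameStack) and source_interval is None:
        source_interval = source.frame_interval
    native = _load_native(source)
    if source_interval is None:
        raise ValueError("source_interval is required for sources without timing")
    if not source_interval > 0:
        raise ValueError("source_interval must be > 0")
    duration = native.shape[0] * source_interval
    n_out = int(np.floor(duration / frame_interval + 1e-9))
    if n_out < 1:
        raise ValueError("recording shorter than one frame interval")
    want = np.arange(n_out) * frame_interval
    idx = np.clip(np.round(want / source_interval).astype(int), 0, native.shape[0] - 1)
    return FrameStack(native[idx].copy(), frame_interval, origin=origin or str(source))


def load_frame_stack(path, frame_interval: float, *, origin: str = "") -> FrameStack:
    """Load a TIFF stack or a directory of single-frame images.

    Frames are ordered by TIFF page index or lexicographic filename.
    """
    if not frame_interval > 0:
        raise ValueError("frame_interval must be > 0")
    frames = _load_native(Path(path))
    return FrameStack(frames, frame_interval, origin=origin or str(path))


def write_frame_stack(stack: FrameStack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF (dtype preserved)."""
    tifffile.imwrite(os.fspath(path), np.asarray(stack.frames))


def mean_roi_fluorescence(stack: FrameStack, mask: Union[np.ndarray, str, None] = "whole-frame") -> CalciumTrace:
    """Mean intensity per frame over a region of interest.

    ``mask`` is a boolean image matching the frame shape, or ``"whole-frame"``
    / ``None`` for the full field of view.
    """
    frames = stack.frames
    if mask is None or (isinstance(mask, str) and mask == "whole-frame"):
        values = frames.reshape(len(stack), -1).mean(axis=1)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != frames.shape[1:]:
            raise ValueError("mask shape must match frame shape")
        if not mask.any():
            raise ValueError("ROI mask is empty")
        values = frames[:, mask].mean(axis=1)
    return CalciumTrace(stack.times, values)


def write_trace_csv(trace: CalciumTrace, path, *, header_lines: Sequence[str] = ()) -> None:
    """Write a trace as 2-column CSV (time_s, fluorescence_au)."""
    df = pd.DataFrame({"time_s": trace.time, "fluorescence_au": trace.fluorescence})
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_trace_csv(path) -> CalciumTrace:
    """Read a 2-column CSV trace written by :func:`write_trace_csv`."""
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError("trace CSV needs two columns (time_s, fluorescence_au)")
    return CalciumTrace(df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float))
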