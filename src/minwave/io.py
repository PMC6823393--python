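"""Reading and writing calibrated image stacks.

Stacks are stored as multi-page TIFF in TCYX order (time, channel, row,
column), 16-bit for raw movies.  Physical calibration (pixel size in µm,
frame interval in s) travels in a JSON sidecar written next to the TIFF,
because plain TIFF has no standard slot for a frame interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """A T-frame, C-channel pixel array with physical calibration.

    data has shape (T, C, Y, X); pixel_size is µm per pixel and
    frame_interval is seconds per frame.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel: T, Y, X -> T, 1, Y, X
            self.data = self.data[:, None, :, :]
        if self.data.ndim != 4:
            raise ValueError(f"stack must be TCYX, got shape {self.data.shape}")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel(self, index: int) -> np.ndarray:
        """Return the (T, Y, X) array for one channel."""
        if not 0 <= index < self.n_channels:
            raise IndexError(
                f"channel {index} out of range for {self.n_channels}-channel stack"
            )
        return self.data[:, index]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: ImageStack, *, dtype=np.uint16,
                extra_metadata: dict | None = None) -> Path:
    """Write a stack as TCYX TIFF plus a JSON calibration sidecar.

    Raw movies are clipped/rounded to ``dtype`` (default 16-bit unsigned);
    pass ``dtype=np.float32`` for derived images such as kymographs.
    """
    path = Path(path)
    data = stack.data
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(dtype)
    else:
        data = data.astype(dtype)
    tifffile.imwrite(path, data, metadata={"axes": "TCYX"})
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "channel_names": list(stack.channel_names),
    }
    if extra_metadata:
        meta.update(extra_metadata)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path, *, pixel_size: float | None = None,
               frame_interval: float | None = None,
               channel_map: dict[str, int] | None = None) -> ImageStack:
    """Read a TCYX TIFF stack with its calibration.

    Calibration comes from the JSON sidecar written by :func:`write_stack`;
    explicit ``pixel_size`` / ``frame_interval`` arguments override it and
    are required when no sidecar exists.  ``channel_map`` (name -> index) is
    validated against the stack's channel count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]
    elif data.ndim != 4:
        raise ValueError(f"cannot resolve axes of shape {data.shape} to TCYX")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise ValueError(
            f"{path}: missing calibration (no sidecar); pass pixel_size and "
            "frame_interval explicitly"
        )
    names = tuple(meta.get("channel_names", ()))
    stack = ImageStack(data, float(px), float(dt), names)
    if channel_map:
        bad = {k: v for k, v in channel_map.items() if not 0 <= v < stack.n_channels}
        if bad:
            raise ValueError(
                f"channel_map entries {bad} out of range for "
                f"{stack.n_channels}-channel stack"
            )
    return stack
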