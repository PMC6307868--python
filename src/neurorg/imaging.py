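"""Imaging metadata and the in-memory image-stack container.

All physical quantities are in micrometres and seconds; pixel indices are
0-based ``(row, col)`` and physical position is ``index * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry and timing.

    Defaults emulate confocal time-lapse imaging of cultured hippocampal
    neurons: 0.08 um pixels, one frame every 5 s, 97 frames (96 intervals =
    480 s, about 8 minutes).
    """

    pixel_size: float = 0.08
    frame_interval: float = 5.0
    n_frames: int = 97
    frame_shape: tuple[int, int] = (512, 512)
    channels: tuple[str, ...] = ("PO", "MITO")

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 16:
            raise ValueError("frame_shape must be 2-D and at least 16 px")

    @property
    def duration(self) -> float:
        """Session length in seconds (n_frames - 1 intervals)."""
        return (self.n_frames - 1) * self.frame_interval

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size


@dataclass
class ImageStack:
    """A time-ordered set of 2-D frames per channel.

    ``channels`` maps channel name -> array of shape (T, H, W).  Single-frame
    (fixed-cell) data uses T = 1.
    """

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    config: ImagingConfig = field(default_factory=ImagingConfig)

    def __post_init__(self) -> None:
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be (T, H, W)")
            if arr.shape[1:] != tuple(self.config.frame_shape):
                raise ValueError(
                    f"channel {name!r} shape {arr.shape[1:]} != frame_shape "
                    f"{tuple(self.config.frame_shape)}"
                )

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} missing; have {sorted(self.channels)}")
        return self.channels[name]
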