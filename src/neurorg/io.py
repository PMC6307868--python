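"""Fixture I/O: multi-page TIFF per channel plus JSON/CSV ground truth.

Each channel is written as an ImageJ-style multi-page TIFF with resolution
and frame-interval tags; a ``meta.json`` sidecar carries the acquisition
metadata at full float precision (the TIFF rational tags are for
interoperability).  Ground truth goes to ``truth.json`` and planted tracks to
``tracks.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FixtureIOError
from .imaging import ImageStack, ImagingConfig
from .truth import GroundTruth

META_NAME = "meta.json"
TRUTH_NAME = "truth.json"
TRACKS_NAME = "tracks.csv"


def write_fixture(stack: ImageStack, truth: GroundTruth | None, directory: str | Path) -> Path:
    """Write a fixture directory; returns the directory path."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        cfg = stack.config
        for name, arr in stack.channels.items():
            axes = "TYX" if arr.shape[0] > 1 else "YX"
            data = arr if arr.shape[0] > 1 else arr[0]
            tifffile.imwrite(
                directory / f"{name}.tif",
                data,
                imagej=True,
                resolution=(1.0 / cfg.pixel_size, 1.0 / cfg.pixel_size),
                metadata={
                    "axes": axes,
                    "unit": "um",
                    "finterval": cfg.frame_interval,
                },
            )
        meta = {
            "pixel_size_um": cfg.pixel_size,
            "frame_interval_s": cfg.frame_interval,
            "n_frames": int(next(iter(stack.channels.values())).shape[0]),
            "frame_shape": list(cfg.frame_shape),
            "channels": sorted(stack.channels),
        }
        (directory / META_NAME).write_text(json.dumps(meta, indent=1))
        if truth is not None:
            truth.to_json(directory / TRUTH_NAME)
            if truth.tracks:
                rows = []
                for t in truth.tracks:
                    for frame in range(len(t.path_pos_um)):
                        rows.append(
                            {
                                "track_id": t.track_id,
                                "frame": frame,
                                "x_um": t.px[frame, 1] * cfg.pixel_size,
                                "y_um": t.px[frame, 0] * cfg.pixel_size,
                                "organelle": t.organelle,
                                "planted_class": t.planted_class,
                            }
                        )
                pd.DataFrame(rows).to_csv(directory / TRACKS_NAME, index=False)
    except OSError as exc:
        raise FixtureIOError(f"writing fixture to {directory}: {exc}") from exc
    return directory


def read_fixture(directory: str | Path) -> tuple[ImageStack, GroundTruth | None]:
    """Read a fixture directory back into an ImageStack (+ GroundTruth if present)."""
    directory = Path(directory)
    meta_path = directory / META_NAME
    if not meta_path.exists():
        raise FixtureIOError(f"{meta_path} not found")
    meta = json.loads(meta_path.read_text())
    channels: dict[str, np.ndarray] = {}
    for name in meta["channels"]:
        path = directory / f"{name}.tif"
        if not path.exists():
            raise FixtureIOError(f"channel file {path} missing")
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        channels[name] = arr
    config = ImagingConfig(
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_s"],
        n_frames=max(meta["n_frames"], 2),
        frame_shape=tuple(meta["frame_shape"]),
        channels=tuple(meta["channels"]),
    )
    truth = None
    truth_path = directory / TRUTH_NAME
    if truth_path.exists():
        truth = GroundTruth.from_json(truth_path)
    return ImageStack(channels=channels, config=config), truth
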