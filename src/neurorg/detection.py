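"""Organelle detection: Gaussian blur, mask-restricted Otsu, component labelling.

Each frame is smoothed (sigma 1 px for peroxisomes, 2 px for mitochondria),
an Otsu threshold is computed from the smoothed values *inside the analysis
mask only*, the masked frame is binarised at that threshold, and 8-connected
components of at least ``min_size`` pixels become regions with
intensity-weighted centroids in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, NamedTuple

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyMaskError
from .imaging import ImageStack

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import SegmentationMasks

EIGHT = np.ones((3, 3), dtype=bool)


class OtsuResult(NamedTuple):
    threshold: float
    degenerate: bool


@dataclass(frozen=True)
class DetectionParams:
    sigma: float = 1.0        # px; 1 for PO, 2 for mitochondria; 0 = no blur
    min_size: int = 4         # px, single-pixel-noise filter
    connectivity: int = 8
    min_contrast_sigma: float = 4.0  # foreground must exceed background by k*sd
    max_fg_fraction: float = 0.15    # larger foregrounds are structured background

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class Region:
    """One detected organelle region in one frame."""

    frame_index: int
    label: int
    centroid_um: tuple[float, float]   # (x, y) = (col, row) * pixel_size
    centroid_px: tuple[float, float]   # (row, col)
    pixel_count: int
    area_um2: float
    bbox: tuple[int, int, int, int]    # (rmin, cmin, rmax, cmax), half-open
    coords: np.ndarray | None = None   # (N, 2) pixel indices, optional


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> OtsuResult:
    """Threshold maximising between-class variance over a 256-bin histogram.

    Only the provided values enter the histogram.  A constant input returns
    that value with the degenerate flag set.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError("otsu_threshold needs at least 2 values")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return OtsuResult(vmin, True)
    hist, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    hist = hist.astype(np.float64)
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(hist)
    w1 = total - w0
    m0 = np.cumsum(hist * centers)
    mtot = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mtot - m0) / w1
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    var_between = var_between[:-1]
    # the variance is flat across an empty gap between modes: take the
    # plateau midpoint so the cut is stable against last-ulp noise
    vmax_var = var_between.max()
    ties = np.nonzero(var_between >= vmax_var * (1 - 1e-10))[0]
    k = int(ties[len(ties) // 2])  # cut after bin k
    return OtsuResult(float(edges[k + 1]), False)


def detect_regions(
    frame: np.ndarray,
    mask: np.ndarray,
    params: DetectionParams,
    pixel_size: float,
    frame_index: int = 0,
    fallback_threshold: float | None = None,
    keep_coords: bool = False,
) -> tuple[list[Region], OtsuResult]:
    """Detect organelle regions in one frame restricted to ``mask``.

    Degenerate (constant) masked frames fall back to ``fallback_threshold``
    (typically the previous frame's threshold) when given.
    """
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    if not mask.any():
        raise EmptyMaskError("analysis mask is empty (no mask, not 'no detections')")
    smoothed = np.asarray(frame, dtype=np.float32)
    if params.sigma > 0:
        smoothed = ndi.gaussian_filter(smoothed, params.sigma)
    vals = smoothed[mask]
    result = otsu_threshold(vals)
    thr = result.threshold
    if result.degenerate and fallback_threshold is not None:
        thr = fallback_threshold
    # the masked histogram may be trimodal (ambient / neurite tube / spots);
    # when the first cut puts an implausibly large fraction in the foreground
    # it has split the structured background, so re-threshold within it
    for _ in range(3):
        fg = vals[vals > thr]
        if fg.size <= params.max_fg_fraction * vals.size:
            break
        inner = otsu_threshold(fg)
        if inner.degenerate:
            break
        thr = inner.threshold
    # organelle-free frames are then unimodal: require the foreground class
    # to stand clear of the background spread, else report no detections
    bg = vals[vals <= thr]
    fg = vals[vals > thr]
    if fg.size == 0 or bg.size < 2:
        return [], result
    if fg.mean() - bg.mean() < params.min_contrast_sigma * max(bg.std(), 1e-12):
        return [], result
    result = OtsuResult(thr, result.degenerate)
    binary = (smoothed > thr) & mask
    labels, n = ndi.label(binary, structure=EIGHT)
    regions: list[Region] = []
    if n == 0:
        return regions, result
    counts = np.bincount(labels.ravel())
    objects = ndi.find_objects(labels)
    # intensity-weighted centroids; weights are smoothed excess over threshold
    weights = np.clip(smoothed - thr, 0, None)
    for lab in range(1, n + 1):
        if counts[lab] < params.min_size:
            continue
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        w = weights[sl] * sub
        wsum = float(w.sum())
        rr, cc = np.mgrid[sl[0].start : sl[0].stop, sl[1].start : sl[1].stop]
        if wsum > 0:
            row = float((w * rr).sum() / wsum)
            col = float((w * cc).sum() / wsum)
        else:
            row = float(rr[sub].mean())
            col = float(cc[sub].mean())
        regions.append(
            Region(
                frame_index=frame_index,
                label=lab,
                centroid_um=(col * pixel_size, row * pixel_size),
                centroid_px=(row, col),
                pixel_count=int(counts[lab]),
                area_um2=float(counts[lab]) * pixel_size**2,
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                coords=np.argwhere(labels == lab) if keep_coords else None,
            )
        )
    return regions, result


def detect_stack(
    stack: ImageStack,
    masks: "SegmentationMasks",
    params_by_channel: dict[str, DetectionParams] | None = None,
    channels: list[str] | None = None,
) -> dict[str, list[list[Region]]]:
    """Per-frame detection for every requested channel within the neurite mask.

    Returns ``{channel: [regions of frame 0, regions of frame 1, ...]}``.
    Degenerate Otsu frames inherit the previous frame's threshold.
    """
    params_by_channel = params_by_channel or {
        "PO": DetectionParams(sigma=1.0),
        "MITO": DetectionParams(sigma=2.0),
    }
    channels = channels or [c for c in stack.channels if c in params_by_channel]
    out: dict[str, list[list[Region]]] = {}
    for name in channels:
        arr = stack.channel(name)
        params = params_by_channel.get(name, DetectionParams())
        frames: list[list[Region]] = []
        prev_thr: float | None = None
        for t in range(arr.shape[0]):
            regions, result = detect_regions(
                arr[t],
                masks.neurite_mask,
                params,
                stack.config.pixel_size,
                frame_index=t,
                fallback_threshold=prev_thr,
            )
            if not result.degenerate:
                prev_thr = result.threshold
            frames.append(regions)
        out[name] = frames
    return out


def regions_to_frame(detections: dict[str, list[list[Region]]]):
    """Flatten detections into a tidy DataFrame."""
    import pandas as pd

    rows = []
    for channel, frames in detections.items():
        for regs in frames:
            for r in regs:
                rows.append(
                    {
                        "frame": r.frame_index,
                        "channel": channel,
                        "label": r.label,
                        "x_um": r.centroid_um[0],
                        "y_um": r.centroid_um[1],
                        "area_um2": r.area_um2,
                        "pixel_count": r.pixel_count,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["frame", "channel", "label", "x_um", "y_um", "area_um2", "pixel_count"],
    )
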