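"""Neuron segmentation: Frangi ridge tracing and scale-space DoG soma detection.

The neurite tracer follows the Canny recipe adapted to ridges: a multi-scale
Frangi vesselness map is thinned by non-maximal suppression across the ridge,
then double-thresholded with hysteresis (weak ridge pixels survive only when
8-connected to a strong seed), and finally dilated to the physical neurite
width to form an analysis mask.  The soma is the largest object detected by a
max-over-scales Difference-of-Gaussian filter and is subtracted (with a small
safety margin) from the neurite mask so organelles are never detected inside
the soma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .detection import otsu_threshold
from .errors import NoSomaFound
from .imaging import ImageStack

EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FrangiParams:
    """Vesselness parameters.  gamma=None -> half the max Hessian norm per scale."""

    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    beta: float = 0.5
    gamma: float | None = None

    def __post_init__(self) -> None:
        if not self.scales or min(self.scales) <= 0:
            raise ValueError("scales must be non-empty and positive")


@dataclass(frozen=True)
class DogParams:
    """Soma detector parameters (scales in px of the full-resolution image)."""

    scales: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0, 40.0)
    ratio: float = 1.6
    open_radius_px: int = 12
    soma_margin_px: int = 3
    downsample: int = 1           # integer decimation before filtering


@dataclass
class RidgeMap:
    strength: np.ndarray       # >= 0, 0 on constant images
    orientation: np.ndarray    # ridge tangent direction, radians
    scales_used: list[float]


@dataclass
class SegmentationMasks:
    soma_mask: np.ndarray
    neurite_mask: np.ndarray       # excludes the soma
    soma_centroid: tuple[float, float]


def frangi_response(image: np.ndarray, params: FrangiParams | None = None) -> RidgeMap:
    """Per-pixel maximum over scales of the Frangi vesselness (bright ridges).

    The orientation channel holds the ridge tangent (minor-eigenvector
    direction) at the scale achieving the maximum response.
    """
    params = params or FrangiParams()
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    best = np.zeros_like(image)
    best_theta = np.zeros_like(image)
    if float(image.max()) == float(image.min()):
        # constant image: zero Hessian, zero vesselness by definition
        return RidgeMap(strength=best, orientation=best_theta,
                        scales_used=list(params.scales))
    for sigma in params.scales:
        # scale-normalised Hessian
        hrr = sigma**2 * ndi.gaussian_filter(image, sigma, order=(2, 0))
        hrc = sigma**2 * ndi.gaussian_filter(image, sigma, order=(1, 1))
        hcc = sigma**2 * ndi.gaussian_filter(image, sigma, order=(0, 2))
        tr_half = (hrr + hcc) / 2.0
        disc = np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc**2)
        ea = tr_half + disc
        eb = tr_half - disc
        swap = np.abs(ea) > np.abs(eb)
        lam1 = np.where(swap, eb, ea)   # smaller magnitude
        lam2 = np.where(swap, ea, eb)   # larger magnitude
        s_norm = np.sqrt(lam1**2 + lam2**2)
        gamma = params.gamma if params.gamma is not None else 0.5 * float(s_norm.max())
        if gamma <= 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(lam2 != 0, (lam1 / lam2) ** 2, 0.0)
        v = np.exp(-rb2 / (2 * params.beta**2)) * (
            1.0 - np.exp(-(s_norm**2) / (2 * gamma**2))
        )
        v = np.where(lam2 < 0, v, 0.0)  # bright-ridge polarity
        # eigenvector of lam2 (cross-ridge normal); tangent is perpendicular
        vr = np.where(np.abs(hrc) > 1e-12, hrc, lam2 - hcc)
        vc = np.where(np.abs(hrc) > 1e-12, lam2 - hrr, np.abs(hrc))
        normal_theta = np.arctan2(vc, vr)
        better = v > best
        best_theta = np.where(better, normal_theta + np.pi / 2.0, best_theta)
        best = np.where(better, v, best)
    return RidgeMap(strength=best, orientation=best_theta, scales_used=list(params.scales))


def _non_max_suppress(strength: np.ndarray, tangent: np.ndarray) -> np.ndarray:
    """Suppress pixels that are not local maxima across the ridge direction."""
    normal = tangent + np.pi / 2.0
    angle = np.mod(normal, np.pi)
    # quantise the cross-ridge direction into 4 bins
    bins = np.round(angle / (np.pi / 4.0)).astype(int) % 4
    # angle is atan2(col, row): bin 0 -> step along rows, bin 2 -> along cols
    shifts = {0: (1, 0), 1: (1, 1), 2: (0, 1), 3: (-1, 1)}
    out = np.zeros_like(strength)
    for b, (dr, dc) in shifts.items():
        sel = bins == b
        fwd = np.roll(strength, (-dr, -dc), axis=(0, 1))
        back = np.roll(strength, (dr, dc), axis=(0, 1))
        keep = sel & (strength >= fwd) & (strength >= back) & (strength > 0)
        out[keep] = strength[keep]
    return out


def auto_thresholds(nms_strength: np.ndarray, noise_mult: float = 8.0) -> tuple[float, float]:
    """Hysteresis thresholds from the thinned vesselness map.

    ``high`` is the Otsu threshold of the nonzero thinned strengths (separating
    structure ridges from the noise floor); ``low`` is ``noise_mult`` times the
    median nonzero strength.  The median is dominated by noise ridges, so the
    low threshold tracks the noise floor rather than the brightest structures
    and dim neurite tubes survive next to bright organelle trails.
    """
    nonzero = nms_strength[nms_strength > 0]
    if nonzero.size < 2:
        return 0.0, 0.0
    high = otsu_threshold(nonzero).threshold
    low = min(noise_mult * float(np.median(nonzero)), high)
    return low, high


def trace_neurites(
    ridge: RidgeMap,
    low: float,
    high: float,
    dilate_px: int = 0,
) -> np.ndarray:
    """Canny-style ridge tracing: NMS, double threshold, 8-connected hysteresis.

    Returns the kept thinned set, dilated by ``dilate_px`` (0 = raw trace).
    """
    if low > high:
        raise ValueError(f"low ({low}) must be <= high ({high})")
    if low < 0:
        raise ValueError("thresholds must be non-negative")
    nms = _non_max_suppress(ridge.strength, ridge.orientation)
    weak = nms >= low if low > 0 else nms > 0
    labels, n = ndi.label(weak, structure=EIGHT)
    if n == 0:
        kept = np.zeros_like(weak)
    else:
        maxima = ndi.maximum(nms, labels, index=np.arange(1, n + 1))
        good = np.concatenate([[False], maxima >= high])
        kept = good[labels]
    if dilate_px > 0:
        rr, cc = np.mgrid[-dilate_px : dilate_px + 1, -dilate_px : dilate_px + 1]
        disk = rr**2 + cc**2 <= dilate_px**2
        kept = ndi.binary_dilation(kept, structure=disk)
    return kept


def _disk(radius: int) -> np.ndarray:
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return rr**2 + cc**2 <= radius**2


def detect_soma(image: np.ndarray, params: DogParams | None = None) -> np.ndarray:
    """Scale-space DoG soma detection: largest thresholded object.

    The max-over-scales DoG response is Otsu-thresholded, holes filled,
    thin (neurite-width) appendages removed by a morphological opening, and
    the largest 8-connected component taken as the soma seed.  Because the
    positive DoG response ends inside the true intensity edge, the seed is
    then refined to the matching component of an intensity-level Otsu
    threshold computed around the seed, which restores the full soma area.
    """
    params = params or DogParams()
    full_shape = np.asarray(image).shape
    ds = max(1, int(params.downsample))
    work = np.asarray(image, dtype=np.float32)[::ds, ::ds]
    resp = np.full(work.shape, -np.inf, dtype=np.float32)
    for sigma in params.scales:
        s = sigma / ds
        dog = ndi.gaussian_filter(work, s) - ndi.gaussian_filter(work, params.ratio * s)
        resp = np.maximum(resp, dog)
    thr = otsu_threshold(resp.ravel())
    binary = resp > thr.threshold
    binary = ndi.binary_fill_holes(binary)
    r = int(round(params.open_radius_px / ds))
    if r > 0:
        binary = ndi.binary_opening(binary, structure=_disk(r))
    labels, n = ndi.label(binary, structure=EIGHT)
    if n == 0:
        raise NoSomaFound("no soma candidate after DoG thresholding")
    counts = np.bincount(labels.ravel())[1:]
    seed = labels == (int(np.argmax(counts)) + 1)
    soma = ndi.binary_fill_holes(_refine_soma(work, seed, r))
    if ds > 1:
        soma = np.repeat(np.repeat(soma, ds, axis=0), ds, axis=1)[
            : full_shape[0], : full_shape[1]
        ]
        pad0 = full_shape[0] - soma.shape[0]
        pad1 = full_shape[1] - soma.shape[1]
        if pad0 > 0 or pad1 > 0:
            soma = np.pad(soma, ((0, pad0), (0, pad1)), mode="edge")
    return soma


def _refine_soma(work: np.ndarray, seed: np.ndarray, open_radius: int) -> np.ndarray:
    """Grow the DoG seed out to the intensity edge of the soma.

    Otsu of the image values in a window around the seed separates the bright
    cell fill from background; thin attached neurites are cut by the same
    opening radius, and the component overlapping the seed most is kept.
    Falls back to the seed when refinement finds nothing.
    """
    rows = np.any(seed, axis=1).nonzero()[0]
    cols = np.any(seed, axis=0).nonzero()[0]
    h, w = work.shape
    rh = max(1, (rows[-1] - rows[0]) // 2)
    cw = max(1, (cols[-1] - cols[0]) // 2)
    r0, r1 = max(0, rows[0] - rh), min(h, rows[-1] + rh + 1)
    c0, c1 = max(0, cols[0] - cw), min(w, cols[-1] + cw + 1)
    window = work[r0:r1, c0:c1]
    # half-max edge criterion: midway between the fill level (median inside
    # the seed, insensitive to bright organelles) and the local background
    ring = np.ones_like(seed)
    ring[r0:r1, c0:c1] = False
    ring |= ndi.binary_dilation(seed, structure=_disk(max(2 * open_radius, 2)))
    outside = work[(~ring)[: h, : w]] if (~ring).any() else None
    fill_level = float(np.median(work[seed]))
    bg_level = float(np.median(outside)) if outside is not None and outside.size else 0.0
    if fill_level <= bg_level:
        return seed
    level = 0.5 * (fill_level + bg_level)
    bright = np.zeros_like(seed)
    bright[r0:r1, c0:c1] = window > level
    bright = ndi.binary_fill_holes(bright)
    if open_radius > 0:
        bright = ndi.binary_opening(bright, structure=_disk(open_radius))
    labels, n = ndi.label(bright, structure=EIGHT)
    if n == 0:
        return seed
    overlap = np.bincount(labels[seed].ravel(), minlength=n + 1)[1:]
    if overlap.max() == 0:
        return seed
    return labels == (int(np.argmax(overlap)) + 1)


def finalize_masks(
    neurite_candidates: np.ndarray,
    soma_mask: np.ndarray,
    margin_px: int = 3,
) -> SegmentationMasks:
    """Subtract the (dilated) soma from the neurite candidates."""
    if neurite_candidates.shape != soma_mask.shape:
        raise ValueError("mask shapes differ")
    if margin_px > 0:
        rr, cc = np.mgrid[-margin_px : margin_px + 1, -margin_px : margin_px + 1]
        disk = rr**2 + cc**2 <= margin_px**2
        soma_grown = ndi.binary_dilation(soma_mask, structure=disk)
    else:
        soma_grown = soma_mask
    neurite = neurite_candidates & ~soma_grown
    if soma_mask.any():
        com = ndi.center_of_mass(soma_mask)
    else:
        com = (float("nan"), float("nan"))
    return SegmentationMasks(
        soma_mask=soma_mask.astype(bool),
        neurite_mask=neurite.astype(bool),
        soma_centroid=(float(com[0]), float(com[1])),
    )


def segmentation_input(stack: ImageStack) -> np.ndarray:
    """Sum of per-channel temporal maximum projections."""
    out = None
    for arr in stack.channels.values():
        proj = arr.max(axis=0).astype(np.float64)
        out = proj if out is None else out + proj
    if out is None:
        raise ValueError("stack has no channels")
    return out


def segment_image(
    image: np.ndarray,
    pixel_size: float,
    neurite_width: float = 1.2,
    frangi_params: FrangiParams | None = None,
    dog_params: DogParams | None = None,
    noise_mult: float = 8.0,
) -> SegmentationMasks:
    """Full segmentation chain on a 2-D projection image.

    Vesselness runs on a log-compressed copy so dim neurite tubes survive the
    per-image gamma normalisation next to bright organelle trails; the DoG
    soma detector sees the linear image.
    """
    dog_params = dog_params or DogParams()
    ridge = frangi_response(np.log1p(np.clip(image, 0, None)), frangi_params)
    nms = _non_max_suppress(ridge.strength, ridge.orientation)
    low, high = auto_thresholds(nms, noise_mult)
    dilate_px = max(1, int(round(neurite_width / 2.0 / pixel_size)))
    thin = trace_neurites(ridge, low, high, dilate_px=0)
    soma = detect_soma(image, dog_params)
    # the soma rim responds as a closed ridge; drop trace pixels hugging the
    # boundary before dilation so the neurite mask does not ring the soma
    rim = dog_params.soma_margin_px + dilate_px
    rr, cc = np.mgrid[-rim : rim + 1, -rim : rim + 1]
    soma_grown = ndi.binary_dilation(soma, structure=rr**2 + cc**2 <= rim**2)
    thin &= ~soma_grown
    rr, cc = np.mgrid[-dilate_px : dilate_px + 1, -dilate_px : dilate_px + 1]
    candidates = ndi.binary_dilation(thin, structure=rr**2 + cc**2 <= dilate_px**2)
    return finalize_masks(candidates, soma, margin_px=dog_params.soma_margin_px)
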