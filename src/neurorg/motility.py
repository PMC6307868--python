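"""Per-track and cohort motility statistics, classification and kymographs.

Definitions (all distances um, speeds um/s):

* per-interval displacement ``d_i``: Euclidean centroid step between
  consecutive frames; steps below ``displacement_floor`` (default 0.1 um,
  1.25 px) count as zero for distance accumulation, suppressing
  sub-resolution localisation jitter;
* ``total_distance`` = sum of floored steps; ``net_distance`` = straight-line
  first-to-last displacement;
* instantaneous speed = unfloored ``d_i / frame_interval``; ``max_speed`` is
  its maximum; ``avg_speed`` = total_distance / track duration (this
  definition reproduces the printed pair 3.6 um over 480 s = 0.0075 um/s);
* motility classes on total distance: static [0, 1), very short [1, 5),
  short [5, 10), long [10, inf) um (half-open on the shared endpoints).

Directionality is signed by the change of within-mask geodesic distance to
the soma: moving away from the soma (anterograde) is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import KymographError, TrackOutsideMaskError
from .geodesic import geodesic_distance
from .segmentation import SegmentationMasks
from .tracking import Track

MOTILITY_CLASSES = ("static", "very_short", "short", "long")
_CLASS_EDGES = np.array([1.0, 5.0, 10.0])


@dataclass
class MotilitySummary:
    track_id: int
    max_speed: float
    avg_speed: float
    total_distance: float
    net_distance: float
    motility_class: str
    signed_net_along_path: float | None = None
    n_samples: int = 0
    duration_s: float = 0.0
    instantaneous_speeds: np.ndarray = field(default_factory=lambda: np.zeros(0))
    moving_speeds: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class CohortSummary:
    n_tracks: int
    class_fractions: dict[str, float]
    mean_avg_speed: float
    mean_max_speed: float
    mean_total_distance: float
    ecdf_speeds: tuple[np.ndarray, np.ndarray]
    ecdf_distances: tuple[np.ndarray, np.ndarray]


@dataclass
class Kymograph:
    data: np.ndarray              # (n_frames, path length px)
    path: np.ndarray              # resampled polyline, (cols, 2) px
    width: int


def classify_motility(total_distance: float) -> str:
    """Class lookup: static < 1, very short [1, 5), short [5, 10), long >= 10 um."""
    if total_distance < 0:
        raise ValueError("total_distance must be >= 0")
    return MOTILITY_CLASSES[int(np.searchsorted(_CLASS_EDGES, total_distance, side="right"))]


def track_statistics(
    track: Track, frame_interval: float, displacement_floor: float = 0.1
) -> MotilitySummary:
    """Per-track speeds, distances and motility class."""
    if len(track) < 2:
        raise ValueError("track needs at least 2 samples")
    steps = np.linalg.norm(np.diff(track.xy_um, axis=0), axis=1)
    floored = np.where(steps < displacement_floor, 0.0, steps)
    total = float(floored.sum())
    net = float(np.linalg.norm(track.xy_um[-1] - track.xy_um[0]))
    inst = steps / frame_interval
    duration = float((track.frames[-1] - track.frames[0]) * frame_interval)
    moving = floored[floored > 0] / frame_interval
    return MotilitySummary(
        track_id=track.track_id,
        max_speed=float(inst.max()),
        avg_speed=total / duration if duration > 0 else 0.0,
        total_distance=total,
        net_distance=net,
        motility_class=classify_motility(total),
        n_samples=len(track),
        duration_s=duration,
        instantaneous_speeds=inst,
        moving_speeds=moving,
    )


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: (sorted values, cumulative fractions)."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, len(x) + 1) / len(x) if len(x) else np.zeros(0)
    return x, y


def cohort_summary(summaries: list[MotilitySummary]) -> CohortSummary:
    """Cohort fractions, means and pooled ECDFs."""
    if not summaries:
        raise ValueError("cohort_summary needs at least one track summary")
    n = len(summaries)
    fractions = {
        cls: sum(1 for s in summaries if s.motility_class == cls) / n
        for cls in MOTILITY_CLASSES
    }
    pooled = np.concatenate([s.instantaneous_speeds for s in summaries]) if n else np.zeros(0)
    return CohortSummary(
        n_tracks=n,
        class_fractions=fractions,
        mean_avg_speed=float(np.mean([s.avg_speed for s in summaries])),
        mean_max_speed=float(np.mean([s.max_speed for s in summaries])),
        mean_total_distance=float(np.mean([s.total_distance for s in summaries])),
        ecdf_speeds=ecdf(pooled),
        ecdf_distances=ecdf(np.array([s.total_distance for s in summaries])),
    )


def soma_distance_map(masks: SegmentationMasks, pixel_size: float) -> np.ndarray:
    """Geodesic distance (um) to the soma boundary within the neurite mask."""
    grown = ndi.binary_dilation(masks.soma_mask, structure=np.ones((9, 9), dtype=bool))
    seeds = grown & masks.neurite_mask
    return geodesic_distance(masks.neurite_mask, seeds, pixel_size)


def directionality(
    track: Track,
    masks: SegmentationMasks,
    pixel_size: float,
    distance_map: np.ndarray | None = None,
    search_px: int = 4,
) -> float:
    """Signed net displacement along the neurite: anterograde positive.

    Sign and magnitude come from the change in within-mask geodesic
    distance-to-soma between the first and last track sample.
    """
    if distance_map is None:
        distance_map = soma_distance_map(masks, pixel_size)

    def sample(xy_um):
        row = xy_um[1] / pixel_size
        col = xy_um[0] / pixel_size
        r0, c0 = int(round(row)), int(round(col))
        best = np.inf
        val = None
        h, w = distance_map.shape
        for dr in range(-search_px, search_px + 1):
            for dc in range(-search_px, search_px + 1):
                r, c = r0 + dr, c0 + dc
                if 0 <= r < h and 0 <= c < w and np.isfinite(distance_map[r, c]):
                    d2 = (row - r) ** 2 + (col - c) ** 2
                    if d2 < best:
                        best = d2
                        val = distance_map[r, c]
        if val is None:
            raise TrackOutsideMaskError(
                f"track sample at ({row:.1f}, {col:.1f}) px not inside the neurite mask"
            )
        return val

    return float(sample(track.xy_um[-1]) - sample(track.xy_um[0]))


def temporal_projection(stack_or_array) -> np.ndarray:
    """Pixel-wise sum over frames (trajectory overview image)."""
    arr = stack_or_array if isinstance(stack_or_array, np.ndarray) else None
    if arr is None:
        from .imaging import ImageStack

        stack: ImageStack = stack_or_array
        arr = next(iter(stack.channels.values()))
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("need a (T, H, W) array with at least one frame")
    return arr.sum(axis=0, dtype=np.float64)


def _resample_polyline(polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-pixel-step resampling; returns (points, unit tangents)."""
    poly = np.asarray(polyline, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(round(arc[-1])) + 1)
    s = np.linspace(0.0, arc[-1], n)
    rows = np.interp(s, arc, poly[:, 0])
    cols = np.interp(s, arc, poly[:, 1])
    pts = np.stack([rows, cols], axis=1)
    tang = np.gradient(pts, axis=0)
    norm = np.linalg.norm(tang, axis=1)
    norm[norm == 0] = 1.0
    return pts, tang / norm[:, None]


def make_kymograph(stack_channel: np.ndarray, polyline: np.ndarray, width: int = 5) -> Kymograph:
    """Kymograph: rows = frames, cols = unit steps along the polyline.

    Each value is the maximum intensity over the ``width``-pixel segment
    perpendicular to the path at that sample (max preserves dim spots).
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    if stack_channel.ndim != 3:
        raise ValueError("stack_channel must be (T, H, W)")
    pts, tang = _resample_polyline(polyline)
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    offsets = np.arange(width) - width // 2
    coords = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    h, w = stack_channel.shape[1:]
    if (
        coords[..., 0].min() < -0.5
        or coords[..., 0].max() > h - 0.5
        or coords[..., 1].min() < -0.5
        or coords[..., 1].max() > w - 0.5
    ):
        raise KymographError("polyline (with width) exits the frame")
    flat = coords.reshape(-1, 2).T
    rows = []
    for t in range(stack_channel.shape[0]):
        sampled = ndi.map_coordinates(
            stack_channel[t].astype(np.float64), flat, order=1, mode="nearest"
        ).reshape(len(pts), width)
        rows.append(sampled.max(axis=1))
    return Kymograph(data=np.asarray(rows), path=pts, width=width)


def kymo_readout(
    vertices: np.ndarray, pixel_size: float, frame_interval: float
) -> tuple[float, float, np.ndarray]:
    """Distance/velocity readout from a polyline drawn on a kymograph.

    ``vertices`` are (row=frame, col=path position px) pairs, monotone in the
    time axis.  Returns (total distance um, mean velocity um/s, per-segment
    velocities um/s).
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need at least 2 vertices")
    drow = np.diff(v[:, 0])
    dcol = np.abs(np.diff(v[:, 1]))
    if np.any(drow <= 0):
        raise ValueError("vertices must be strictly increasing in the time axis")
    seg_dist = dcol * pixel_size
    seg_vel = seg_dist / (drow * frame_interval)
    total = float(seg_dist.sum())
    duration = float(drow.sum() * frame_interval)
    return total, total / duration, seg_vel
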