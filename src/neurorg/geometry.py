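"""Synthetic neuron geometry: a soma disk with smooth random-walk neurites.

The geometry is the ground-truth scaffold for the simulator: neurite paths
are polylines in pixel coordinates, rooted on the soma boundary, that stay
inside the frame and outside the soma disk.  Organelle motion is 1-D along a
path (matching kymograph-style analysis); rasterised tubes of the stated
neurite width provide the image-space footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .imaging import ImagingConfig


@dataclass
class NeuronGeometry:
    """Soma disk plus neurite centerline polylines (pixel coordinates)."""

    soma_center: tuple[float, float]          # (row, col) px
    soma_radius: float = 10.0                 # um
    neurite_paths: list[np.ndarray] = field(default_factory=list)  # each (N, 2) px
    neurite_width: float = 1.2                # um
    pixel_size: float = 0.08                  # um/px, cached for convenience

    # -- path parameterisation ------------------------------------------------

    def path_arclength_um(self, index: int) -> np.ndarray:
        """Cumulative arc length (um) at each vertex of neurite ``index``."""
        path = self.neurite_paths[index]
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1) * self.pixel_size
        return np.concatenate([[0.0], np.cumsum(seg)])

    def path_length_um(self, index: int) -> float:
        return float(self.path_arclength_um(index)[-1])

    def point_at_arc(self, index: int, s_um: np.ndarray | float):
        """Interpolate position (row, col) px and unit tangent at arc length ``s_um``.

        Values are clipped to the path extent.
        """
        path = self.neurite_paths[index]
        arc = self.path_arclength_um(index)
        s = np.clip(np.atleast_1d(np.asarray(s_um, dtype=float)), 0.0, arc[-1])
        rows = np.interp(s, arc, path[:, 0])
        cols = np.interp(s, arc, path[:, 1])
        # tangent from neighbouring vertices
        idx = np.clip(np.searchsorted(arc, s) - 1, 0, len(path) - 2)
        d = path[idx + 1] - path[idx]
        norm = np.linalg.norm(d, axis=1)
        norm[norm == 0] = 1.0
        tangents = d / norm[:, None]
        pts = np.stack([rows, cols], axis=1)
        if np.isscalar(s_um):
            return pts[0], tangents[0]
        return pts, tangents

    # -- rasterisation --------------------------------------------------------

    def soma_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = shape or (0, 0)
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        r_px = self.soma_radius / self.pixel_size
        return (rr - self.soma_center[0]) ** 2 + (cc - self.soma_center[1]) ** 2 <= r_px**2

    def neurite_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Tube of ``neurite_width`` around every centerline (may enter soma disk)."""
        mask = np.zeros(shape, dtype=bool)
        radius_px = max(1, int(round(self.neurite_width / 2.0 / self.pixel_size)))
        dr, dc = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
        disk = dr**2 + dc**2 <= radius_px**2
        offs = np.stack([dr[disk], dc[disk]], axis=1)
        for i in range(len(self.neurite_paths)):
            arc = self.path_arclength_um(i)
            n = max(2, int(math.ceil(arc[-1] / self.pixel_size)))
            pts, _ = self.point_at_arc(i, np.linspace(0, arc[-1], n))
            centers = np.round(pts).astype(int)
            all_px = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
            valid = (
                (all_px[:, 0] >= 0)
                & (all_px[:, 0] < shape[0])
                & (all_px[:, 1] >= 0)
                & (all_px[:, 1] < shape[1])
            )
            all_px = all_px[valid]
            mask[all_px[:, 0], all_px[:, 1]] = True
        return mask

    def to_dict(self) -> dict:
        return {
            "soma_center": list(self.soma_center),
            "soma_radius": self.soma_radius,
            "neurite_paths": [p.tolist() for p in self.neurite_paths],
            "neurite_width": self.neurite_width,
            "pixel_size": self.pixel_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronGeometry":
        return cls(
            soma_center=tuple(d["soma_center"]),
            soma_radius=d["soma_radius"],
            neurite_paths=[np.asarray(p, dtype=float) for p in d["neurite_paths"]],
            neurite_width=d["neurite_width"],
            pixel_size=d["pixel_size"],
        )


def _feasible(pt: np.ndarray, shape, margin: float, center: np.ndarray, r_px: float) -> bool:
    if not (margin <= pt[0] < shape[0] - margin and margin <= pt[1] < shape[1] - margin):
        return False
    return float(np.linalg.norm(pt - center)) > r_px + 2.0


def make_geometry(
    config: ImagingConfig,
    n_neurites: int,
    seed: int,
    soma_radius: float = 10.0,
    min_length: float = 40.0,
    max_length: float = 50.0,
    heading_noise: float = 0.08,
    step_px: float = 2.0,
    margin_px: float = 8.0,
) -> NeuronGeometry:
    """Generate a soma-centred geometry with smooth random-walk neurites.

    Neurites leave the soma radially (evenly spaced base angles with jitter)
    and perform a bounded-curvature random walk; when the walk approaches the
    frame boundary or the soma it steers to the nearest feasible heading, so
    long paths serpentine inside small frames.  Deterministic for a fixed
    seed.

    Raises
    ------
    GeometryError
        If the soma does not fit in the frame or a neurite cannot reach
        ``min_length`` without leaving the frame.
    """
    if n_neurites < 0:
        raise ValueError("n_neurites must be >= 0")
    rng = np.random.default_rng(seed)
    shape = tuple(config.frame_shape)
    center = np.array([shape[0] / 2.0, shape[1] / 2.0])
    r_px = soma_radius / config.pixel_size
    if r_px + 4 * margin_px >= min(shape) / 2.0:
        raise GeometryError(
            f"soma radius {soma_radius} um ({r_px:.0f} px) does not fit in frame {shape}"
        )
    paths: list[np.ndarray] = []
    for k in range(n_neurites):
        base = 2 * math.pi * k / max(n_neurites, 1) + rng.uniform(-0.3, 0.3) / max(
            n_neurites, 1
        )
        heading = base
        start = center + (r_px + 1.0) * np.array([math.sin(base), math.cos(base)])
        target_um = rng.uniform(min_length, max_length)
        pts = [start]
        length_um = 0.0
        guard = 0
        while length_um < target_um:
            guard += 1
            if guard > 20000:
                raise GeometryError(
                    f"neurite {k}: could not reach {min_length} um inside frame {shape}"
                )
            desired = heading + rng.normal(0.0, heading_noise)
            chosen = None
            for delta in _steer_sequence():
                cand_heading = desired + delta
                step_vec = step_px * np.array(
                    [math.sin(cand_heading), math.cos(cand_heading)]
                )
                nxt = pts[-1] + step_vec
                ahead = pts[-1] + 5 * step_vec
                if _feasible(nxt, shape, margin_px, center, r_px) and _feasible(
                    ahead, shape, margin_px, center, r_px
                ):
                    chosen = (cand_heading, nxt)
                    break
            if chosen is None:
                raise GeometryError(
                    f"neurite {k}: no feasible direction at {pts[-1]} in frame {shape}"
                )
            heading, nxt = chosen
            pts.append(nxt)
            length_um += step_px * config.pixel_size
        paths.append(np.asarray(pts))
    return NeuronGeometry(
        soma_center=(float(center[0]), float(center[1])),
        soma_radius=soma_radius,
        neurite_paths=paths,
        neurite_width=1.2,
        pixel_size=config.pixel_size,
    )


def _steer_sequence():
    """Candidate heading offsets: straight first, then widening alternating turns."""
    yield 0.0
    for deg in range(10, 180, 10):
        rad = math.radians(deg)
        yield rad
        yield -rad
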