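"""Render ground-truth scenes into noisy two-channel image stacks.

Peroxisomes are diffraction-limited 2-D Gaussian spots (sigma ~0.15 um);
mitochondria are elongated soft capsules (0.5-3 um) oriented along the local
neurite tangent.  Frames sit on a dim neurite/soma-shaped background bright
enough for ridge tracing.  Shot noise uses the Gaussian approximation
N(lambda, lambda) of Poisson counts (exact to <1% at the 100-count
background) plus Gaussian read noise; rendering is a pure function of
(inputs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import PackingError
from .geometry import NeuronGeometry, make_geometry
from .imaging import ImageStack, ImagingConfig
from .kinetics import GroundTruthTrack
from .truth import GroundTruth

PO_SIGMA_UM = 0.15        # diffraction-limited spot sigma
MITO_RADIUS_UM = 0.25     # capsule cross-section sigma


@dataclass(frozen=True)
class NoiseParams:
    """Intensity and noise defaults, calibrated for sub-0.1-px centroid noise."""

    background: float = 100.0     # ambient counts
    structure: float = 120.0      # added counts inside soma/neurite shapes
    spot_peak: float = 1000.0     # organelle peak counts
    read_sigma: float = 10.0      # Gaussian read noise
    enabled: bool = True


@dataclass(frozen=True)
class ContactPreset:
    """Planting parameters for peroxisome-mitochondria contacts."""

    contact_fraction: float = 0.846
    clearance: float = 1.0        # um, minimum PO-mito distance for non-contacts

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must be in [0, 1]")


CONTACT_PRESETS = {"contact-control": ContactPreset(contact_fraction=0.846)}


@dataclass
class FixedNeuronSpec:
    """Planted spot counts/areas for a fixed-cell peroxisome fixture."""

    geometry: NeuronGeometry
    soma_po_count: int
    neurite_po_count: int
    soma_po_area: float          # um^2 total
    neurite_po_area: float       # um^2 total
    spot_radius: float = 0.0     # derived per region when 0
    min_spot_separation: float = 0.5  # um edge-to-edge clearance


#: (soma count, proximal-neurite count, soma area um^2, neurite area um^2)
FIXED_PRESETS = {
    "fixed-control": (174, 65, 22.0, 6.0),
    "fixed-acbd5": (88, 99, 11.0, 11.0),
}


def fixed_spec_from_preset(
    name: str, config: ImagingConfig, seed: int, n_neurites: int = 5
) -> FixedNeuronSpec:
    """Build a FixedNeuronSpec with near-straight radial neurites.

    Fixed-cell analysis delineates the soma from the cytosol fill, so the
    geometry keeps neurites radial (low heading noise) to avoid arms folding
    back against the soma; the frame must be large enough for ~35 um of
    straight neurite (1280 px at 0.08 um/px).
    """
    counts = FIXED_PRESETS[name]
    geometry = make_geometry(
        config, n_neurites=n_neurites, seed=seed, min_length=34.0, max_length=38.0,
        heading_noise=0.02,
    )
    return FixedNeuronSpec(geometry, counts[0], counts[1], counts[2], counts[3])


# ---------------------------------------------------------------------------
# primitive stamps


def _stamp_gaussian(frame: np.ndarray, row: float, col: float, sigma_px: float, amp: float):
    h, w = frame.shape
    rad = int(math.ceil(4 * sigma_px))
    r0, r1 = max(0, int(row) - rad), min(h, int(row) + rad + 1)
    c0, c1 = max(0, int(col) - rad), min(w, int(col) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    frame[r0:r1, c0:c1] += amp * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma_px**2)
    )


def _segment_distance(rr, cc, p0, p1):
    """Distance of pixel grid points to the segment p0-p1 (row, col)."""
    d = p1 - p0
    denom = float(d @ d)
    pr = rr - p0[0]
    pc = cc - p0[1]
    if denom < 1e-12:
        return np.sqrt(pr**2 + pc**2)
    t = np.clip((pr * d[0] + pc * d[1]) / denom, 0.0, 1.0)
    return np.sqrt((pr - t * d[0]) ** 2 + (pc - t * d[1]) ** 2)


def _stamp_capsule(frame: np.ndarray, p0: np.ndarray, p1: np.ndarray, sigma_px: float, amp: float):
    h, w = frame.shape
    rad = int(math.ceil(4 * sigma_px))
    r0 = max(0, int(min(p0[0], p1[0])) - rad)
    r1 = min(h, int(max(p0[0], p1[0])) + rad + 1)
    c0 = max(0, int(min(p0[1], p1[1])) - rad)
    c1 = min(w, int(max(p0[1], p1[1])) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = _segment_distance(rr.astype(float), cc.astype(float), p0, p1)
    frame[r0:r1, c0:c1] += amp * np.exp(-(dist**2) / (2 * sigma_px**2))


def _stamp_disk(frame: np.ndarray, row: float, col: float, radius_px: float, amp: float,
                edge_px: float = 0.5):
    """Soft-edged disk: amp * 0.5 * erfc((d - r) / (sqrt(2) * edge))."""
    from scipy.special import erfc

    h, w = frame.shape
    rad = int(math.ceil(radius_px + 4 * edge_px))
    r0, r1 = max(0, int(row) - rad), min(h, int(row) + rad + 1)
    c0, c1 = max(0, int(col) - rad), min(w, int(col) + rad + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.sqrt((rr - row) ** 2 + (cc - col) ** 2)
    frame[r0:r1, c0:c1] += amp * 0.5 * erfc((d - radius_px) / (math.sqrt(2) * edge_px))


# ---------------------------------------------------------------------------
# backgrounds and noise


def render_background(geometry: NeuronGeometry, config: ImagingConfig,
                      noise: NoiseParams) -> np.ndarray:
    shape = tuple(config.frame_shape)
    base = np.full(shape, noise.background, dtype=np.float32)
    structure = geometry.soma_mask(shape) | geometry.neurite_mask(shape)
    base += noise.structure * gaussian_filter(structure.astype(np.float32), 2.0)
    return base


def _apply_noise(clean: np.ndarray, noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    if not noise.enabled:
        return np.clip(np.round(clean), 0, 65535).astype(np.uint16)
    # shot + read noise combined: N(0, lambda) + N(0, sigma^2) = N(0, lambda + sigma^2)
    std = np.sqrt(np.clip(clean, 0, None) + noise.read_sigma**2)
    draw = rng.standard_normal(clean.shape).astype(np.float32)
    return np.clip(np.round(clean + draw * std), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# time-lapse rendering


def render_timelapse(
    geometry: NeuronGeometry,
    po_tracks: list[GroundTruthTrack] | None,
    mito_tracks: list[GroundTruthTrack] | None,
    config: ImagingConfig,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Render tracks into a (multi-)channel uint16 time-lapse stack.

    A channel is rendered when its track list is not None (an empty list
    yields a background-only channel).  Bit-identical for a fixed seed.
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    bg = render_background(geometry, config, noise)
    amp = noise.spot_peak - noise.background
    shape = tuple(config.frame_shape)
    sigma_po = PO_SIGMA_UM / config.pixel_size
    sigma_mito = MITO_RADIUS_UM / config.pixel_size

    channels: dict[str, np.ndarray] = {}
    for name, tracks in (("PO", po_tracks), ("MITO", mito_tracks)):
        if tracks is None:
            continue
        stack = np.empty((config.n_frames, *shape), dtype=np.uint16)
        for t in range(config.n_frames):
            frame = bg.copy()
            for tr in tracks:
                if name == "PO":
                    _stamp_gaussian(frame, tr.px[t, 0], tr.px[t, 1], sigma_po, amp)
                else:
                    half = max(tr.extent_um / 2.0 - MITO_RADIUS_UM, 0.05)
                    s = tr.path_pos_um[t]
                    ends, _ = geometry.point_at_arc(
                        tr.neurite_index, np.array([s - half, s + half])
                    )
                    _stamp_capsule(frame, ends[0], ends[1], sigma_mito, amp)
            stack[t] = _apply_noise(frame, noise, rng)
        channels[name] = stack

    truth = GroundTruth(
        geometry=geometry,
        tracks=(po_tracks or []) + (mito_tracks or []),
        meta={"seed": seed, "config": {
            "pixel_size": config.pixel_size,
            "frame_interval": config.frame_interval,
            "n_frames": config.n_frames,
        }},
    )
    return ImageStack(channels=channels, config=config), truth


# ---------------------------------------------------------------------------
# fixed-cell rendering


def _sample_soma_spots(geometry, n, r_spot_um, min_sep_um, config, rng, margin_um=0.6):
    """Dart-throwing with edge-to-edge clearance inside the soma disk."""
    ps = config.pixel_size
    r_soma_px = geometry.soma_radius / ps
    max_r = r_soma_px - (r_spot_um + margin_um) / ps
    min_d_px = (min_sep_um + 2 * r_spot_um) / ps
    center = np.asarray(geometry.soma_center)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 400 * max(n, 1):
            raise PackingError(
                f"could not pack {n} spots (r={r_spot_um:.2f} um, "
                f"sep={min_sep_um} um) in the soma"
            )
        rho = max_r * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        cand = center + rho * np.array([math.sin(phi), math.cos(phi)])
        if pts and np.min(np.linalg.norm(np.asarray(pts) - cand, axis=1)) < min_d_px:
            continue
        pts.append(cand)
    return np.asarray(pts).reshape(n, 2)


def _sample_neurite_spots(geometry, n, r_spot_um, min_sep_um, config, rng,
                          s_range=(1.0, 28.0), existing=None):
    """Spots along neurite paths inside the proximal region, with clearance."""
    ps = config.pixel_size
    min_d_px = (min_sep_um + 2 * r_spot_um) / ps
    lateral_max = max(geometry.neurite_width / 2.0 - r_spot_um - 0.05, 0.0) / ps
    n_paths = len(geometry.neurite_paths)
    if n_paths == 0 and n > 0:
        raise PackingError("no neurites to host neurite spots")
    all_pts = [] if existing is None else [np.asarray(p) for p in existing]
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 400 * max(n, 1):
            raise PackingError(
                f"could not pack {n} spots (sep={min_sep_um} um) in the proximal neurites"
            )
        j = int(rng.integers(n_paths))
        s_hi = min(s_range[1] - r_spot_um, geometry.path_length_um(j) - 1.0)
        s = rng.uniform(s_range[0] + r_spot_um, s_hi)
        pt, tang = geometry.point_at_arc(j, float(s))
        normal = np.array([-tang[1], tang[0]])
        cand = pt + rng.uniform(-lateral_max, lateral_max) * normal
        pool = all_pts + pts
        if pool and np.min(np.linalg.norm(np.asarray(pool) - cand, axis=1)) < min_d_px:
            continue
        pts.append(cand)
    return np.asarray(pts).reshape(n, 2)


def _raster_disk_area(radius_px: float, row: float = 0.0, col: float = 0.0) -> int:
    """Pixel count of a rasterised disk centred at a sub-pixel position."""
    rad = int(math.ceil(radius_px)) + 1
    r0, c0 = int(round(row)), int(round(col))
    rr, cc = np.mgrid[r0 - rad : r0 + rad + 1, c0 - rad : c0 + rad + 1]
    return int(np.sum((rr - row) ** 2 + (cc - col) ** 2 <= radius_px**2))


def render_fixed_neuron(
    spec: FixedNeuronSpec,
    config: ImagingConfig,
    seed: int = 0,
    noise: NoiseParams | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-frame fixed-cell fixture: PO channel + cytosol fill.

    Plants exactly the requested spot counts with the stated edge-to-edge
    separation; per-region spot radii are solved so planted total areas match
    the spec (verified against rasterised disk areas, within 5%).
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    geometry = spec.geometry
    ps = config.pixel_size
    shape = tuple(config.frame_shape)

    def radius_for(count, area_um2):
        if spec.spot_radius > 0:
            return spec.spot_radius
        if count == 0:
            return 0.2
        # at random sub-pixel positions the expected raster footprint of a
        # disk equals its analytic area, so the analytic radius is unbiased
        return math.sqrt(area_um2 / count / math.pi)

    r_soma = radius_for(spec.soma_po_count, spec.soma_po_area)
    r_neur = radius_for(spec.neurite_po_count, spec.neurite_po_area)
    soma_pts = _sample_soma_spots(
        geometry, spec.soma_po_count, r_soma, spec.min_spot_separation, config, rng
    )
    neur_pts = _sample_neurite_spots(
        geometry, spec.neurite_po_count, r_neur, spec.min_spot_separation, config, rng,
        existing=list(soma_pts),
    )

    amp = noise.spot_peak - noise.background
    po = np.full(shape, noise.background, dtype=np.float64)
    for p in soma_pts:
        _stamp_disk(po, p[0], p[1], r_soma / ps, amp)
    for p in neur_pts:
        _stamp_disk(po, p[0], p[1], r_neur / ps, amp)

    cyto = np.full(shape, noise.background, dtype=np.float64)
    fill = geometry.soma_mask(shape) | geometry.neurite_mask(shape)
    cyto += 4 * noise.structure * gaussian_filter(fill.astype(np.float64), 1.5)

    channels = {
        "PO": _apply_noise(po, noise, rng)[None],
        "CYTO": _apply_noise(cyto, noise, rng)[None],
    }
    area_px2 = ps * ps
    planted_soma_area = area_px2 * sum(
        _raster_disk_area(r_soma / ps, p[0], p[1]) for p in soma_pts
    )
    planted_neur_area = area_px2 * sum(
        _raster_disk_area(r_neur / ps, p[0], p[1]) for p in neur_pts
    )
    truth = GroundTruth(
        geometry=geometry,
        fixed_spots={
            "soma_px": soma_pts.tolist(),
            "neurite_px": neur_pts.tolist(),
            "soma_radius_um": r_soma,
            "neurite_radius_um": r_neur,
            "planted_soma_area_um2": planted_soma_area,
            "planted_neurite_area_um2": planted_neur_area,
        },
        meta={"seed": seed},
    )
    fixed_config = ImagingConfig(
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        n_frames=2,  # container minimum; arrays carry a single frame
        frame_shape=config.frame_shape,
        channels=("PO", "CYTO"),
    )
    return ImageStack(channels=channels, config=fixed_config), truth


# ---------------------------------------------------------------------------
# contact planting


@dataclass
class Capsule:
    """A mitochondrion footprint along a neurite path."""

    neurite_index: int
    s_center: float       # um along path
    length: float         # um end-to-end
    radius: float         # um cross-section
    p0: np.ndarray        # axis endpoints, px
    p1: np.ndarray

    def surface_distance_um(self, points_px: np.ndarray, pixel_size: float) -> np.ndarray:
        pts = np.atleast_2d(points_px)
        d = _segment_distance(pts[:, 0], pts[:, 1], self.p0, self.p1) * pixel_size
        return d - self.radius


def place_capsules(
    geometry: NeuronGeometry,
    config: ImagingConfig,
    rng: np.random.Generator,
    length_range=(1.5, 3.0),
    gap_range=(2.6, 3.6),
    margin: float = 2.0,
) -> list[Capsule]:
    """Tile every neurite with capsules separated by random gaps."""
    capsules = []
    for j in range(len(geometry.neurite_paths)):
        total = geometry.path_length_um(j)
        s = margin + rng.uniform(0, 1.0)
        while True:
            length = rng.uniform(*length_range)
            if s + length > total - margin:
                break
            half = length / 2.0 - MITO_RADIUS_UM
            ends, _ = geometry.point_at_arc(j, np.array([s + length / 2 - half,
                                                         s + length / 2 + half]))
            capsules.append(
                Capsule(j, s + length / 2, length, MITO_RADIUS_UM, ends[0], ends[1])
            )
            s += length + rng.uniform(*gap_range)
    return capsules


def plant_contacts(
    po_seeds: list[tuple[int, float]],
    mito_capsules: list[Capsule],
    preset: ContactPreset,
    geometry: NeuronGeometry,
    config: ImagingConfig,
    seed: int = 0,
    po_min_sep: float = 0.7,
) -> tuple[np.ndarray, list[bool]]:
    """Adjust PO seed positions to plant the requested contact fraction.

    Each PO is labelled contact with probability ``contact_fraction``.
    Contacts are placed with their centre inside a mitochondrion footprint;
    non-contacts keep at least ``clearance`` um from every capsule surface.
    Returns planted PO pixel positions and per-PO labels.
    """
    rng = np.random.default_rng(seed)
    ps = config.pixel_size
    n = len(po_seeds)
    labels = [bool(rng.random() < preset.contact_fraction) for _ in range(n)]
    if any(labels) and not mito_capsules:
        raise PackingError("contacts requested but no mitochondria footprints given")
    placed: list[np.ndarray] = []

    def far_from_placed(cand_px):
        if not placed:
            return True
        return np.min(np.linalg.norm(np.asarray(placed) - cand_px, axis=1)) * ps >= po_min_sep

    def min_surface_dist(cand_px):
        return min(
            float(c.surface_distance_um(cand_px[None], ps)[0]) for c in mito_capsules
        ) if mito_capsules else np.inf

    n_paths = len(geometry.neurite_paths)
    positions = np.zeros((n, 2))
    for i in range(n):
        ok = False
        for attempt in range(2000):
            if labels[i]:
                c = mito_capsules[int(rng.integers(len(mito_capsules)))]
                u = rng.uniform(-c.length / 2 + 0.1, c.length / 2 - 0.1)
                pt, tang = geometry.point_at_arc(c.neurite_index, c.s_center + u)
                normal = np.array([-tang[1], tang[0]])
                cand = pt + rng.uniform(-0.4, 0.4) * c.radius / ps * normal
                if far_from_placed(cand):
                    ok = True
                    break
            else:
                if attempt < 200:
                    j, s0 = po_seeds[i]
                    s = s0 + rng.uniform(-3.0, 3.0)
                else:
                    # fall back to a uniform search over all neurites
                    j = int(rng.integers(n_paths))
                    s = rng.uniform(1.0, geometry.path_length_um(j) - 1.0)
                s = float(np.clip(s, 1.0, geometry.path_length_um(j) - 1.0))
                cand, _ = geometry.point_at_arc(j, s)
                if far_from_placed(cand) and min_surface_dist(cand) >= preset.clearance:
                    ok = True
                    break
        if not ok:
            raise PackingError(
                f"no room to plant PO {i} as "
                f"{'contact' if labels[i] else 'non-contact'}"
            )
        placed.append(cand)
        positions[i] = cand
    return positions, labels


def make_contact_fixture(
    config: ImagingConfig,
    n_po: int = 200,
    preset: ContactPreset | None = None,
    seed: int = 0,
    n_neurites: int = 10,
    noise: NoiseParams | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-frame two-channel fixture with planted PO-mito contacts."""
    preset = preset or CONTACT_PRESETS["contact-control"]
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    geometry = make_geometry(config, n_neurites=n_neurites, seed=seed)
    capsules = place_capsules(geometry, config, rng)
    # seed POs spread along the paths (non-contacts search near their seed)
    seeds = []
    lengths = [geometry.path_length_um(j) for j in range(n_neurites)]
    for i in range(n_po):
        j = int(rng.integers(n_neurites))
        seeds.append((j, rng.uniform(2.0, lengths[j] - 2.0)))
    positions, labels = plant_contacts(
        seeds, capsules, preset, geometry, config, seed=seed + 1
    )

    amp = noise.spot_peak - noise.background
    bg = render_background(geometry, config, noise)
    po = bg.copy()
    sigma_po = PO_SIGMA_UM / config.pixel_size
    for p in positions:
        _stamp_gaussian(po, p[0], p[1], sigma_po, amp)
    mito = bg.copy()
    sigma_mito = MITO_RADIUS_UM / config.pixel_size
    for c in capsules:
        _stamp_capsule(mito, c.p0, c.p1, sigma_mito, amp)
    channels = {
        "PO": _apply_noise(po, noise, rng)[None],
        "MITO": _apply_noise(mito, noise, rng)[None],
    }
    truth = GroundTruth(
        geometry=geometry,
        contact_labels=labels,
        po_positions_px=positions,
        meta={
            "seed": seed,
            "contact_fraction_param": preset.contact_fraction,
            "planted_fraction": float(np.mean(labels)),
            "capsules": [
                {
                    "neurite_index": c.neurite_index,
                    "s_center": c.s_center,
                    "length": c.length,
                    "radius": c.radius,
                }
                for c in capsules
            ],
        },
    )
    contact_config = ImagingConfig(
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        n_frames=2,
        frame_shape=config.frame_shape,
        channels=("PO", "MITO"),
    )
    return ImageStack(channels=channels, config=contact_config), truth
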