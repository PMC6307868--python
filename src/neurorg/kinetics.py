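"""Ground-truth organelle trajectories with a saltatory run/pause kinetic model.

Each track belongs to one of four motility classes defined on total travelled
path length: static (< 1 um), very short range (1-5 um), short range
(5-10 um) and long range (>= 10 um, capped at 15 um in the generator).  A
track's target distance is drawn uniformly inside its class interval and
realised as:

* ``1 + Poisson(2)`` saltatory runs of contiguous full-speed steps
  (``run_speed * frame_interval`` per interval, random +/- direction per run),
* isolated oscillation steps of fixed magnitude (default 0.15 um), and
* pauses filling the remaining intervals.

Because steps are restricted to these two magnitudes, the target distance is
quantised down onto the realisable lattice (one oscillation step is added
back if quantisation would cross the class lower bound), so every nonzero
step has magnitude >= the oscillation step and ``planted_total_distance``
always lies inside its class interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrackPlacementError
from .geometry import NeuronGeometry
from .imaging import ImagingConfig

CLASS_NAMES = ("static", "very_short", "short", "long")

DEFAULT_CLASS_BOUNDS = {
    "static": (0.0, 1.0),
    "very_short": (1.0, 5.0),
    "short": (5.0, 10.0),
    "long": (10.0, 15.0),
}


@dataclass(frozen=True)
class MotilityPreset:
    """Class mixture and kinetic parameters for one cohort condition."""

    class_probs: tuple[float, float, float, float]
    run_speed: float  # um/s
    class_distance_bounds: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_BOUNDS)
    )
    oscillation_step: float = 0.15  # um

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.run_speed <= 0:
            raise ValueError("run_speed must be > 0")


#: Named presets with class mixtures at the reported cohort values.
PRESETS: dict[str, MotilityPreset] = {
    "control-PO": MotilityPreset((0.01, 0.59, 0.30, 0.10), run_speed=0.1),
    "acbd5-PO": MotilityPreset((0.03, 0.81, 0.14, 0.02), run_speed=0.1),
    "control-MITO": MotilityPreset((0.75, 0.05, 0.05, 0.15), run_speed=0.06),
}


@dataclass
class GroundTruthTrack:
    """One planted organelle trajectory (path coordinate + 2-D pixel coords)."""

    track_id: int
    organelle: str                  # "PO" or "MITO"
    neurite_index: int
    path_pos_um: np.ndarray         # (T,) um along the neurite
    px: np.ndarray                  # (T, 2) (row, col) pixel coordinates
    planted_class: str
    planted_total_distance: float   # um, equals sum of |per-interval steps|
    planted_max_speed: float        # um/s
    n_run_steps: int                # number of full-speed intervals
    extent_um: float = 0.0          # capsule length for mitochondria, 0 for PO

    def to_dict(self) -> dict:
        return {
            "track_id": self.track_id,
            "organelle": self.organelle,
            "neurite_index": self.neurite_index,
            "path_pos_um": self.path_pos_um.tolist(),
            "px": self.px.tolist(),
            "planted_class": self.planted_class,
            "planted_total_distance": self.planted_total_distance,
            "planted_max_speed": self.planted_max_speed,
            "n_run_steps": self.n_run_steps,
            "extent_um": self.extent_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthTrack":
        return cls(
            track_id=d["track_id"],
            organelle=d["organelle"],
            neurite_index=d["neurite_index"],
            path_pos_um=np.asarray(d["path_pos_um"], dtype=float),
            px=np.asarray(d["px"], dtype=float),
            planted_class=d["planted_class"],
            planted_total_distance=d["planted_total_distance"],
            planted_max_speed=d["planted_max_speed"],
            n_run_steps=d["n_run_steps"],
            extent_um=d.get("extent_um", 0.0),
        )


def _realize(
    distance: float,
    lower_bound: float,
    preset: MotilityPreset,
    frame_interval: float,
    n_intervals: int,
    rng: np.random.Generator,
) -> np.ndarray:
    step_run = preset.run_speed * frame_interval
    osc = preset.oscillation_step
    n_full = int(distance / step_run + 1e-12)
    rem = distance - n_full * step_run
    n_osc = int(rem / osc + 1e-12)
    realized = n_full * step_run + n_osc * osc
    # quantisation must not cross the class lower bound, and must not sit
    # exactly on it either: a uniform draw has zero mass at the boundary,
    # whereas an atom there would flip class under measurement noise
    while realized < lower_bound + 1e-9 and lower_bound > 0:
        n_osc += 1
        realized += osc
    while realized < lower_bound - 1e-9:
        n_osc += 1
        realized += osc
    if n_full + n_osc > n_intervals:
        raise TrackPlacementError(
            f"distance {distance:.2f} um unreachable in {n_intervals} intervals "
            f"at run speed {preset.run_speed} um/s"
        )
    # split run steps into 1 + Poisson(2) contiguous runs
    tokens: list[np.ndarray] = []
    if n_full > 0:
        n_runs = min(1 + rng.poisson(2.0), n_full)
        cuts = np.sort(rng.choice(np.arange(1, n_full), size=n_runs - 1, replace=False))
        sizes = np.diff(np.concatenate([[0], cuts, [n_full]]))
        for size in sizes:
            direction = rng.choice([-1.0, 1.0])
            tokens.append(np.full(int(size), direction * step_run))
    for _ in range(n_osc):
        tokens.append(np.array([rng.choice([-1.0, 1.0]) * osc]))
    n_pause = n_intervals - n_full - n_osc
    tokens.extend(np.array([0.0]) for _ in range(n_pause))
    order = rng.permutation(len(tokens))
    steps = np.concatenate([tokens[i] for i in order]) if tokens else np.zeros(0)
    return steps


def sample_tracks(
    geometry: NeuronGeometry,
    preset: MotilityPreset,
    n_organelles: int,
    config: ImagingConfig,
    seed: int,
    organelle: str = "PO",
    territory_gap: float = 1.2,
    start_margin: float = 2.0,
) -> list[GroundTruthTrack]:
    """Sample ground-truth tracks confined to neurite paths.

    Each organelle gets a disjoint "territory" along a neurite: the interval
    its trajectory visits, padded by half its rendered extent, is kept at
    least ``territory_gap`` um from every other territory, so planted tracks
    never approach each other closer than the tracking gate.

    Raises
    ------
    TrackPlacementError
        If the neurites cannot host all requested territories.
    """
    if n_organelles < 1:
        raise ValueError("n_organelles must be >= 1")
    if not geometry.neurite_paths:
        raise TrackPlacementError("geometry has no neurites to host tracks")
    rng = np.random.default_rng(seed)
    n_intervals = config.n_frames - 1
    bounds = [preset.class_distance_bounds[name] for name in CLASS_NAMES]

    drafts = []
    for tid in range(n_organelles):
        cls_idx = rng.choice(4, p=np.asarray(preset.class_probs, dtype=float))
        lo, hi = bounds[cls_idx]
        target = rng.uniform(lo, hi)
        steps = _realize(target, lo, preset, config.frame_interval, n_intervals, rng)
        offsets = np.concatenate([[0.0], np.cumsum(steps)])
        extent = rng.uniform(0.5, 3.0) if organelle == "MITO" else 0.0
        pad = extent / 2.0 + 0.3
        drafts.append(
            {
                "track_id": tid,
                "class": CLASS_NAMES[cls_idx],
                "steps": steps,
                "offsets": offsets,
                "span": (float(offsets.min()) - pad, float(offsets.max()) + pad),
                "extent": extent,
            }
        )

    # greedy territory packing, round-robin over neurites
    cursors = [start_margin for _ in geometry.neurite_paths]
    lengths = [geometry.path_length_um(i) for i in range(len(geometry.neurite_paths))]
    order = rng.permutation(n_organelles)
    placements: dict[int, tuple[int, float]] = {}
    ni = 0
    for di in order:
        d = drafts[di]
        lo_off, hi_off = d["span"]
        needed = hi_off - lo_off
        placed = False
        for attempt in range(len(cursors)):
            j = (ni + attempt) % len(cursors)
            if cursors[j] + needed <= lengths[j] - start_margin:
                s0 = cursors[j] - lo_off
                placements[di] = (j, s0)
                cursors[j] += needed + territory_gap
                placed = True
                ni = j + 1
                break
        if not placed:
            raise TrackPlacementError(
                f"no room for track {d['track_id']} (span {needed:.1f} um) on "
                f"{len(cursors)} neurites"
            )

    tracks = []
    for di in range(n_organelles):
        d = drafts[di]
        j, s0 = placements[di]
        s = s0 + d["offsets"]
        pts, _ = geometry.point_at_arc(j, s)
        steps = d["steps"]
        abs_steps = np.abs(steps)
        tracks.append(
            GroundTruthTrack(
                track_id=d["track_id"],
                organelle=organelle,
                neurite_index=j,
                path_pos_um=s,
                px=pts,
                planted_class=d["class"],
                planted_total_distance=float(abs_steps.sum()),
                planted_max_speed=float(abs_steps.max() / config.frame_interval)
                if len(abs_steps)
                else 0.0,
                n_run_steps=int(
                    np.sum(
                        np.isclose(
                            abs_steps, preset.run_speed * config.frame_interval
                        )
                    )
                ),
                extent_um=d["extent"],
            )
        )
    return sorted(tracks, key=lambda t: t.track_id)
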