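"""Frame-to-frame particle linking by globally optimal nearest neighbours.

Adjacent-frame detections are linked by solving a linear assignment problem
over centroid distances with a hard distance gate: the augmented-matrix
formulation (distance block, birth/death diagonal at the gate cost, and its
transpose completion) yields the matching that first maximises the number of
gated links and then minimises their total distance.  Chaining assignments
produces gap-free trajectories; an unmatched detection starts a new track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Region

_BIG = 1e9


@dataclass
class Assignment:
    matches: list[tuple[int, int]]
    unmatched_t: list[int]
    unmatched_t1: list[int]
    total_cost: float            # sum of matched centroid distances, um


@dataclass
class Track:
    """One organelle trajectory over strictly consecutive frames."""

    track_id: int
    organelle: str
    frames: np.ndarray               # (T,) int, consecutive
    xy_um: np.ndarray                # (T, 2) = (x, y) um
    region_labels: list[int] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    def __len__(self) -> int:
        return len(self.frames)


def _centroids(regions) -> np.ndarray:
    if len(regions) == 0:
        return np.zeros((0, 2))
    if isinstance(regions[0], Region):
        return np.array([r.centroid_um for r in regions], dtype=float)
    return np.asarray(regions, dtype=float)


def link_pair(regions_t, regions_t1, max_link_dist: float = 1.0) -> Assignment:
    """Globally optimal gated assignment between two frames.

    Pairs farther apart than ``max_link_dist`` are never matched; among
    matchings of maximal cardinality the total matched distance is minimal.
    """
    if max_link_dist <= 0:
        raise ValueError("max_link_dist must be > 0")
    a = _centroids(regions_t)
    b = _centroids(regions_t1)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return Assignment([], list(range(n)), list(range(m)), 0.0)
    dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    gated = np.where(dist <= max_link_dist, dist, _BIG)
    size = n + m
    cost = np.full((size, size), _BIG)
    cost[:n, :m] = gated
    cost[np.arange(n), m + np.arange(n)] = max_link_dist       # deaths
    cost[n + np.arange(m), np.arange(m)] = max_link_dist       # births
    # completion block: zero cost, finite exactly where a link is feasible
    cost[n:, m:] = np.where(gated.T < _BIG, 0.0, _BIG)
    rows, cols = linear_sum_assignment(cost)
    matches = []
    total = 0.0
    for r, c in zip(rows, cols):
        if r < n and c < m and dist[r, c] <= max_link_dist:
            matches.append((int(r), int(c)))
            total += float(dist[r, c])
    matched_t = {r for r, _ in matches}
    matched_t1 = {c for _, c in matches}
    return Assignment(
        matches=sorted(matches),
        unmatched_t=[i for i in range(n) if i not in matched_t],
        unmatched_t1=[j for j in range(m) if j not in matched_t1],
        total_cost=total,
    )


def build_tracks(
    per_frame_regions: list[list[Region]],
    max_link_dist: float = 1.0,
    organelle: str = "",
) -> list[Track]:
    """Chain pairwise assignments into trajectories.

    Unmatched detections at t+1 start new tracks; unmatched at t terminate.
    Deterministic for fixed input.
    """
    next_id = 0
    open_tracks: dict[int, dict] = {}   # region index in current frame -> record
    done: list[dict] = []

    def new_record(frame, region):
        nonlocal next_id
        rec = {
            "id": next_id,
            "frames": [frame],
            "xy": [region.centroid_um],
            "labels": [region.label],
        }
        next_id += 1
        return rec

    for t, regions in enumerate(per_frame_regions):
        if t == 0:
            open_tracks = {i: new_record(0, r) for i, r in enumerate(regions)}
            continue
        prev = per_frame_regions[t - 1]
        assign = link_pair(prev, regions, max_link_dist)
        new_open: dict[int, dict] = {}
        for i, j in assign.matches:
            rec = open_tracks[i]
            rec["frames"].append(t)
            rec["xy"].append(regions[j].centroid_um)
            rec["labels"].append(regions[j].label)
            new_open[j] = rec
        for i in assign.unmatched_t:
            done.append(open_tracks[i])
        for j in assign.unmatched_t1:
            new_open[j] = new_record(t, regions[j])
        open_tracks = new_open
    done.extend(open_tracks.values())
    tracks = [
        Track(
            track_id=rec["id"],
            organelle=organelle,
            frames=np.asarray(rec["frames"], dtype=int),
            xy_um=np.asarray(rec["xy"], dtype=float),
            region_labels=rec["labels"],
        )
        for rec in done
    ]
    return sorted(tracks, key=lambda tr: tr.track_id)


def greedy_cost(regions_t, regions_t1, max_link_dist: float) -> float:
    """Objective value of greedy closest-pair matching (optimality yardstick).

    Objective = sum of matched distances + gate * number of unmatched
    detections on both sides; the same functional the global solver
    minimises.
    """
    a = _centroids(regions_t)
    b = _centroids(regions_t1)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return max_link_dist * (n + m)
    dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    free_a = set(range(n))
    free_b = set(range(m))
    total = 0.0
    pairs = sorted(
        ((dist[i, j], i, j) for i in range(n) for j in range(m) if dist[i, j] <= max_link_dist)
    )
    for d, i, j in pairs:
        if i in free_a and j in free_b:
            free_a.remove(i)
            free_b.remove(j)
            total += d
    return total + max_link_dist * (len(free_a) + len(free_b))


def assignment_objective(assign: Assignment, n: int, m: int, max_link_dist: float) -> float:
    """Full objective of an assignment (matched distance + gate per unmatched)."""
    return assign.total_cost + max_link_dist * (len(assign.unmatched_t) + len(assign.unmatched_t1))
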