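"""Geodesic distance within a binary mask (8-connected, diagonal = sqrt(2))."""

from __future__ import annotations

import numpy as np
from skimage.graph import MCP_Geometric


def geodesic_distance(
    traversable: np.ndarray, seeds: np.ndarray, pixel_size: float = 1.0
) -> np.ndarray:
    """Shortest within-mask path length (um) from any seed pixel.

    Pixels outside ``traversable`` or unreachable from the seeds are +inf.
    """
    traversable = traversable.astype(bool)
    seeds = seeds.astype(bool) & traversable
    if not seeds.any():
        raise ValueError("no seed pixels inside the traversable mask")
    costs = np.where(traversable, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    dist, _ = mcp.find_costs(np.argwhere(seeds))
    dist = np.asarray(dist, dtype=float)
    dist[~traversable] = np.inf
    return dist * pixel_size
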