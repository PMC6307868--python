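"""Peroxisome distribution (soma vs proximal neurites) and mito contacts.

The proximal neurite region is the set of neurite-mask pixels within a
geodesic distance (default 30 um) of the soma boundary.  Counts assign a
region to a compartment by centroid membership (avoiding double counting of
regions straddling the partition); areas sum the binarised pixel areas.  A
peroxisome is in contact with a mitochondrion when its binarised region
overlaps or is 8-adjacent to the binarised mitochondria mask (equivalently:
overlaps the mask dilated by one pixel).  Two-group comparisons use a
one-tailed unpaired pooled-variance t-test with significance stars at
0.05 / 0.01 / 0.005 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .detection import Region
from .errors import UndefinedFractionError
from .geodesic import geodesic_distance
from .segmentation import SegmentationMasks


@dataclass
class RegionPartition:
    soma_region: np.ndarray
    proximal_region: np.ndarray
    soma_area_um2: float
    proximal_area_um2: float
    unreachable_px: int              # neurite pixels not connected to the soma


@dataclass
class DistributionSummary:
    soma_count: int
    neurite_count: int
    soma_area_um2: float
    neurite_area_um2: float
    soma_percent_area: float
    neurite_percent_area: float


@dataclass
class ContactSummary:
    n_po_total: int
    n_po_contact: int

    @property
    def contact_fraction(self) -> float:
        return self.n_po_contact / self.n_po_total


@dataclass
class ComparisonResult:
    t: float
    df: int
    p: float
    stars: str
    degenerate: bool = False


def proximal_region(
    masks: SegmentationMasks, pixel_size: float, length: float = 30.0
) -> RegionPartition:
    """Soma region plus the proximal ``length`` um of each neurite."""
    if not masks.soma_mask.any() or not masks.neurite_mask.any():
        raise ValueError("need non-empty soma and neurite masks")
    grown = ndi.binary_dilation(masks.soma_mask, structure=np.ones((9, 9), dtype=bool))
    seeds = grown & masks.neurite_mask
    dist = geodesic_distance(masks.neurite_mask, seeds, pixel_size)
    proximal = masks.neurite_mask & (dist <= length)
    unreachable = int(np.sum(masks.neurite_mask & ~np.isfinite(dist)))
    area = pixel_size**2
    return RegionPartition(
        soma_region=masks.soma_mask.copy(),
        proximal_region=proximal,
        soma_area_um2=float(masks.soma_mask.sum()) * area,
        proximal_area_um2=float(proximal.sum()) * area,
        unreachable_px=unreachable,
    )


def distribution_summary(
    regions: list[Region], partition: RegionPartition, pixel_size: float
) -> DistributionSummary:
    """Counts, areas and percent areas of PO regions per compartment."""
    if not partition.soma_region.any() and not partition.proximal_region.any():
        raise ValueError("empty partition")
    soma_count = neur_count = 0
    soma_area = neur_area = 0.0
    h, w = partition.soma_region.shape
    for r in regions:
        row = min(max(int(round(r.centroid_px[0])), 0), h - 1)
        col = min(max(int(round(r.centroid_px[1])), 0), w - 1)
        if partition.soma_region[row, col]:
            soma_count += 1
            soma_area += r.area_um2
        elif partition.proximal_region[row, col]:
            neur_count += 1
            neur_area += r.area_um2
    return DistributionSummary(
        soma_count=soma_count,
        neurite_count=neur_count,
        soma_area_um2=soma_area,
        neurite_area_um2=neur_area,
        soma_percent_area=100.0 * soma_area / partition.soma_area_um2
        if partition.soma_area_um2 > 0
        else 0.0,
        neurite_percent_area=100.0 * neur_area / partition.proximal_area_um2
        if partition.proximal_area_um2 > 0
        else 0.0,
    )


def contact_fraction(
    po_regions: list[Region],
    mito_mask: np.ndarray,
    analysis_region: np.ndarray,
    dilation_px: int = 1,
) -> ContactSummary:
    """Fraction of POs overlapping or 8-adjacent to the mitochondria mask.

    Only POs whose centroid lies inside ``analysis_region`` are counted.
    PO regions must carry pixel coordinates (``keep_coords=True`` at
    detection time).
    """
    if dilation_px > 0:
        size = 2 * dilation_px + 1
        dilated = ndi.binary_dilation(mito_mask, structure=np.ones((size, size), dtype=bool))
    else:
        dilated = mito_mask.astype(bool)
    h, w = analysis_region.shape
    total = hits = 0
    for r in po_regions:
        row = min(max(int(round(r.centroid_px[0])), 0), h - 1)
        col = min(max(int(round(r.centroid_px[1])), 0), w - 1)
        if not analysis_region[row, col]:
            continue
        if r.coords is None:
            raise ValueError("PO regions need coords; detect with keep_coords=True")
        total += 1
        if dilated[r.coords[:, 0], r.coords[:, 1]].any():
            hits += 1
    if total == 0:
        raise UndefinedFractionError("no POs inside the analysis region")
    return ContactSummary(n_po_total=total, n_po_contact=hits)


_STAR_LEVELS = ((0.001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


def compare_groups(
    values_a, values_b, direction: str = "greater"
) -> ComparisonResult:
    """One-tailed unpaired pooled-variance t-test.

    ``direction='greater'`` tests mean(values_b) > mean(values_a);
    ``'less'`` tests the opposite.  Zero variance in both groups with equal
    means returns t = 0, p = 0.5, flagged degenerate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = b.mean() - a.mean()
    if sp2 == 0:
        if diff == 0:
            return ComparisonResult(t=0.0, df=df, p=0.5, stars="ns", degenerate=True)
        t = np.inf * np.sign(diff)
    else:
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = float(stats.t.sf(t, df)) if direction == "greater" else float(stats.t.cdf(t, df))
    stars = "ns"
    for level, s in _STAR_LEVELS:
        if p < level:
            stars = s
            break
    return ComparisonResult(t=float(t), df=df, p=p, stars=stars)
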