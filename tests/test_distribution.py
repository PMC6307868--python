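"""Compartment partitioning, distribution summaries, contacts, group comparison."""

import numpy as np
import pytest
from scipy import stats

import neurorg as ng
from neurorg.detection import Region
from neurorg.distribution import (
    compare_groups,
    contact_fraction,
    distribution_summary,
    proximal_region,
)
from neurorg.errors import UndefinedFractionError
from neurorg.segmentation import SegmentationMasks


def corridor_masks(length_px=500, width_px=15, ps=0.08):
    h = 64
    soma = np.zeros((h, 40 + length_px), bool)
    rr, cc = np.mgrid[: h, : soma.shape[1]].astype(float)
    soma[(rr - 32) ** 2 + (cc - 20) ** 2 <= 15**2] = True
    neurite = np.zeros_like(soma)
    lo = 32 - width_px // 2
    neurite[lo : lo + width_px, 36 : 36 + length_px] = True
    neurite &= ~soma
    return SegmentationMasks(soma, neurite, (32.0, 20.0))


def fake_region(row, col, px_count=10, ps=0.08):
    return Region(
        frame_index=0, label=1, centroid_um=(col * ps, row * ps),
        centroid_px=(row, col), pixel_count=px_count,
        area_um2=px_count * ps * ps, bbox=(0, 0, 1, 1),
    )


class TestProximalRegion:
    def test_strip_area_matches_analytic(self):
        ps = 0.08
        masks = corridor_masks(length_px=625)  # 50 um corridor
        part = proximal_region(masks, ps, length=30.0)
        width_um = 15 * ps
        assert part.proximal_area_um2 == pytest.approx(30.0 * width_um, rel=0.10)

    def test_short_neurite_fully_included(self):
        masks = corridor_masks(length_px=250)  # 20 um
        part = proximal_region(masks, 0.08, length=30.0)
        assert part.proximal_region.sum() == masks.neurite_mask.sum()

    def test_disjoint_from_soma(self):
        part = proximal_region(corridor_masks(), 0.08)
        assert not (part.proximal_region & part.soma_region).any()

    def test_unreachable_pixels_counted(self):
        masks = corridor_masks()
        masks.neurite_mask[5:9, 450:470] = True  # floating island
        part = proximal_region(masks, 0.08)
        assert part.unreachable_px >= 1


class TestDistributionSummary:
    def test_no_detections_zeros(self):
        part = proximal_region(corridor_masks(), 0.08)
        s = distribution_summary([], part, 0.08)
        assert s.soma_count == 0 and s.neurite_count == 0
        assert s.soma_area_um2 == 0 and s.neurite_percent_area == 0

    def test_centroid_membership(self):
        part = proximal_region(corridor_masks(), 0.08)
        regions = [fake_region(32, 20), fake_region(32, 100), fake_region(2, 500)]
        s = distribution_summary(regions, part, 0.08)
        assert s.soma_count == 1       # first region in soma
        assert s.neurite_count == 1    # second in proximal strip; third nowhere

    def test_percent_area_bounds(self):
        part = proximal_region(corridor_masks(), 0.08)
        regions = [fake_region(32, 100, px_count=50)]
        s = distribution_summary(regions, part, 0.08)
        assert 0 <= s.neurite_percent_area <= 100


class TestContactFraction:
    @staticmethod
    def po_region(row, col, size=2):
        coords = np.array(
            [[row + i, col + j] for i in range(size) for j in range(size)]
        )
        return Region(
            frame_index=0, label=1, centroid_um=(col * 0.08, row * 0.08),
            centroid_px=(float(row), float(col)), pixel_count=size * size,
            area_um2=size * size * 0.0064, bbox=(row, col, row + size, col + size),
            coords=coords,
        )

    def test_all_overlapping_is_one(self):
        mito = np.zeros((64, 64), bool)
        mito[20:40, 20:40] = True
        region_mask = np.ones((64, 64), bool)
        pos = [self.po_region(25, 25), self.po_region(30, 30)]
        s = contact_fraction(pos, mito, region_mask)
        assert s.contact_fraction == 1.0

    def test_all_far_is_zero(self):
        mito = np.zeros((64, 64), bool)
        mito[0:5, 0:5] = True
        pos = [self.po_region(40, 40), self.po_region(50, 50)]
        s = contact_fraction(pos, mito, np.ones((64, 64), bool))
        assert s.contact_fraction == 0.0

    def test_adjacency_counts_as_contact(self):
        mito = np.zeros((64, 64), bool)
        mito[10:20, 10:20] = True
        # PO region diagonally adjacent (8-neighbourhood) to the mito mask
        po = self.po_region(20, 20)
        s = contact_fraction([po], mito, np.ones((64, 64), bool), dilation_px=1)
        assert s.n_po_contact == 1
        # with no dilation the same region does not overlap
        s0 = contact_fraction([po], mito, np.ones((64, 64), bool), dilation_px=0)
        assert s0.n_po_contact == 0

    def test_outside_analysis_region_excluded(self):
        mito = np.zeros((64, 64), bool)
        analysis = np.zeros((64, 64), bool)
        analysis[:, :32] = True
        pos = [self.po_region(10, 10), self.po_region(10, 50)]
        s = contact_fraction(pos, mito, analysis)
        assert s.n_po_total == 1

    def test_zero_po_raises(self):
        with pytest.raises(UndefinedFractionError):
            contact_fraction([], np.zeros((8, 8), bool), np.ones((8, 8), bool))


class TestCompareGroups:
    def test_identical_groups(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(0.5)

    def test_textbook_example(self):
        r = compare_groups([1, 2, 3], [2, 3, 4], direction="greater")
        assert r.t == pytest.approx(1.2247, abs=1e-4)
        assert r.df == 4
        assert r.p == pytest.approx(0.1438, abs=1e-3)

    def test_direction_reversal(self):
        a, b = [1.0, 2.0, 3.5], [2.0, 3.0, 4.0]
        pg = compare_groups(a, b, "greater").p
        pl = compare_groups(a, b, "less").p
        assert pg + pl == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_scipy_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 20))
        b = rng.normal(0.5, 1.5, rng.integers(3, 20))
        r = compare_groups(a, b, "greater")
        ref = stats.ttest_ind(b, a, equal_var=True, alternative="greater")
        assert r.t == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_zero_variance(self):
        r = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert r.degenerate and r.p == 0.5

    def test_stars(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, 30)
        b = rng.normal(5, 0.1, 30)
        assert compare_groups(a, b, "greater").stars == "****"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestFixedRecovery:
    def test_counts_exact_and_areas(self):
        # planted counts recovered exactly at the 0.5 um separation default;
        # soma area within the 10% band, neurite area within 15% (Otsu skirt
        # bias is largest for the smallest spots; see methods note)
        config = ng.ImagingConfig(frame_shape=(1280, 1280), channels=("PO", "CYTO"))
        from neurorg import pipeline

        spec = ng.fixed_spec_from_preset("fixed-acbd5", config, seed=11)
        stack, truth = ng.render_fixed_neuron(spec, config, seed=11)
        _, _, _, summary = pipeline.analyze_fixed(stack)
        assert summary.soma_count == 88
        assert summary.neurite_count == 99
        assert summary.soma_area_um2 == pytest.approx(11.0, rel=0.10)
        assert summary.neurite_area_um2 == pytest.approx(11.0, rel=0.15)


class TestContactRecovery:
    def test_planted_fraction_recovered(self):
        from neurorg import pipeline

        config = ng.ImagingConfig(frame_shape=(1280, 1280), channels=("PO", "MITO"))
        stack, truth = ng.make_contact_fixture(config, n_po=120, seed=8)
        s = pipeline.measure_contacts(stack)
        planted = truth.meta["planted_fraction"]
        se = np.sqrt(planted * (1 - planted) / 120)
        assert abs(s.contact_fraction - planted) <= 3 * se + 0.02
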