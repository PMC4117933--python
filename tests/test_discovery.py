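import numpy as np
import pytest

from locuscn import (GenomicInterval, WindowGrid, derive_subregions,
                     identify_polymorphic_region, subregion_stats)
from locuscn.discovery import SubRegionProfile
from locuscn.segment import Segment, SegmentList


def _seglist(sid, bounds, means, n):
    segs = [Segment(a, b, m) for (a, b), m in zip(zip(bounds[:-1], bounds[1:]), means)]
    assert bounds[0] == 0 and bounds[-1] == n
    return SegmentList(sid, segs, n)


GRID = WindowGrid("c", 0, 200_000, 1000)  # 200 windows


class TestDeriveSubregions:
    def test_single_sample_single_segment(self):
        sls = [_seglist("a", [0, 200], [0.0], 200)]
        assert derive_subregions(sls) == [(0, 200)]

    def test_union_of_breakpoints(self):
        sls = [
            _seglist("a", [0, 100, 200], [0, 1], 200),
            _seglist("b", [0, 150, 200], [0, 1], 200),
        ]
        assert derive_subregions(sls) == [(0, 100), (100, 150), (150, 200)]

    def test_identical_breakpoints_idempotent(self):
        sls = [
            _seglist(s, [0, 50, 120, 200], [0, 1, 0], 200) for s in "abc"
        ]
        assert derive_subregions(sls) == [(0, 50), (50, 120), (120, 200)]

    def test_inconsistent_grids_rejected(self):
        sls = [
            _seglist("a", [0, 200], [0.0], 200),
            _seglist("b", [0, 100], [0.0], 100),
        ]
        with pytest.raises(ValueError):
            derive_subregions(sls)


class TestSubregionStats:
    def _profile(self, values_per_sample):
        """Samples with one breakpoint at 100; values = (left, right)."""
        sls = [
            _seglist(f"s{i}", [0, 100, 200], v, 200)
            for i, v in enumerate(values_per_sample)
        ]
        subs = derive_subregions(sls)
        return subregion_stats(sls, subs, GRID)

    def test_equal_values_zero_sd(self):
        prof = self._profile([(0.5, 1.0)] * 4)
        np.testing.assert_allclose(prof.sd, 0.0)

    def test_sample_sd_hand_value(self):
        prof = self._profile([(0, 9), (0, 9), (2, 9), (2, 9)])
        assert prof.sd[0] == pytest.approx(1.1547, abs=1e-4)

    def test_median_percentile(self):
        prof = self._profile([(1, 0), (2, 0), (3, 0)])
        assert prof.percentiles["p50"][0] == pytest.approx(2.0)

    def test_values_are_exact_segment_means(self):
        prof = self._profile([(0.123456, -1.5)] * 2)
        np.testing.assert_array_equal(prof.values[:, 0], 0.123456)

    def test_requires_two_samples(self):
        sls = [_seglist("a", [0, 200], [0.0], 200)]
        with pytest.raises(ValueError):
            subregion_stats(sls, derive_subregions(sls), GRID)


def _profile_from_sd(sd, width_windows=10):
    subs = [
        (i * width_windows, (i + 1) * width_windows) for i in range(len(sd))
    ]
    grid = WindowGrid("c", 0, len(sd) * width_windows * 1000, 1000)
    values = np.zeros((2, len(sd)))
    import pandas as pd

    pct = pd.DataFrame({f"p{q}": np.zeros(len(sd)) for q in (1, 5, 25, 50, 75, 95, 99)})
    return SubRegionProfile(grid, subs, values, ["a", "b"], np.asarray(sd, float), pct)


def _gene_in_subregion(profile, k):
    lo, hi = profile.subregions[k]
    g = profile.grid
    return GenomicInterval(g.contig, g.region_start + lo * g.window_size + 1,
                           g.region_start + hi * g.window_size - 1)


class TestIdentifyPolymorphicRegion:
    def test_all_below_threshold_no_region(self):
        prof = _profile_from_sd([0.1, 0.2, 0.3])
        res = identify_polymorphic_region(prof, _gene_in_subregion(prof, 1))
        assert not res.found and res.runs == []

    def test_thresholded_run_containing_gene(self):
        prof = _profile_from_sd([0.2, 0.9, 0.85, 0.2])
        res = identify_polymorphic_region(prof, _gene_in_subregion(prof, 1))
        assert res.found
        lo, _ = prof.subregions[1]
        _, hi = prof.subregions[2]
        assert res.gene_region.start == prof.grid.region_start + lo * 1000
        assert res.gene_region.end == prof.grid.region_start + hi * 1000

    def test_bridging_short_low_sd_gap(self):
        prof = _profile_from_sd([0.9, 0.4, 0.9], width_windows=4)
        res = identify_polymorphic_region(
            prof, _gene_in_subregion(prof, 0), max_bridge_bp=5000
        )
        assert len(res.runs) == 1
        assert res.gene_region.length == 12 * 1000

    def test_long_gap_not_bridged(self):
        prof = _profile_from_sd([0.9, 0.4, 0.9], width_windows=10)
        res = identify_polymorphic_region(
            prof, _gene_in_subregion(prof, 0), max_bridge_bp=5000
        )
        assert len(res.runs) == 2
        assert res.gene_region.length == 10 * 1000

    def test_raising_threshold_never_enlarges_region(self):
        rng = np.random.default_rng(3)
        sd = rng.uniform(0.2, 1.2, 30)
        prof = _profile_from_sd(list(sd))
        gene = _gene_in_subregion(prof, 15)
        prev = None
        for thr in (0.3, 0.5, 0.7, 0.9, 1.1):
            res = identify_polymorphic_region(prof, gene, sd_threshold=thr)
            size = res.gene_region.length if res.found else 0
            if prev is not None:
                assert size <= prev
            prev = size


def test_discovered_region_matches_truth_on_simulated_cohort(small_cohort):
    """Only the block is CN-variable; the found region should match it to
    within one window at 30x coverage."""
    from locuscn import compute_ratios, segment_sample, standardize

    cfg, counts, truth = small_cohort
    std = standardize(compute_ratios(counts))
    sls = [
        segment_sample(std.x[i], std.mask, seed=100 + i, sample_id=s)
        for i, s in enumerate(counts.sample_ids)
    ]
    prof = subregion_stats(sls, derive_subregions(sls), counts.grid)
    res = identify_polymorphic_region(prof, truth.gene)
    assert res.found
    w = cfg.window_size
    assert abs(res.gene_region.start - truth.block.start) <= w
    assert abs(res.gene_region.end - truth.block.end) <= w
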