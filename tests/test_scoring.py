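import numpy as np
import pytest

from locuscn import (GenomicInterval, Rule, ScoreParams, WindowGrid,
                     gene_score, pooled_gene_score)
from locuscn.segment import Segment, SegmentList

from rule_reference import (GRID, W, build_case, generate_cases,
                            reference_gene_score)

PARAMS = ScoreParams(window_size=W)  # tau 0.35, boundary threshold 250 bp


def _run_case(case):
    means, fc, lc, z = case
    sl, gene, x, expected = build_case(list(means), fc, lc, z)
    got = gene_score(sl, gene, x, GRID, PARAMS)
    want_score, want_rule = reference_gene_score(
        expected, PARAMS.merge_threshold, PARAMS.boundary_len_bp
    )
    return got, want_score, want_rule


class TestRuleExamples:
    def test_single_segment(self):
        sl = SegmentList("s", [Segment(0, GRID.n_windows, 0.8)], GRID.n_windows)
        gs = gene_score(sl, GenomicInterval("c", 1000, 3000),
                        np.full(GRID.n_windows, 0.8), GRID, PARAMS)
        assert gs.rule is Rule.SINGLE_SEGMENT
        assert gs.score == pytest.approx(0.8)

    def test_length_weighted_same_sign_merge(self):
        # clipped lengths 1000 and 500 bp, means 0.6 / 0.9 -> 0.7
        segs = [Segment(0, 4, 0.6), Segment(4, GRID.n_windows, 0.9)]
        sl = SegmentList("s", segs, GRID.n_windows)
        gene = GenomicInterval("c", 4 * W - 1000, 4 * W + 500)
        x = np.full(GRID.n_windows, 0.6)
        x[4:] = 0.9
        gs = gene_score(sl, gene, x, GRID, PARAMS)
        assert gs.rule is Rule.SAME_SIGN_MERGE
        assert gs.score == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "z,rule,score",
        [(0.3, Rule.BOUNDARY_ZSCORE_RESCUE, 0.5), (-0.3, Rule.ZERO_DEFAULT, 0.0)],
    )
    def test_boundary_zscore_arbitration(self, z, rule, score):
        # 1700 bp at +0.5 then a 200 bp opposite-sign boundary segment
        segs = [Segment(0, 10, 0.5), Segment(10, GRID.n_windows, -0.1)]
        sl = SegmentList("s", segs, GRID.n_windows)
        gene = GenomicInterval("c", 10 * W - 1700, 10 * W + 200)
        x = np.full(GRID.n_windows, 0.5)
        x[10:] = z
        gs = gene_score(sl, gene, x, GRID, PARAMS)
        assert gs.rule is rule
        assert gs.score == pytest.approx(score)

    def test_gene_outside_grid_errors(self):
        sl = SegmentList("s", [Segment(0, GRID.n_windows, 0.5)], GRID.n_windows)
        with pytest.raises(ValueError):
            gene_score(sl, GenomicInterval("c", 60_000, 61_000),
                       np.zeros(GRID.n_windows), GRID, PARAMS)


class TestGeneratedSuite:
    @pytest.mark.parametrize("case", generate_cases(),
                             ids=lambda c: f"{c[0]}|{c[1]}|{c[2]}|{c[3]}")
    def test_matches_straight_line_reference(self, case):
        got, want_score, want_rule = _run_case(case)
        assert got.rule.value == want_rule
        assert got.score == pytest.approx(want_score, abs=1e-12)

    def test_every_rule_branch_hit(self):
        rules = {_run_case(c)[0].rule for c in generate_cases()}
        assert rules == set(Rule)


class TestProperties:
    def test_score_bounded_by_clipped_means_unless_zeroed(self):
        for case in generate_cases():
            means, fc, lc, z = case
            got, _, _ = _run_case(case)
            if got.rule is not Rule.ZERO_DEFAULT:
                assert min(means) - 1e-12 <= got.score <= max(means) + 1e-12

    def test_scale_equivariance(self):
        lam = 3.7
        for case in generate_cases()[::7]:
            means, fc, lc, z = case
            sl, gene, x, _ = build_case(list(means), fc, lc, z)
            base = gene_score(sl, gene, x, GRID, PARAMS)
            scaled_sl = SegmentList(
                sl.sample_id,
                [Segment(s.start_window, s.end_window, lam * s.mean)
                 for s in sl.segments],
                sl.n_windows,
            )
            scaled_params = ScoreParams(
                window_size=W, merge_threshold=lam * PARAMS.merge_threshold
            )
            scaled = gene_score(scaled_sl, gene, lam * x, GRID, scaled_params)
            assert scaled.rule == base.rule
            assert scaled.score == pytest.approx(lam * base.score)

    def test_storage_order_irrelevant(self):
        means = (0.9, -0.2, 0.8)
        sl, gene, x, _ = build_case(list(means), 150, 700, 0.3)
        shuffled = SegmentList(sl.sample_id, sl.segments[::-1], sl.n_windows)
        a = gene_score(sl, gene, x, GRID, PARAMS)
        b = gene_score(shuffled, gene, x, GRID, PARAMS)
        assert (a.score, a.rule) == (b.score, b.rule)


class TestPooledScore:
    def test_single_covering_segment(self):
        sl = SegmentList("s", [Segment(0, GRID.n_windows, -0.4)], GRID.n_windows)
        gs = pooled_gene_score(sl, GenomicInterval("c", 1000, 3000), GRID)
        assert gs.rule is Rule.SINGLE_SEGMENT
        assert gs.score == pytest.approx(-0.4)

    @pytest.mark.parametrize("means", [(0.5, 0.9), (0.7, 0.7)])
    def test_any_split_zeroes_even_cosmetic(self, means):
        segs = [Segment(0, 10, means[0]), Segment(10, GRID.n_windows, means[1])]
        sl = SegmentList("s", segs, GRID.n_windows)
        gene = GenomicInterval("c", 10 * W - 1000, 10 * W + 1000)
        gs = pooled_gene_score(sl, gene, GRID)
        assert gs.rule is Rule.ZERO_DEFAULT and gs.score == 0.0
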