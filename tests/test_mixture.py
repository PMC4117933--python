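import numpy as np
import pytest

from locuscn import (CNCalls, assign_cn, bic_select, choose_K, detect_outliers,
                     em_fit)
from locuscn.mixture import MixtureModel, fit_reference_grid, robust_distances


class TestEmFit:
    def test_k1_closed_form(self, rng):
        x = rng.normal(2.0, 0.5, 200)
        model, resp = em_fit(x, 1)
        assert model.means[0] == pytest.approx(x.mean())
        assert model.sds[0] == pytest.approx(x.std())
        assert model.weights[0] == 1.0
        np.testing.assert_allclose(resp, 1.0)

    def test_two_point_masses(self):
        x = np.concatenate([np.full(100, -1.0), np.full(100, 1.0)])
        model, resp = em_fit(x, 2, seed=1)
        np.testing.assert_allclose(model.means, [-1.0, 1.0], atol=1e-6)
        np.testing.assert_allclose(model.weights, [0.5, 0.5], atol=1e-6)
        assert (resp.argmax(axis=1) == (x > 0)).all()

    def test_mixture_recovery(self):
        rng = np.random.default_rng(77)
        n1 = 600
        x = np.concatenate(
            [rng.normal(0.0, 0.15, n1), rng.normal(1.0, 0.15, 1000 - n1)]
        )
        model, _ = em_fit(x, 2, seed=3)
        assert abs(model.means[0] - 0.0) <= 0.05
        assert abs(model.means[1] - 1.0) <= 0.05
        assert abs(model.weights[0] - 0.6) <= 0.05

    def test_means_sorted(self, rng):
        x = np.concatenate([rng.normal(5, 0.2, 50), rng.normal(-5, 0.2, 50)])
        model, _ = em_fit(x, 2, seed=0)
        assert model.means[0] < model.means[1]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            em_fit(np.arange(9.0), 2)


class TestBicSelect:
    def test_unimodal_picks_one(self, rng):
        x = rng.normal(0, 1, 300)
        assert bic_select(x, range(1, 5), seed=2) == 1

    def test_well_separated_three_components(self, rng):
        x = np.concatenate(
            [rng.normal(0, 0.2, 100), rng.normal(2, 0.2, 100),
             rng.normal(4, 0.2, 100)]
        )
        assert bic_select(x, range(1, 6), seed=2) == 3

    def test_oversized_k_skipped_with_warning(self, rng):
        x = rng.normal(0, 1, 12)
        with pytest.warns(UserWarning, match="skipping"):
            k = bic_select(x, range(1, 6), seed=0)
        assert k in (1, 2)


class TestChooseK:
    def test_printed_range_and_distances_give_ten_groups(self):
        assert choose_K(-1.66, 3.42, [0.39, 0.62]) == 10

    def test_zero_range(self):
        assert choose_K(0.0, 0.0, [0.5]) == 1

    def test_hand_formula(self):
        assert choose_K(0.0, 2.0, [0.5]) == 4

    def test_invalid_distances(self):
        with pytest.raises(ValueError):
            choose_K(0.0, 1.0, [])


class TestRobustDistances:
    def test_intra_cluster_split_filtered(self):
        m = MixtureModel(
            np.array([-9.5, -5.0, -0.9, -0.2, 4.0]),
            np.ones(5), np.full(5, 0.2),
        )
        d = robust_distances(m)
        np.testing.assert_allclose(d, [4.5, 4.1, 4.2])

    def test_regular_spacing_untouched(self):
        m = MixtureModel(np.array([0.0, 1.0, 2.0]), np.ones(3), np.full(3, 1 / 3))
        np.testing.assert_allclose(robust_distances(m), [1.0, 1.0])


class TestFitReferenceGrid:
    def _model(self, means):
        means = np.asarray(means, dtype=float)
        k = means.size
        return MixtureModel(means, np.full(k, 0.3), np.full(k, 1 / k))

    def test_clean_grid_recovered_exactly(self):
        d, a = fit_reference_grid(self._model([0.0, 4.5, 9.0, 13.5]))
        assert d == pytest.approx(4.5)
        assert a == pytest.approx(0.0)

    def test_split_cluster_does_not_bias_spacing_or_anchor(self):
        # true grid 0, 4.5, 9, 13.5 with the 9-group split into 8.8/9.2
        d, a = fit_reference_grid(self._model([0.0, 4.5, 8.8, 9.2, 13.5]))
        assert d == pytest.approx(4.5)
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_fixed_distance_fits_anchor_only(self):
        d, a = fit_reference_grid(self._model([0.1, 4.6, 9.1]), distance=4.5)
        assert d == 4.5
        assert a == pytest.approx(0.1)

    def test_single_component_needs_distance(self):
        with pytest.raises(ValueError):
            fit_reference_grid(self._model([1.0]))
        d, a = fit_reference_grid(self._model([1.0]), distance=0.57)
        assert (d, a) == (0.57, 1.0)


class TestOutliers:
    def test_no_outliers(self):
        kept, idx = detect_outliers([0.1, 0.2, 3.0], 3.42)
        assert idx.size == 0 and kept.size == 3

    def test_flagged_above_bound(self):
        kept, idx = detect_outliers([0.1, 0.2, 4.5], 3.42)
        assert list(idx) == [2]
        np.testing.assert_allclose(kept, [0.1, 0.2])

    def test_all_flagged_rejected(self):
        with pytest.raises(ValueError):
            detect_outliers([5.0, 6.0], 3.42)


class TestAssignCn:
    def _calls(self, groups, K):
        n = len(groups)
        probs = np.zeros((n, K))
        probs[np.arange(n), groups] = 1.0
        return CNCalls([f"s{i}" for i in range(n)], np.array(groups), probs,
                       np.zeros(n, dtype=bool))

    def test_zero_based(self):
        calls = assign_cn(self._calls([3], 10), 0)
        assert calls.cn[0] == 3 and calls.cn_labels[0] == "3"

    def test_smallest_group_cn_two(self):
        calls = assign_cn(self._calls([0], 8), 2)
        assert calls.cn[0] == 2 and calls.cn_labels[0] == "2"

    def test_top_group_open_class(self):
        calls = assign_cn(self._calls([9], 10), 0)
        assert calls.cn[9 - 9] == 9
        assert calls.cn_labels[0] == ">=9"

    def test_negative_base_rejected(self):
        with pytest.raises(ValueError):
            assign_cn(self._calls([0], 2), -1)
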