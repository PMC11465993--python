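"""Metrics: confusion-matrix ratios, matching, RMS, heatmaps, SSIM."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from skimage.metrics import structural_similarity as sk_ssim

import multispot as ms
from multispot.evaluation import ConfusionMatrix


class TestClassificationMetrics:
    def test_perfect_matrix(self):
        p, r, a = ms.classification_metrics(ConfusionMatrix(10, 0, 0, 10))
        assert (p, r, a) == (1.0, 1.0, 1.0)

    def test_direct_arithmetic(self):
        p, r, a = ms.classification_metrics(ConfusionMatrix(9, 1, 1, 9))
        assert p == pytest.approx(0.9)
        assert r == pytest.approx(0.9)
        assert a == pytest.approx(0.9)

    def test_undefined_precision_flagged_as_nan(self):
        with pytest.warns(UserWarning, match="precision"):
            p, _, _ = ms.classification_metrics(ConfusionMatrix(0, 0, 5, 5))
        assert np.isnan(p)

    def test_random_matrices_match_direct_formulas(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 100, size=4)
            p, r, a = ms.classification_metrics(ConfusionMatrix(tp, fp, fn, tn))
            assert p == pytest.approx(tp / (tp + fp))
            assert r == pytest.approx(tp / (tp + fn))
            assert a == pytest.approx((tp + tn) / (tp + fp + fn + tn))


class TestMatching:
    def test_identity_assignment_for_identical_lists(self):
        pts = np.array([[0.0, 0.0], [50.0, 50.0]])
        assert list(ms.match_emitters(pts, pts)) == [0, 1]

    def test_swapped_labels_produce_crossing_assignment(self):
        truth = np.array([[0.0, 0.0], [100.0, 0.0]])
        pred = truth[::-1]
        assert list(ms.match_emitters(pred, truth)) == [1, 0]

    def test_matches_brute_force_on_random_four_point_instances(self):
        """Min-cost assignment equals exhaustive search over all 24 orderings."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            pred = rng.uniform(0, 240, size=(4, 2))
            truth = rng.uniform(0, 240, size=(4, 2))
            assign = ms.match_emitters(pred, truth)
            cost = np.sum((pred - truth[assign]) ** 2)
            best = min(
                np.sum((pred - truth[list(perm)]) ** 2)
                for perm in permutations(range(4))
            )
            assert cost == pytest.approx(best)


class TestRms:
    def test_exact_match_is_zero(self):
        pts = [[1.0, 2.0], [3.0, 4.0]]
        assert ms.rms_error(pts, pts) == 0.0

    def test_single_emitter_offset(self):
        # sqrt(25/2) for an offset of (3,4)
        assert ms.rms_error([[3.0, 4.0]], [[0.0, 0.0]]) == pytest.approx(np.sqrt(12.5))

    def test_two_emitters_one_offset(self):
        pred = [[3.0, 4.0], [10.0, 10.0]]
        truth = [[0.0, 0.0], [10.0, 10.0]]
        assert ms.rms_error(pred, truth) == pytest.approx(2.5)

    def test_invariant_under_emitter_relabeling(self):
        rng = np.random.default_rng(3)
        truth = rng.uniform(0, 240, (3, 2))
        pred = truth + rng.normal(0, 5, (3, 2))
        assert ms.rms_error(pred[::-1], truth) == pytest.approx(ms.rms_error(pred, truth))

    def test_scales_linearly_with_coordinates(self):
        pred = np.array([[3.0, 4.0], [9.0, 1.0]])
        truth = np.zeros((2, 2))
        assert ms.rms_error(3 * pred, 3 * truth) == pytest.approx(3 * ms.rms_error(pred, truth))

    def test_midpoint_baseline_closed_form(self):
        """Predicting both emitters of a pair at the midpoint gives d/(2*sqrt2)."""
        d = 30.0
        truth = np.array([[0.0, 0.0], [d, 0.0]])
        mid = np.array([[d / 2, 0.0], [d / 2, 0.0]])
        assert ms.rms_error(mid, truth) == pytest.approx(ms.midpoint_baseline_rms(d))
        assert ms.midpoint_baseline_rms(30.0) == pytest.approx(10.6066, abs=1e-3)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            ms.rms_error(np.empty((0, 2)), np.empty((0, 2)))


class TestBinning:
    def test_default_edges_give_four_bins(self):
        df = pd.DataFrame({"distance_nm": [30.0, 90.0], "rms_nm": [10.0, 12.0]})
        out = ms.bin_rms_by_distance(df)
        assert len(out) == 4

    def test_single_bin_populated(self):
        df = pd.DataFrame({"distance_nm": [30.0] * 5, "rms_nm": np.arange(5.0)})
        out = ms.bin_rms_by_distance(df)
        assert out.loc[0, "n"] == 5
        assert out.loc[1:, "n"].sum() == 0

    def test_per_bin_means_match_naive_group_by(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 240, 500)
        r = rng.uniform(0, 40, 500)
        out = ms.bin_rms_by_distance(pd.DataFrame({"distance_nm": d, "rms_nm": r}))
        for _, row in out.iterrows():
            sel = (d >= row.bin_lo_nm) & (d < row.bin_hi_nm)
            assert row.mean_rms_nm == pytest.approx(r[sel].mean())


class TestHeatmapsAndSpikes:
    def test_perfect_predictions_concentrate_at_origin(self):
        hist, edges = ms.displacement_heatmap(np.zeros((20, 2)), grid_nm=2.0)
        iy = ix = (len(edges) - 1) // 2
        assert hist[iy, ix] == 20
        assert hist.sum() == 20

    def test_isotropic_noise_gives_radially_symmetric_heatmap(self):
        rng = np.random.default_rng(5)
        disp = rng.normal(0, 10, size=(200000, 2))
        hist, _ = ms.displacement_heatmap(disp, grid_nm=10.0, extent_nm=40.0)
        assert hist.sum() > 0
        flipped = hist[::-1, ::-1]
        # Poisson counting noise: symmetric cells agree within ~4 sigma
        assert np.all(np.abs(hist - flipped) <= 4 * np.sqrt(hist + flipped + 1))

    def test_spike_rendering_conserves_counts(self):
        assert ms.render_spikes(np.empty((0, 2))).sum() == 0
        one = ms.render_spikes([[300.0, 500.0]])
        assert one.sum() == 1 and np.count_nonzero(one) == 1
        many = ms.render_spikes(np.full((7, 2), 1000.0))
        assert many.sum() == 7

    def test_out_of_canvas_coordinate_rejected(self):
        with pytest.raises(ValueError):
            ms.render_spikes([[-1.0, 10.0]])

    def test_gaussian_convolution_preserves_mass_and_linearity(self):
        rng = np.random.default_rng(6)
        a = rng.random((40, 40))
        b = rng.random((40, 40))
        assert ms.heatmap_from_spikes(np.zeros((40, 40))).sum() == 0
        single = np.zeros((41, 41))
        single[20, 20] = 1.0
        hm = ms.heatmap_from_spikes(single, 2.0)
        assert hm.sum() == pytest.approx(1.0, rel=1e-6)
        assert np.unravel_index(np.argmax(hm), hm.shape) == (20, 20)
        np.testing.assert_allclose(
            ms.heatmap_from_spikes(a + b), ms.heatmap_from_spikes(a) + ms.heatmap_from_spikes(b),
            atol=1e-12,
        )


class TestSsim:
    def test_identical_images_score_one(self):
        img = np.random.default_rng(7).random((32, 32))
        assert ms.ssim(img, img) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.random((25, 25)), rng.random((25, 25))
        assert ms.ssim(a, b) == pytest.approx(ms.ssim(b, a), abs=1e-12)

    def test_matches_reference_implementation(self):
        """Agreement with an independent SSIM implementation to 1e-6."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.random((40, 40))
            b = np.clip(a + rng.normal(0, rng.uniform(0.05, 0.5), a.shape), 0, None)
            dr = max(a.max(), b.max()) - min(a.min(), b.min())
            ours = ms.ssim(a, b, data_range=dr)
            ref = sk_ssim(a, b, win_size=7, data_range=dr, gaussian_weights=False)
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ms.ssim(np.zeros((10, 10)), np.zeros((12, 12)))
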