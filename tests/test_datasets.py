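"""Multi-emitter dataset construction: coordinate sampling and spot merging."""

import numpy as np
import pytest
from scipy.integrate import quad

import multispot as ms
from multispot.datasets import INPUT_SHAPE, translate_record
from multispot.library import SpotRecord


def _pair_distance_cdf(d, radius):
    """Closed-form CDF of the distance between two uniform points in a disk."""

    def pdf(s):
        u = s / (2 * radius)
        return (2 * s / radius**2) * (
            (2 / np.pi) * np.arccos(u) - (s / (np.pi * radius)) * np.sqrt(1 - u**2)
        )

    return np.array([quad(pdf, 0, x)[0] for x in np.atleast_1d(d)])


class TestSampleCoordinates:
    def test_pairwise_distances_bounded_by_diameter(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            pts = ms.sample_emitter_coordinates(4, rng=rng)
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            assert d.max() <= 240.0

    def test_coordinates_on_one_nm_grid(self):
        pts = ms.sample_emitter_coordinates(3, rng=2)
        np.testing.assert_array_equal(pts, np.round(pts))

    def test_fewer_than_two_emitters_rejected(self):
        with pytest.raises(ValueError):
            ms.sample_emitter_coordinates(1, rng=0)

    def test_pair_distance_matches_disk_line_picking_distribution(self):
        """Empirical pair distances follow the closed-form disk distribution."""
        rng = np.random.default_rng(3)
        n = 100000
        d = np.empty(n)
        for i in range(n):
            a, b = ms.sample_emitter_coordinates(2, rng=rng)
            d[i] = np.hypot(*(a - b))
        xs = np.linspace(1, 239, 60)
        emp = np.searchsorted(np.sort(d), xs) / n
        theo = _pair_distance_cdf(xs, 120.0)
        assert np.max(np.abs(emp - theo)) < 0.01


class TestConstrainedPair:
    def test_fixed_distance_up_to_grid_rounding(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b = ms.sample_constrained_pair((30.0, 30.0), rng)
            assert np.hypot(*(a - b)) == pytest.approx(30.0, abs=np.sqrt(2))

    def test_interval_bounds_respected(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b = ms.sample_constrained_pair((28.0, 32.0), rng)
            d = np.hypot(*(a - b))
            assert 28 - np.sqrt(2) <= d <= 32 + np.sqrt(2)

    def test_orientation_uniform(self):
        rng = np.random.default_rng(6)
        angles = []
        for _ in range(10000):
            a, b = ms.sample_constrained_pair((100.0, 100.0), rng)
            v = b - a
            angles.append(np.arctan2(v[1], v[0]) % (2 * np.pi))
        hist, _ = np.histogram(angles, bins=12, range=(0, 2 * np.pi))
        expected = len(angles) / 12
        chi2 = ((hist - expected) ** 2 / expected).sum()
        # chi-square 11 dof, 99.9th percentile ~ 31.3
        assert chi2 < 31.3

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            ms.sample_constrained_pair((0.0, 0.0), rng=0)


class TestMergeSpots:
    def test_identity_translation_preserves_image(self, small_library):
        rec = small_library[0]
        q = (rec.fit.x0_nm, rec.fit.y0_nm)
        # place the anchor at its own position inside the 15x15 canvas
        target = (q[0] + 4 * 160, q[1] + 4 * 160)
        canvas = np.zeros(INPUT_SHAPE)
        translate_record(rec, target, canvas, 160.0)
        np.testing.assert_allclose(canvas[4:11, 4:11], rec.image.pixels, atol=1e-9)

    def test_integer_pixel_shift_is_exact(self, small_library):
        rec = small_library[1]
        q = (rec.fit.x0_nm, rec.fit.y0_nm)
        spot = ms.merge_spots(
            [rec, rec],
            [(q[0] + 3 * 160, q[1] + 4 * 160), (q[0] + 4 * 160, q[1] + 4 * 160)],
        )
        expected = np.zeros(INPUT_SHAPE)
        expected[4:11, 3:10] += rec.image.pixels
        expected[4:11, 4:11] += rec.image.pixels
        np.testing.assert_allclose(spot.image.pixels, expected, atol=1e-9)

    def test_merged_matches_direct_two_emitter_render(self, noiseless_library,
                                                      noise_free_camera):
        """Anchored superposition ~ direct render of both emitters.

        At sigma = 0.64 px the spot is sampled below Nyquist, so any
        sub-pixel interpolation carries a few-percent peak error; the
        Fourier shift stays within 8% of peak while conserving flux.
        """
        psf = ms.PsfModel()
        r1, r2 = noiseless_library[0], noiseless_library[1]
        t1 = np.array([7.2 * 160, 7.5 * 160])
        t2 = t1 + np.array([95.0, -40.0])
        spot = ms.merge_spots([r1, r2], [t1, t2])
        direct = (
            ms.render_psf(t1, r1.true_photons, psf, noise_free_camera, INPUT_SHAPE).pixels
            + ms.render_psf(t2, r2.true_photons, psf, noise_free_camera, INPUT_SHAPE).pixels
        )
        assert np.max(np.abs(spot.image.pixels - direct)) < 0.08 * direct.max()
        assert spot.image.pixels.sum() == pytest.approx(direct.sum(), rel=5e-3)

    def test_single_gaussian_center_lies_between_two_emitters(self, noiseless_library):
        """A single-Gaussian fit of a two-emitter spot lands between them."""
        r1, r2 = noiseless_library[2], noiseless_library[3]
        t1 = np.array([6.9 * 160, 7.4 * 160])
        t2 = t1 + np.array([180.0, 60.0])
        spot = ms.merge_spots([r1, r2], [t1, t2])
        fit = ms.fit_gaussian_2d(spot.image)
        lo = np.minimum(t1, t2) - 1.0
        hi = np.maximum(t1, t2) + 1.0
        assert lo[0] <= fit.x0_nm <= hi[0] and lo[1] <= fit.y0_nm <= hi[1]

    def test_target_outside_crop_rejected(self, small_library):
        with pytest.raises(ValueError):
            ms.merge_spots([small_library[0]], [(-50.0, 100.0)])


class TestPadToInput:
    def test_eleven_to_fifteen_pads_two_pixel_border(self):
        inner = np.arange(121, dtype=float).reshape(11, 11)
        img = ms.SpotImage(inner, offset_nm=(0.0, 0.0))
        out = ms.pad_to_input(img)
        assert out.shape == (15, 15)
        np.testing.assert_array_equal(out.pixels[2:13, 2:13], inner)
        assert np.all(out.pixels[:2, :] == 0) and np.all(out.pixels[:, :2] == 0)

    def test_identity_when_already_target_shape(self):
        img = ms.SpotImage(np.random.default_rng(0).random((15, 15)))
        out = ms.pad_to_input(img)
        np.testing.assert_array_equal(out.pixels, img.pixels)
        assert out.offset_nm == img.offset_nm

    def test_global_coordinates_survive_padding(self):
        img = ms.SpotImage(np.ones((11, 11)), offset_nm=(800.0, 1600.0))
        out = ms.pad_to_input(img)
        # a global position at the old crop's pixel (0,0) center
        gx, gy = 800.0 + 80.0, 1600.0 + 80.0
        col_old = (gx - img.offset_nm[0]) / 160.0
        col_new = (gx - out.offset_nm[0]) / 160.0
        assert col_new == col_old + 2
        assert (gy - out.offset_nm[1]) / 160.0 == (gy - img.offset_nm[1]) / 160.0 + 2

    def test_oversized_input_rejected(self):
        with pytest.raises(ValueError):
            ms.pad_to_input(ms.SpotImage(np.zeros((17, 17))))


class TestBuildDataset:
    def test_balanced_classes_and_sizes(self, small_library):
        ds = ms.build_dataset(small_library, 50, (1, 2), rng=7)
        assert len(ds) == 100
        assert (ds.counts == 1).sum() == 50 and (ds.counts == 2).sum() == 50

    def test_two_emitter_distances_below_diffraction_limit(self, mini_dataset):
        d = mini_dataset.pair_distance_nm[mini_dataset.counts == 2]
        assert np.all(d <= 240.0)

    def test_fixed_seed_reproduces_dataset_hash(self, small_library):
        a = ms.build_dataset(small_library, 30, (1, 2), rng=8)
        b = ms.build_dataset(small_library, 30, (1, 2), rng=8)
        assert a.content_hash() == b.content_hash()

    def test_train_test_molecules_disjoint(self, small_library):
        ds = ms.build_dataset(small_library, 100, (1, 2), rng=9)
        assert set(ds.split) == {"train", "test"}

    def test_empty_library_rejected(self, small_library):
        with pytest.raises(ValueError):
            ms.build_dataset(small_library.subset([]), 10)
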