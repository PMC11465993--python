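"""Network losses, architecture contracts, and small-scale trainability."""

import numpy as np
import pytest

import multispot as ms
from multispot.datasets import LabeledDataset


class TestClassificationLoss:
    def test_perfect_prediction_is_zero(self):
        assert ms.classification_loss([0.0, 1.0], [0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_two_class_is_ln2(self):
        assert ms.classification_loss([0.5, 0.5], [1.0, 0.0]) == pytest.approx(np.log(2))

    def test_confident_correct_prediction(self):
        # q = (0.9, 0.1), truth class 1 -> -ln 0.9
        assert ms.classification_loss([0.9, 0.1], [1.0, 0.0]) == pytest.approx(
            -np.log(0.9), rel=1e-9
        )

    def test_zero_probability_clipped_not_infinite(self):
        with pytest.warns(UserWarning):
            loss = ms.classification_loss([0.0, 1.0], [1.0, 0.0])
        assert np.isfinite(loss) and loss > 0

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            ms.classification_loss([0.7, 0.7], [1.0, 0.0])


class TestLocalizationLoss:
    def test_identical_coordinates_zero(self):
        pts = [[10.0, 20.0], [30.0, 40.0]]
        assert ms.localization_loss(pts, pts) == 0.0

    def test_single_emitter_offset(self):
        # I=1, offset (3,4): (9+16)/2 = 12.5
        assert ms.localization_loss([[3.0, 4.0]], [[0.0, 0.0]]) == pytest.approx(12.5)

    def test_permutation_min_recovers_swapped_labels(self):
        truth = np.array([[0.0, 0.0], [100.0, 0.0]])
        pred_swapped = truth[::-1]
        canonical = ms.localization_loss(truth, truth)
        assert ms.localization_loss(
            pred_swapped, truth, variant="permutation-min-mse"
        ) == pytest.approx(canonical)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ms.localization_loss([[0, 0]], [[0, 0], [1, 1]])


class TestBuildModel:
    def test_localizer_output_dimension_is_twice_the_count(self):
        cfg = ms.TrainConfig(epochs=1)
        for n in (1, 2, 3, 4):
            mdl = ms.build_model("localize", n, cfg)
            assert mdl.net.out_dim == 2 * n

    def test_classifier_emits_a_valid_simplex(self):
        cfg = ms.TrainConfig(epochs=1, seed=1)
        mdl = ms.build_model("classify", 2, cfg)
        probs = mdl.predict_proba(np.random.default_rng(0).random((3, 15, 15)) * 500)
        assert probs.shape == (3, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_zero_image_forward_pass_is_finite(self):
        cfg = ms.TrainConfig(epochs=1)
        for task, n in (("classify", 2), ("localize", 2)):
            out = ms.build_model(task, n, cfg).forward(np.zeros((15, 15)))
            assert np.all(np.isfinite(out))

    def test_unsupported_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            ms.build_model("classify", 2, ms.TrainConfig(backbone="resnet50"))

    def test_paper_scale_profile_sets_reference_schedule(self):
        cfg = ms.TrainConfig(paper_scale=True)
        assert cfg.epochs == 400
        assert cfg.lr_initial == pytest.approx(1e-5)
        assert cfg.lr_final == pytest.approx(1e-8)
        assert cfg.weight_decay == pytest.approx(0.01)
        assert cfg.batch_size == 64


def _toy_dataset(rng, n_per_class=1000):
    """Trivially separable singles (1000 photons) vs pairs (10k total, 200 nm)."""
    camera = ms.CameraModel()
    psf = ms.PsfModel()
    images, counts, coords, dists = [], [], [], []
    center = np.array([7.5 * 160, 7.5 * 160])
    for _ in range(n_per_class):
        img = ms.render_psf(center, 1000, psf, camera, (15, 15))
        img = ms.add_camera_noise(img, camera, rng)
        images.append(img.pixels.astype(np.float32))
        counts.append(1)
        coords.append(np.array([[center[0], center[1]], [np.nan, np.nan]]))
        dists.append(np.nan)
    for _ in range(n_per_class):
        theta = rng.uniform(0, 2 * np.pi)
        off = 100.0 * np.array([np.cos(theta), np.sin(theta)])
        a, b = center + off, center - off
        img = ms.render_psf(a, 5000, psf, camera, (15, 15)).pixels + ms.render_psf(
            b, 5000, psf, camera, (15, 15)
        ).pixels
        img = ms.add_camera_noise(ms.SpotImage(img), camera, rng).pixels
        images.append(img.astype(np.float32))
        counts.append(2)
        pair = np.array(sorted([a, b], key=lambda v: (v[0], v[1])))
        coords.append(pair)
        dists.append(200.0)
    n = len(images)
    split = np.array(["train"] * n, dtype=object)
    split[rng.random(n) < 0.2] = "test"
    return LabeledDataset(
        images=np.stack(images),
        counts=np.asarray(counts),
        coords_nm=np.stack(coords),
        pair_distance_nm=np.asarray(dists),
        split=split,
    )


class TestTraining:
    def test_one_epoch_history(self, mini_dataset):
        cfg = ms.TrainConfig(epochs=1, seed=5)
        mdl = ms.build_model("classify", 2, cfg)
        ms.train(mdl, mini_dataset.subset(np.arange(200)), cfg)
        assert len(mdl.history) == 1
        assert np.isfinite(mdl.history[0]["train_loss"])

    def test_separable_classes_learned_quickly(self):
        """Compact classifier separates photon-disjoint classes to >=99%."""
        rng = np.random.default_rng(31)
        ds = _toy_dataset(rng)
        cfg = ms.TrainConfig(epochs=20, seed=32)
        mdl = ms.build_model("classify", 2, cfg)
        ms.train(mdl, ds, cfg)
        te = ds.test()
        acc = (mdl.predict_count(te.images) == te.counts).mean()
        assert acc >= 0.99

    def test_noiseless_single_emitter_localizer_below_10nm(self, noise_free_camera):
        """Regression on clean single spots reaches RMS < 10 nm quickly."""
        rng = np.random.default_rng(33)
        psf = ms.PsfModel()
        images, coords = [], []
        center_px = np.array([7.5, 7.5]) * 160
        for _ in range(2000):
            pos = center_px + rng.uniform(-80, 80, size=2)
            img = ms.render_psf(pos, 5000, psf, noise_free_camera, (15, 15))
            images.append(img.pixels.astype(np.float32))
            coords.append(pos[None, :])
        n = len(images)
        split = np.array(["train"] * n, dtype=object)
        split[rng.random(n) < 0.15] = "test"
        ds = LabeledDataset(
            images=np.stack(images),
            counts=np.ones(n, dtype=int),
            coords_nm=np.stack(coords),
            pair_distance_nm=np.full(n, np.nan),
            split=split,
        )
        cfg = ms.TrainConfig(epochs=50, seed=34)
        mdl = ms.build_model("localize", 1, cfg)
        ms.train(mdl, ds, cfg)
        te = ds.test()
        pred = mdl.predict_coords(te.images) + np.array([7.5 * 160, 7.5 * 160])
        rms = np.array([ms.rms_error(pred[i], te.coords_nm[i]) for i in range(len(te))])
        assert rms.mean() < 10.0

    def test_training_is_deterministic_given_seed(self, mini_dataset):
        sub = mini_dataset.subset(np.arange(400))
        outs = []
        for _ in range(2):
            cfg = ms.TrainConfig(epochs=2, seed=35)
            mdl = ms.build_model("classify", 2, cfg)
            ms.train(mdl, sub, cfg)
            outs.append(mdl.predict_proba(sub.images[:20]))
        np.testing.assert_array_equal(outs[0], outs[1])


class TestBundlePersistence:
    def test_bundle_round_trips_through_disk(self, mini_bundle, mini_dataset, tmp_path):
        mini_bundle.save(tmp_path / "bundle")
        loaded = ms.ModelBundle.load(tmp_path / "bundle")
        imgs = mini_dataset.images[:10]
        np.testing.assert_allclose(
            loaded.classifier.predict_proba(imgs),
            mini_bundle.classifier.predict_proba(imgs),
            atol=1e-6,
        )
        np.testing.assert_allclose(
            loaded.localizers[2].predict_coords(imgs),
            mini_bundle.localizers[2].predict_coords(imgs),
            atol=1e-4,
        )

    def test_localizer_dimension_contract_enforced(self, mini_bundle):
        with pytest.raises(ValueError):
            ms.ModelBundle(
                classifier=mini_bundle.classifier,
                localizers={3: mini_bundle.localizers[2]},
            )
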