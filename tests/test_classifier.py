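"""Feature bank, training, class maps, and the evaluation protocol."""

import numpy as np
import pytest

from histoquant.classifier import (
    FEATURE_NAMES,
    INTACT,
    NECROSIS,
    ClassifierModel,
    TrainingExample,
    evaluate,
    extract_features,
    predict_map,
    sample_training_patches,
    train,
)
from histoquant.image_model import CalibratedImage, RegionAnnotation
from histoquant.synthetic import SceneParams, make_scene


def flat_image(rgb, shape=(64, 64)):
    arr = np.empty((*shape, 3), dtype=np.uint8)
    arr[:] = rgb
    return CalibratedImage(arr, mpp=1.0)


class TestFeatures:
    def test_uniform_patch_has_zero_texture(self):
        img = flat_image((130, 90, 170))
        f = extract_features(img, (32, 32), 32)
        assert len(f) == len(FEATURE_NAMES)
        named = dict(zip(FEATURE_NAMES, f))
        assert named["sd_r"] == named["sd_g"] == named["sd_b"] == 0.0
        assert named["gradient_energy"] == 0.0
        assert named["mean_r"] == 130.0

    def test_checkerboard_separates_on_texture_not_mean(self):
        board = np.zeros((32, 32, 3), dtype=np.uint8)
        board[::2, ::2] = 200
        board[1::2, 1::2] = 200
        checker = CalibratedImage(board, mpp=1.0)
        uniform = flat_image((100, 100, 100), (32, 32))
        f_c = dict(zip(FEATURE_NAMES,
                       extract_features(checker, (16, 16), 32)))
        f_u = dict(zip(FEATURE_NAMES,
                       extract_features(uniform, (16, 16), 32)))
        assert f_c["mean_r"] == pytest.approx(f_u["mean_r"])
        assert f_c["gradient_energy"] > f_u["gradient_energy"]
        assert f_c["sd_r"] > f_u["sd_r"]

    def test_patch_outside_bounds_rejected(self):
        img = flat_image((10, 10, 10), (32, 32))
        with pytest.raises(ValueError, match="bounds"):
            extract_features(img, (2, 2), 32)

    def test_feature_length_constant_across_images(self):
        rng = np.random.default_rng(0)
        lengths = set()
        for _ in range(3):
            img = CalibratedImage(
                rng.integers(0, 256, (48, 48, 3)).astype(np.uint8), mpp=1.0)
            lengths.add(len(extract_features(img, (24, 24), 32)))
        assert lengths == {len(FEATURE_NAMES)}


class TestTraining:
    def test_training_accuracy_on_separable_scenes(self, trained_necrosis_model):
        model, _, _ = trained_necrosis_model
        assert model.training_accuracy >= 0.99

    def test_single_class_training_rejected(self):
        scene = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=160, height_px=160,
            necrosis_fraction=0.5), 1)
        examples = [TrainingExample(scene.image, ann, NECROSIS)
                    for ann in scene.manual_proxies]
        with pytest.raises(ValueError, match="both"):
            train(examples, seed=0)

    def test_same_seed_reproduces_predictions(self, trained_necrosis_model):
        model, pos, neg = trained_necrosis_model
        examples = [TrainingExample(pos.image, ann, NECROSIS)
                    for ann in pos.manual_proxies]
        h, w = neg.image.shape
        roi = RegionAnnotation(((2, 2), (w - 2, 2), (w - 2, h - 2), (2, h - 2)),
                               "intact_training")
        examples.append(TrainingExample(neg.image, roi, INTACT))
        again = train(examples, seed=42)
        probe = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=160, height_px=160,
            necrosis_fraction=0.4), 55)
        mask = np.ones(probe.image.shape, bool)
        a = predict_map(model, probe.image, mask)
        b = predict_map(again, probe.image, mask)
        assert np.array_equal(a["labels"], b["labels"])

    def test_permuted_labels_collapse_to_chance(self):
        """With randomly shuffled labels, held-out accuracy sits at ~50%."""
        pos = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=256, height_px=256,
            necrosis_fraction=0.5, necrosis_blob_scale_px=40.0), 31)
        neg = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=256, height_px=256,
            necrosis_fraction=0.0), 32)
        rng = np.random.default_rng(6)
        h, w = neg.image.shape
        frame = RegionAnnotation(((2, 2), (w - 2, 2), (w - 2, h - 2),
                                  (2, h - 2)), "f")
        x_pos = np.vstack([
            sample_training_patches(
                TrainingExample(pos.image, ann, NECROSIS), 32, 100, rng)
            for ann in pos.manual_proxies[:1]])
        x_neg = sample_training_patches(
            TrainingExample(neg.image, frame, INTACT), 32, 100, rng)
        x = np.vstack([x_pos, x_neg])
        y = np.array([NECROSIS] * len(x_pos) + [INTACT] * len(x_neg))
        y_shuffled = rng.permutation(y)
        split = rng.random(len(y)) < 0.7
        from sklearn.ensemble import RandomForestClassifier
        forest = RandomForestClassifier(n_estimators=100, random_state=0)
        forest.fit(x[split], y_shuffled[split])
        acc = (forest.predict(x[~split]) == y_shuffled[~split]).mean()
        assert 0.4 <= acc <= 0.6

    def test_model_save_load_roundtrip(self, trained_necrosis_model, tmp_path):
        model, pos, _ = trained_necrosis_model
        path = tmp_path / "model.pkl"
        model.save(path)
        loaded = ClassifierModel.load(path)
        probe = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=128, height_px=128,
            necrosis_fraction=0.3), 66)
        mask = np.ones(probe.image.shape, bool)
        assert np.array_equal(
            predict_map(model, probe.image, mask)["labels"],
            predict_map(loaded, probe.image, mask)["labels"])


class TestPredictMap:
    def test_single_patch_roi_equals_single_prediction(
            self, trained_necrosis_model):
        model, _, _ = trained_necrosis_model
        probe = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=64, height_px=64,
            necrosis_fraction=0.0), 70)
        mask = np.zeros(probe.image.shape, bool)
        mask[8:40, 8:40] = True  # exactly one 32 px patch
        res = predict_map(model, probe.image, mask)
        assert res["necrosis_fraction"] in (0.0, 1.0)

    def test_roi_smaller_than_patch_rejected(self, trained_necrosis_model):
        model, _, _ = trained_necrosis_model
        probe = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=64, height_px=64,
            necrosis_fraction=0.0), 71)
        mask = np.zeros(probe.image.shape, bool)
        mask[10:20, 10:20] = True
        with pytest.raises(ValueError, match="patch"):
            predict_map(model, probe.image, mask)

    def test_class_fractions_partition_roi(self, trained_necrosis_model):
        model, _, _ = trained_necrosis_model
        probe = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=192, height_px=192,
            necrosis_fraction=0.4, necrosis_blob_scale_px=30.0), 72)
        mask = np.ones(probe.image.shape, bool)
        res = predict_map(model, probe.image, mask)
        labels = res["labels"]
        covered = labels >= 0
        nec_pct = 100.0 * (labels == 1).sum() / covered.sum()
        int_pct = 100.0 * (labels == 0).sum() / covered.sum()
        assert nec_pct + int_pct == pytest.approx(100.0)

    def test_controls(self, trained_necrosis_model):
        model, _, _ = trained_necrosis_model
        neg = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=192, height_px=192,
            necrosis_fraction=0.0), 80)
        pos = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=192, height_px=192,
            necrosis_fraction=0.85, necrosis_blob_scale_px=45.0), 81)
        mask = np.ones(neg.image.shape, bool)
        assert predict_map(model, neg.image, mask)["necrosis_fraction"] <= 0.05
        pos_mask = pos.truth_masks["necrosis"]
        assert predict_map(
            model, pos.image, pos_mask)["necrosis_fraction"] >= 0.95


class TestEvaluate:
    def test_leakage_guard_refuses_training_regions(
            self, trained_necrosis_model):
        model, pos, neg = trained_necrosis_model
        h, w = neg.image.shape
        frame = RegionAnnotation(((2, 2), (w - 2, 2), (w - 2, h - 2),
                                  (2, h - 2)), "eval")
        mask = np.ones(neg.image.shape, bool)
        with pytest.raises(ValueError, match="overlaps"):
            evaluate(model,
                     (neg.image, frame, mask),
                     (pos.image, pos.manual_proxies[0], mask))

    def test_fresh_scene_evaluation(self, trained_necrosis_model):
        model, _, _ = trained_necrosis_model
        neg = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=192, height_px=192,
            necrosis_fraction=0.0), 90)
        pos = make_scene(SceneParams(
            scenario="cv_necrosis", width_px=192, height_px=192,
            necrosis_fraction=0.85, necrosis_blob_scale_px=45.0), 91)
        h, w = neg.image.shape
        frame = RegionAnnotation(((0, 0), (w, 0), (w, h), (0, h)), "eval")
        res = evaluate(
            model,
            (neg.image, frame, np.ones(neg.image.shape, bool)),
            (pos.image, frame, pos.truth_masks["necrosis"]),
        )
        assert 0.0 <= res.fpr <= 100.0 and 0.0 <= res.prr <= 100.0
        assert res.fpr < 5.0
        assert res.prr > 95.0


def test_noise_degrades_gracefully(trained_necrosis_model):
    """FPR and missed-positive rate are non-decreasing in generator noise."""
    model, _, _ = trained_necrosis_model
    fpr_by_noise, miss_by_noise = [], []
    for noise in (3.0, 25.0, 60.0):
        fprs, misses = [], []
        for seed in range(3):
            neg = make_scene(SceneParams(
                scenario="cv_necrosis", width_px=160, height_px=160,
                necrosis_fraction=0.0, noise_amplitude=noise), 500 + seed)
            pos = make_scene(SceneParams(
                scenario="cv_necrosis", width_px=160, height_px=160,
                necrosis_fraction=0.85, necrosis_blob_scale_px=40.0,
                noise_amplitude=noise), 600 + seed)
            mask = np.ones(neg.image.shape, bool)
            fprs.append(predict_map(model, neg.image, mask)["necrosis_fraction"])
            misses.append(1.0 - predict_map(
                model, pos.image, pos.truth_masks["necrosis"])["necrosis_fraction"])
        fpr_by_noise.append(np.mean(fprs))
        miss_by_noise.append(np.mean(misses))
    tol = 0.005
    assert fpr_by_noise[0] <= fpr_by_noise[1] + tol <= fpr_by_noise[2] + 2 * tol
    assert miss_by_noise[0] <= miss_by_noise[1] + tol <= miss_by_noise[2] + 2 * tol
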