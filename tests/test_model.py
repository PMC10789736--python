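import numpy as np
import pytest
from scipy import ndimage

from dermxai.model import (
    LIGHT_AUGMENTATION,
    ModelConfig,
    ModelConfigError,
    TinyCNN,
    attention_loss,
    binary_cross_entropy,
    class_activation_map,
    combined_loss,
    loss_and_grads,
    predict_characteristics,
    train_model,
)
from dermxai.synthetic import GeneratorConfig, generate_dataset


def _tiny_config(**kw):
    base = dict(
        image_size=(32, 32),
        learning_rate=1e-2,
        batch_size=8,
        epochs=2,
        dropout=0.0,
        augmentation=LIGHT_AUGMENTATION,
        seed=42,
        select_best=False,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def tiny_bundle():
    return generate_dataset(GeneratorConfig(image_size=(32, 32), n_lesions=20, seed=2))


def _dice_oracle(a, h, eps=1e-6):
    """Independent per-pixel Dice computed with explicit python loops."""
    inter = sa = sh = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            inter += a[i, j] * h[i, j]
            sa += a[i, j]
            sh += h[i, j]
    return 2.0 * inter / (sa + sh + eps)


class TestAttentionLoss:
    def test_zero_when_maps_equal_targets(self):
        h = np.zeros((2, 3, 8, 8))
        h[:, :, 2:5, 2:5] = 1.0
        assert attention_loss(h, h) == pytest.approx(0.0, abs=1e-5)

    def test_one_on_disjoint_nonzero_supports(self):
        a = np.zeros((1, 2, 8, 8))
        h = np.zeros((1, 2, 8, 8))
        a[:, :, :4] = 1.0
        h[:, :, 4:] = 1.0
        assert attention_loss(a, h) == pytest.approx(1.0, abs=1e-6)

    def test_hand_worked_partial_overlap(self):
        # one sample, one class: A covers 4 px, H covers 2 of them
        a = np.zeros((1, 1, 8, 8))
        h = np.zeros((1, 1, 8, 8))
        a[0, 0, 0, :4] = 1.0
        h[0, 0, 0, :2] = 1.0
        assert attention_loss(a, h) == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_matches_per_pixel_dice_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(0, 1, (2, 2, 8, 8))
            h = (rng.uniform(0, 1, (2, 2, 8, 8)) > 0.6).astype(float)
            expected = 1.0 - np.mean(
                [
                    np.mean([_dice_oracle(a[i, c], h[i, c]) for c in range(2)])
                    for i in range(2)
                ]
            )
            assert attention_loss(a, h) == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_loss(np.zeros((1, 1, 8, 8)), np.zeros((1, 1, 4, 4)))


class TestCombinedLoss:
    def test_reduces_to_classification_when_lambda_a_zero(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(4, 3))
        labels = (rng.uniform(size=(4, 3)) > 0.5).astype(float)
        a = rng.uniform(0, 1, (4, 3, 8, 8))
        h = (rng.uniform(0, 1, (4, 3, 8, 8)) > 0.5).astype(float)
        cfg = _tiny_config(lambda_A=0.0)
        assert combined_loss(logits, labels, a, h, cfg) == pytest.approx(
            binary_cross_entropy(logits, labels)
        )

    def test_zero_for_perfect_prediction_and_matching_maps(self):
        logits = np.full((2, 2), 30.0)
        labels = np.ones((2, 2))
        h = np.zeros((2, 2, 8, 8))
        h[..., 2:4, 2:4] = 1.0
        cfg = _tiny_config()
        assert combined_loss(logits, labels, h, h, cfg) == pytest.approx(0.0, abs=1e-5)

    def test_weighted_arithmetic_from_constructed_components(self):
        # L_C = 0.2: single logit z with label 1 and softplus(-z) = 0.2
        z = -np.log(np.exp(0.2) - 1.0)
        logits, labels = np.array([[z]]), np.array([[1.0]])
        # L_A = 0.05: Dice = 38/40
        a = np.zeros((1, 1, 8, 8))
        h = np.zeros((1, 1, 8, 8))
        a.ravel()[:20] = 1.0
        h.ravel()[1:21] = 1.0
        cfg = _tiny_config(lambda_C=1.0, lambda_A=10.0)
        assert combined_loss(logits, labels, a, h, cfg) == pytest.approx(0.7, abs=1e-4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ModelConfigError):
            _tiny_config(lambda_A=-1.0).validate()


class TestClassActivationMap:
    def test_zeroed_head_gives_all_zero_map(self):
        model = TinyCNN(_tiny_config(), 4)
        model.head_W[...] = 0.0
        amap = class_activation_map(model, np.random.default_rng(0).uniform(0, 1, (32, 32, 3)), 0)
        assert np.all(amap.values == 0.0)

    def test_values_within_unit_interval_and_image_shape(self):
        model = TinyCNN(_tiny_config(), 4)
        img = np.random.default_rng(1).uniform(0, 1, (32, 32, 3))
        amap = class_activation_map(model, img, 2)
        assert amap.values.shape == (32, 32)
        assert amap.values.min() >= 0.0 and amap.values.max() <= 1.0

    def test_matches_explicit_feature_weighting_oracle(self):
        """CAM equals relu(sum_k w_ck F_k) normalised, interpolated bilinearly."""
        model = TinyCNN(_tiny_config(), 3)
        img = np.random.default_rng(2).uniform(0, 1, (32, 32, 3)).astype(np.float32)
        x = np.moveaxis(img, -1, 0)[None]
        feats = model.features(x)[0]
        for c in range(3):
            raw = np.maximum(np.tensordot(model.head_W[c], feats, axes=1), 0.0)
            norm = raw / raw.max() if raw.max() > 0 else raw
            # independent bilinear interpolation via map_coordinates
            h, w = raw.shape
            ys = (np.arange(32) + 0.5) * h / 32 - 0.5
            xs = (np.arange(32) + 0.5) * w / 32 - 0.5
            grid = np.meshgrid(ys, xs, indexing="ij")
            expected = ndimage.map_coordinates(norm, grid, order=1, mode="nearest")
            got = class_activation_map(model, img, c).values
            assert np.allclose(got, np.clip(expected, 0, 1), atol=1e-5)

    def test_gradcam_agrees_with_training_cam(self):
        model = TinyCNN(_tiny_config(), 3)
        img = np.random.default_rng(3).uniform(0, 1, (32, 32, 3)).astype(np.float32)
        x = np.moveaxis(img, -1, 0)[None]
        cams, _ = model.cams(model.features(x), (32, 32))
        for c in range(3):
            assert np.allclose(class_activation_map(model, img, c).values, cams[0, c], atol=1e-5)

    def test_class_id_out_of_range(self):
        model = TinyCNN(_tiny_config(), 3)
        with pytest.raises(IndexError):
            class_activation_map(model, np.zeros((32, 32, 3)), 3)


class TestTraining:
    def test_fixed_seed_reproduces_loss_curves(self, tiny_bundle):
        _, h1 = train_model(tiny_bundle, _tiny_config(), mode="xai")
        _, h2 = train_model(tiny_bundle, _tiny_config(), mode="xai")
        assert h1 == h2

    def test_baseline_trains_single_output_head(self, tiny_bundle):
        model, hist = train_model(tiny_bundle, _tiny_config(), mode="baseline")
        assert model.n_outputs == 1
        assert all(h["loss_a"] == 0.0 for h in hist)

    def test_wrong_n_outputs_rejected_in_xai_mode(self, tiny_bundle):
        with pytest.raises(ModelConfigError):
            train_model(tiny_bundle, _tiny_config(n_outputs=5), mode="xai")

    def test_empty_split_rejected(self, tiny_bundle):
        import copy

        broken = copy.copy(tiny_bundle)
        broken.samples = [s for s in tiny_bundle.samples if s.split != "val"]
        with pytest.raises(ValueError):
            train_model(broken, _tiny_config(), mode="xai")

    def test_unavailable_backbone_rejected(self):
        with pytest.raises(ModelConfigError):
            _tiny_config(backbone="resnet50").validate()

    def test_mask_perturbation_changes_gradients_only_in_xai_mode(self, tiny_bundle, ontology):
        from dermxai.model import _batch_arrays

        samples = tiny_bundle.split("train")[:4]
        x, y, m = _batch_arrays(samples, ontology, (32, 32), "xai")
        m2 = np.roll(m, 5, axis=2)
        grads = {}
        for mode, yy in (("xai", y), ("baseline", y[:, :1])):
            model = TinyCNN(_tiny_config(), 18 if mode == "xai" else 1)
            out = []
            for masks in (m, m2):
                loss_and_grads(model, x, yy, masks, mode, train=False)
                out.append(model.convs[0].dW.copy())
            grads[mode] = out
        assert not np.allclose(grads["xai"][0], grads["xai"][1])
        assert np.array_equal(grads["baseline"][0], grads["baseline"][1])

    def test_attention_loss_decreases_over_training(self, study):
        hist = study["xai_history"]
        first = hist[0]["loss_a"]
        late = np.mean([h["loss_a"] for h in hist[-5:]])
        assert late < first


class TestPrediction:
    def test_deterministic_scores_in_unit_interval(self, tiny_bundle):
        model, _ = train_model(tiny_bundle, _tiny_config(), mode="xai")
        img = tiny_bundle.samples[0].image
        a = predict_characteristics(model, img)
        b = predict_characteristics(model, img)
        assert np.array_equal(a.scores, b.scores)
        assert np.all((a.scores >= 0) & (a.scores <= 1))
        assert np.allclose(a.scores, 1 / (1 + np.exp(-a.logits)))
        assert len(a.attention) == 18

    def test_wrong_channel_count_rejected(self, tiny_bundle):
        model, _ = train_model(tiny_bundle, _tiny_config(), mode="xai")
        with pytest.raises(ValueError):
            predict_characteristics(model, np.zeros((32, 32, 4)))

    def test_save_load_round_trip(self, tiny_bundle, tmp_path):
        model, _ = train_model(tiny_bundle, _tiny_config(), mode="xai")
        model.save(tmp_path / "m.npz")
        clone = TinyCNN.load(tmp_path / "m.npz")
        img = tiny_bundle.samples[3].image
        assert np.allclose(
            predict_characteristics(model, img).logits,
            predict_characteristics(clone, img).logits,
        )

    def test_trained_model_scores_present_motifs_higher(self, study):
        """On generated positives vs negatives, the grey-patterns score separates."""
        bundle = study["bundle"]
        model = study["xai_model"]
        c = bundle.ontology.index_of("grey_patterns")
        pos, neg = [], []
        for s in bundle.split("test") + bundle.split("val"):
            score = predict_characteristics(model, s.image).scores[c]
            (pos if s.labels[c] else neg).append(score)
        assert len(pos) >= 10 and len(neg) >= 10
        assert np.mean(pos) > np.mean(neg)
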