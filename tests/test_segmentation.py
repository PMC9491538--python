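"""Preprocessing, ROI adjustment, model training/inference, GAW."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glottikit.errors import ConfigurationError, DimensionError, GeometryError
from glottikit.phantom import PhantomSpec, generate_recording
from glottikit.segmentation import (
    GAW,
    MaskSequence,
    adjust_roi,
    build_model,
    compute_gaw,
    load_model,
    normalize_intensity,
    predict_masks,
    save_model,
    to_luminance,
    train_model,
)
from glottikit.videoio import Recording, ROIBox


class TestLuminance:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((255, 0, 0), 76)],
    )
    def test_rec601_weights(self, rgb, expected):
        frame = np.full((2, 2, 3), rgb, dtype=np.uint8)
        assert (to_luminance(frame) == expected).all()

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(DimensionError):
            to_luminance(np.zeros((4, 4), dtype=np.uint8))


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        assert normalize_intensity(np.zeros((2, 2))).min() == -1.0
        assert normalize_intensity(np.full((2, 2), 255)).max() == 1.0
        assert normalize_intensity(np.full((1, 1), 127.5))[0, 0] == 0.0


class TestAdjustROI:
    def test_grows_to_next_multiple(self):
        out = adjust_roi(ROIBox(400, 400, 210, 150), (1024, 1024))
        assert (out.width, out.height) == (224, 160)
        assert out.x0 <= 400 and out.x1 >= 610 and out.y0 <= 400 and out.y1 >= 550

    def test_already_divisible_unchanged(self):
        roi = ROIBox(32, 64, 224, 160)
        assert adjust_roi(roi, (1024, 1024)) == roi

    def test_shifted_inward_at_edge(self):
        out = adjust_roi(ROIBox(1024 - 210, 100, 210, 150), (1024, 1024))
        assert (out.width, out.height) == (224, 160)
        assert out.x1 <= 1024 and out.x0 <= 1024 - 210

    def test_frame_too_small(self):
        with pytest.raises(GeometryError):
            adjust_roi(ROIBox(0, 0, 20, 20), (24, 24))

    @settings(max_examples=200, deadline=None)
    @given(data=st.data())
    def test_containment_and_minimality(self, data):
        H = data.draw(st.integers(64, 512))
        W = data.draw(st.integers(64, 512))
        w = data.draw(st.integers(1, min(W, 300)))
        h = data.draw(st.integers(1, min(H, 300)))
        x0 = data.draw(st.integers(0, W - w))
        y0 = data.draw(st.integers(0, H - h))
        req = ROIBox(x0, y0, w, h)
        try:
            out = adjust_roi(req, (H, W))
        except GeometryError:
            assert -(-w // 32) * 32 > W or -(-h // 32) * 32 > H
            return
        assert out.width % 32 == 0 and out.height % 32 == 0
        # contains the request
        assert out.x0 <= req.x0 and out.y0 <= req.y0
        assert out.x1 >= req.x1 and out.y1 >= req.y1
        # in-frame
        assert out.x0 >= 0 and out.y0 >= 0 and out.x1 <= W and out.y1 <= H
        # minimal among containing 32-multiple boxes
        assert out.width - 32 < w and out.height - 32 < h


class TestModel:
    def test_output_shape_and_range(self):
        model = build_model(depth=3, base_channels=4, seed=0)
        x = np.random.default_rng(0).uniform(-1, 1, (2, 64, 64)).astype(np.float32)
        y = model.net.forward(x)
        assert y.shape == (2, 64, 64)
        assert 0 < y.min() and y.max() < 1

    def test_seeded_init_reproducible(self):
        a = build_model(depth=2, base_channels=4, seed=42)
        b = build_model(depth=2, base_channels=4, seed=42)
        for k in a.net.params:
            np.testing.assert_array_equal(a.net.params[k], b.net.params[k])
        c = build_model(depth=2, base_channels=4, seed=43)
        assert any(
            (a.net.params[k] != c.net.params[k]).any() for k in a.net.params
        )

    def test_zero_learning_rate_is_noop(self):
        model = build_model(depth=2, base_channels=2, seed=1)
        before = {k: v.copy() for k, v in model.net.params.items()}
        x = np.random.default_rng(0).integers(0, 256, (4, 32, 32)).astype(np.uint8)
        y = np.zeros((4, 32, 32), dtype=bool)
        train_model(model, x, y, epochs=2, learning_rate=0.0, seed=0)
        for k, v in before.items():
            np.testing.assert_array_equal(v, model.net.params[k])

    def test_non_multiple_of_32_rejected(self):
        model = build_model(depth=2, base_channels=2, seed=1)
        x = np.zeros((2, 63, 64), dtype=np.uint8)
        with pytest.raises(GeometryError):
            train_model(model, x, np.zeros((2, 63, 64), bool), epochs=1)

    def test_empty_training_set_rejected(self):
        model = build_model(depth=2, base_channels=2, seed=1)
        with pytest.raises(ConfigurationError):
            train_model(
                model, np.zeros((0, 32, 32), np.uint8), np.zeros((0, 32, 32), bool),
                epochs=1,
            )

    def test_overfits_small_set(self):
        """A small model memorizes ten frames (loss -> ~0, IoU >= 0.95)."""
        from glottikit.evaluation import iou

        spec = PhantomSpec(H=64, W=64, T=10, axis_a=10.0, A_peak=200.0, seed=9)
        pr = generate_recording(spec)
        lum = np.stack([to_luminance(f) for f in pr.rec.frames])
        model = build_model(depth=2, base_channels=4, seed=0)
        train_model(
            model, lum, pr.gt_masks, epochs=60, learning_rate=1e-3, seed=0,
            batch_size=2,
        )
        assert model.loss_history[-1] < 0.5 * model.loss_history[0]
        ms = predict_masks(model, pr.rec)
        binm = ms.binarize()
        scores = [
            iou(pr.gt_masks[t], binm[t]) for t in range(10) if pr.gt_gaw[t] > 0
        ]
        assert np.mean(scores) >= 0.95

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_model(depth=2, base_channels=2, seed=3)
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        for k in model.net.params:
            np.testing.assert_array_equal(model.net.params[k], loaded.net.params[k])


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(depth=2, base_channels=2, seed=0)


class TestPredictMasks:
    def test_identical_frames_identical_masks(self, tiny_model):
        frames = np.tile(
            np.random.default_rng(0).integers(0, 256, (1, 64, 64, 3), np.uint8),
            (3, 1, 1, 1),
        )
        rec = Recording(frames=frames)
        ms = predict_masks(tiny_model, rec)
        np.testing.assert_array_equal(ms.masks[0], ms.masks[1])
        np.testing.assert_array_equal(ms.masks[0], ms.masks[2])

    def test_roi_masks_zero_outside(self, tiny_model):
        rng = np.random.default_rng(1)
        rec = Recording(frames=rng.integers(0, 256, (2, 96, 96, 3), np.uint8))
        roi = ROIBox(16, 32, 32, 32)
        ms = predict_masks(tiny_model, rec, roi=roi)
        outside = np.ones((96, 96), dtype=bool)
        outside[roi.as_slices()] = False
        assert ms.masks[:, outside].max() == 0

    def test_roi_restriction_is_bookkeeping_identity(self, tiny_model):
        rng = np.random.default_rng(2)
        rec = Recording(frames=rng.integers(0, 256, (2, 96, 96, 3), np.uint8))
        roi = ROIBox(0, 0, 32, 32)
        full = predict_masks(tiny_model, rec, roi=roi)
        crop = Recording(frames=rec.frames[:, :32, :32])
        direct = predict_masks(tiny_model, crop)
        np.testing.assert_array_equal(full.masks[:, :32, :32], direct.masks)

    def test_unadjusted_roi_rejected(self, tiny_model):
        rec = Recording(frames=np.zeros((1, 96, 96, 3), np.uint8))
        with pytest.raises(GeometryError):
            predict_masks(tiny_model, rec, roi=ROIBox(0, 0, 30, 32))


class TestGAW:
    def test_all_zero_masks(self):
        ms = MaskSequence(np.zeros((5, 8, 8), np.uint8))
        assert (compute_gaw(ms).areas == 0).all()

    def test_counts_pixels(self):
        m = np.zeros((1, 10, 10), np.uint8)
        m[0].flat[:37] = 255
        assert compute_gaw(MaskSequence(m)).areas[0] == 37

    def test_reproduces_phantom_ground_truth(self, small_phantom):
        ms = MaskSequence(small_phantom.gt_masks)
        np.testing.assert_array_equal(
            compute_gaw(ms).areas, small_phantom.gt_gaw
        )

    def test_subthreshold_values_not_counted(self):
        m = np.full((1, 4, 4), 100, np.uint8)  # 100/255 < 0.5
        assert compute_gaw(MaskSequence(m, threshold=0.5)).areas[0] == 0

    def test_negative_areas_rejected(self):
        with pytest.raises(ValueError):
            GAW(areas=np.array([1.0, -2.0]))


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_binarization_idempotent(seed):
    """binarize(binarize(x)) == binarize(x) at any threshold 0.5."""
    rng = np.random.default_rng(seed)
    ms = MaskSequence(rng.integers(0, 256, (2, 8, 8), dtype=np.uint8))
    once = ms.binarize()
    again = MaskSequence(once.astype(np.uint8) * 255).binarize()
    np.testing.assert_array_equal(once, again)
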