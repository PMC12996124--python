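"""Background subtraction, resize-for-inference, and the builtin segmenter."""

from __future__ import annotations

import numpy as np
import pytest

import synmap as sm
from synmap.core import ChannelImage, FieldOfView, LabelMask
from synmap.segment import rescale_for_inference, segment_builtin, upsample_mask
from conftest import disk_mask, small_config


def _field_from(arrs: dict[str, np.ndarray]) -> FieldOfView:
    return FieldOfView([ChannelImage(a, n) for n, a in arrs.items()])


class TestSubtractBackground:
    def test_scalar_median_outside_mask(self):
        img = np.full((32, 32), 100.0)
        mask = np.zeros((32, 32), dtype=np.int32)
        mask[8:16, 8:16] = 1
        img[mask == 1] = 300.0
        out, bgs = sm.subtract_background(_field_from({"a": img}), LabelMask(mask))
        assert bgs["a"] == 100.0
        assert np.all(out.channels[0].pixels[mask == 0] == 0.0)
        assert np.all(out.channels[0].pixels[mask == 1] == 200.0)

    def test_all_zero_channel_unchanged(self):
        out, bgs = sm.subtract_background(_field_from({"a": np.zeros((16, 16))}))
        assert bgs["a"] == 0.0
        assert np.all(out.channels[0].pixels == 0.0)

    def test_values_below_background_clip_to_zero(self):
        img = np.full((16, 16), 80.0)
        img[0, 0] = 50.0
        mask = np.zeros((16, 16), dtype=np.int32)
        out, _ = sm.subtract_background(_field_from({"a": img}), LabelMask(mask))
        assert out.channels[0].pixels[0, 0] == 0.0

    def test_maskfree_fallback_uses_lowest_quartile(self):
        # three quarters signal, one quarter background: the fallback must
        # still find the background level
        img = np.full((20, 20), 500.0)
        img[:5, :] = 100.0
        _, bgs = sm.subtract_background(_field_from({"a": img}))
        assert bgs["a"] == 100.0


class TestRescaleForInference:
    @pytest.mark.parametrize(
        "shape,scale,diam,out_shape,out_diam",
        [
            ((200, 200), 0.7, 100.0, (140, 140), 70.0),
            ((100, 100), 1.0, 100.0, (100, 100), 100.0),
            ((100, 100), 0.3, 100.0, (30, 30), 30.0),
        ],
    )
    def test_shape_and_diameter_arithmetic(self, shape, scale, diam, out_shape, out_diam):
        img = np.ones(shape)
        resized, adj = rescale_for_inference(img, scale, diam)
        assert resized.shape == out_shape
        assert adj == pytest.approx(out_diam)

    def test_too_small_result_is_fatal(self):
        with pytest.raises(ValueError, match="8"):
            rescale_for_inference(np.ones((20, 20)), 0.3, 10.0)

    def test_scale_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            rescale_for_inference(np.ones((50, 50)), 0.2, 10.0)

    def test_mask_upsampling_keeps_labels_integral(self, rng):
        small = rng.integers(0, 4, size=(35, 35)).astype(np.int32)
        up = upsample_mask(small, (50, 50))
        assert up.shape == (50, 50)
        assert set(np.unique(up)) <= set(np.unique(small))


class TestSegmentBuiltin:
    def test_single_disk_found_with_accurate_centroid(self, rng):
        img = rng.normal(5.0, 1.0, (200, 200))
        img[disk_mask((200, 200), (100, 100), 40)] += 300.0
        labels = segment_builtin(np.clip(img, 0, None), 80.0)
        assert labels.max() == 1
        rr, cc = np.nonzero(labels == 1)
        assert abs(rr.mean() - 100) < 2 and abs(cc.mean() - 100) < 2

    def test_blank_image_yields_no_labels(self):
        assert segment_builtin(np.zeros((64, 64)), 50.0).max() == 0

    def test_two_separated_disks_found(self):
        img = np.zeros((128, 320))
        img[disk_mask((128, 320), (64, 64), 20)] = 300.0
        img[disk_mask((128, 320), (64, 184), 20)] = 300.0  # 3 diameters apart
        labels = segment_builtin(img, 40.0)
        assert labels.max() == 2

    def test_pure_function_of_inputs(self, rng):
        img = rng.normal(10, 2, (100, 100))
        img[disk_mask((100, 100), (50, 50), 20)] += 100
        a = segment_builtin(img, 40.0)
        b = segment_builtin(img.copy(), 40.0)
        np.testing.assert_array_equal(a, b)


class TestSegmentStage:
    def test_label_set_gapfree_and_4connected(self, tiny_run):
        # re-segment one field and validate the invariants directly
        config, result, gt = tiny_run
        from synmap.io import discover_dataset, read_descriptor

        desc = discover_dataset(config.input_root)[0]
        field, _ = sm.subtract_background(read_descriptor(desc))
        mask = sm.segment(field, config)
        assert mask.n_cells > 0
        mask.validate()

    def test_all_zero_segmentation_channel_yields_empty_pipeline(self, tmp_path):
        field = _field_from({"actin": np.zeros((64, 64)), "tcr": np.ones((64, 64))})
        config = small_config(tmp_path, tmp_path / "o")
        mask = sm.segment(field, config)
        assert mask.n_cells == 0
        assert sm.compute_features(field, mask) == []

    def test_scale_invariance_of_count_and_area(self, tiny_dataset):
        root, gt = tiny_dataset
        from synmap.io import discover_dataset, read_descriptor

        desc = discover_dataset(root)[0]
        field, _ = sm.subtract_background(read_descriptor(desc))
        n_true = (gt["fov_id"] == desc.fov_id).sum()
        base = small_config(root, root)
        m07 = sm.segment(field, base.model_copy(update={"pre_inference_scale": 0.7}))
        m10 = sm.segment(field, base.model_copy(update={"pre_inference_scale": 1.0}))
        assert m07.n_cells == m10.n_cells == n_true
        a07 = np.sort(np.bincount(m07.labels.ravel())[1:])
        a10 = np.sort(np.bincount(m10.labels.ravel())[1:])
        assert np.all(np.abs(a07 / a10 - 1.0) < 0.10)

    def test_unknown_backend_is_fatal_with_hint(self, tmp_path):
        field = _field_from({"actin": np.ones((64, 64))})
        config = small_config(tmp_path, tmp_path, backend="cellpose-cyto3")
        with pytest.raises(RuntimeError, match="builtin"):
            sm.segment(field, config)

    def test_registered_adapter_is_used(self, tmp_path):
        def fake_backend(image, diameter):
            out = np.zeros(image.shape, dtype=np.int32)
            out[:4, :4] = 7  # arbitrary label id: stage must normalize to 1
            return out

        sm.register_backend("fake", fake_backend)
        try:
            field = _field_from({"actin": np.ones((64, 64))})
            mask = sm.segment(field, small_config(tmp_path, tmp_path, backend="fake"))
            assert mask.n_cells == 1 and mask.backend_used == "fake"
        finally:
            from synmap.segment import BACKENDS

            BACKENDS.pop("fake", None)
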