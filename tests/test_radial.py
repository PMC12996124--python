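"""Ring-replacement radial averaging against an independent brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

import synmap as sm
from synmap.core import LabelMask, RadialProfile
from conftest import disk_mask


def brute_radial(image: np.ndarray, binary: np.ndarray):
    """Independent oracle: explicit per-pixel loop grouping by integer radius.

    Center is the rounded mask centroid; radii are rounded Euclidean
    distances; means run over all bounding-box pixels.
    """
    rows, cols = np.nonzero(binary)
    cr = int(np.rint(rows.mean()))
    cc = int(np.rint(cols.mean()))
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    groups: dict[int, list[float]] = {}
    for i in range(r0, r1):
        for j in range(c0, c1):
            r = int(round(np.hypot(i - cr, j - cc)))
            groups.setdefault(r, []).append(image[i, j])
    means = {r: sum(v) / len(v) for r, v in groups.items()}
    out = np.empty((r1 - r0, c1 - c0))
    for i in range(r0, r1):
        for j in range(c0, c1):
            out[i - r0, j - c0] = means[int(round(np.hypot(i - cr, j - cc)))]
    profile = np.array([means[r] for r in range(max(means) + 1)])
    return out, profile, (cr, cc)


def _random_cell(rng, shape=(32, 32)):
    image = rng.uniform(0, 100, shape)
    center = (int(rng.integers(10, shape[0] - 10)), int(rng.integers(10, shape[1] - 10)))
    radius = float(rng.uniform(5, 9))
    mask = disk_mask(shape, center, radius).astype(np.int32)
    return image, mask


class TestRadialAverage:
    def test_five_by_five_center_pixel(self):
        image = np.zeros((9, 9))
        image[4, 4] = 10.0
        mask = np.zeros((9, 9), dtype=np.int32)
        mask[2:7, 2:7] = 1
        _, prof = sm.radial_average(image, LabelMask(mask), 1)
        assert prof.values[0] == pytest.approx(10.0)
        assert prof.counts[1] == 8
        assert prof.values[1] == 0.0 and prof.values[2] == 0.0

    def test_uniform_image_stays_uniform(self, rng):
        image = np.full((32, 32), 7.25)
        _, mask = _random_cell(rng)
        img, prof = sm.radial_average(image, LabelMask(mask), 1)
        assert np.allclose(img.pixels, 7.25)
        assert np.allclose(prof.values[np.isfinite(prof.values)], 7.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        image, mask = _random_cell(rng)
        img, prof = sm.radial_average(image, LabelMask(mask), 1)
        oracle_img, oracle_prof, center = brute_radial(image, mask == 1)
        assert img.center == center
        np.testing.assert_allclose(img.pixels, oracle_img, atol=1e-9, rtol=0)
        np.testing.assert_allclose(prof.values, oracle_prof, atol=1e-9, rtol=0)

    def test_ring_mean_conservation(self, rng):
        image, mask = _random_cell(rng)
        img, prof = sm.radial_average(image, LabelMask(mask), 1)
        rows, cols = np.nonzero(mask)
        r0, c0 = rows.min(), cols.min()
        sub = image[r0: rows.max() + 1, c0: cols.max() + 1]
        gr, gc = np.mgrid[r0: rows.max() + 1, c0: cols.max() + 1]
        radii = np.rint(np.hypot(gr - img.center[0], gc - img.center[1])).astype(int)
        for r in np.unique(radii):
            assert img.pixels[radii == r].mean() == pytest.approx(sub[radii == r].mean(), abs=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rotation_by_90_degrees_leaves_profile_unchanged(self, rng, k):
        # a centered mask makes 90-degree rotation a permutation within rings
        image = rng.uniform(0, 50, (33, 33))
        mask = disk_mask((33, 33), (16, 16), 10).astype(np.int32)
        _, base = sm.radial_average(image, LabelMask(mask), 1)
        _, rot = sm.radial_average(np.rot90(image, k).copy(), LabelMask(mask), 1)
        np.testing.assert_allclose(rot.values, base.values, atol=1e-9, rtol=0)

    def test_mask_only_mode_ignores_outside_pixels(self):
        image = np.zeros((21, 21))
        mask = disk_mask((21, 21), (10, 10), 6).astype(np.int32)
        image[mask == 0] = 1000.0  # bounding-box corners
        image[mask == 1] = 5.0
        _, prof = sm.radial_average(image, LabelMask(mask), 1, mask_only=True)
        assert np.nanmax(prof.values) == pytest.approx(5.0)


class TestScaleProfile:
    def test_identity_at_native_length(self):
        p = RadialProfile(values=np.array([3.0, 1.0, 4.0, 1.5]), counts=np.ones(4))
        out = sm.scale_profile(p, 4)
        np.testing.assert_allclose(out.values, p.values)
        assert out.scaled

    def test_constant_stays_constant(self):
        p = RadialProfile(values=np.full(7, 2.5), counts=np.ones(7))
        np.testing.assert_allclose(sm.scale_profile(p, 30).values, 2.5)

    def test_linear_ramp_stays_linear(self):
        p = RadialProfile(values=np.linspace(0, 10, 11), counts=np.ones(11))
        out = sm.scale_profile(p, 21)
        np.testing.assert_allclose(out.values, np.linspace(0, 10, 21), atol=1e-12)
        assert out.values[0] == 0.0 and out.values[-1] == 10.0

    def test_monotone_profiles_stay_monotone(self, rng):
        vals = np.sort(rng.uniform(0, 10, 15))
        p = RadialProfile(values=vals, counts=np.ones(15))
        for target in (5, 15, 40):
            out = sm.scale_profile(p, target).values
            assert np.all(np.diff(out) >= -1e-12)
            assert out[0] == pytest.approx(vals[0]) and out[-1] == pytest.approx(vals[-1])

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            sm.scale_profile(RadialProfile(values=np.array([1.0]), counts=np.array([1.0])), 10)


class TestAggregateProfiles:
    def test_identical_profiles_have_zero_sem(self):
        p = RadialProfile(values=np.array([1.0, 2.0, 3.0]), counts=np.ones(3))
        ens = sm.aggregate_profiles([p, p])
        np.testing.assert_allclose(ens.mean, p.values)
        np.testing.assert_allclose(ens.sem, 0.0)
        assert ens.n_cells == 2

    def test_sem_is_sample_sd_over_sqrt_n(self):
        a = RadialProfile(values=np.array([0.0, 2.0]), counts=np.ones(2))
        b = RadialProfile(values=np.array([2.0, 0.0]), counts=np.ones(2))
        ens = sm.aggregate_profiles([a, b])
        np.testing.assert_allclose(ens.mean, [1.0, 1.0])
        np.testing.assert_allclose(ens.sem, [1.0, 1.0])  # SD(0,2)=sqrt(2), /sqrt(2)

    def test_normalized_mean_peaks_at_one(self, rng):
        profiles = [
            RadialProfile(values=rng.uniform(1, 5, 10), counts=np.ones(10)) for _ in range(5)
        ]
        ens = sm.aggregate_profiles(profiles, normalize=True)
        assert np.nanmax(ens.mean) == pytest.approx(1.0)

    def test_empty_list_is_not_fatal(self):
        ens = sm.aggregate_profiles([])
        assert ens.n_cells == 0 and ens.mean.size == 0


class TestGroupOutputs:
    def _images(self, n, shape=(11, 11), value=None, rng=None):
        from synmap.core import RadialAverageImage

        out = []
        for i in range(n):
            px = np.full(shape, float(i + 1)) if value is None else np.full(shape, value)
            if rng is not None:
                px = rng.uniform(0, 1, shape)
            out.append(RadialAverageImage(pixels=px, center=(5, 5), bbox=(0, 0, 11, 11)))
        return out

    def test_nine_cells_make_three_by_three_montage(self, tmp_path):
        import tifffile

        paths = sm.build_group_outputs(self._images(9), "tcr", tmp_path)
        montage = tifffile.imread(paths["montage"])
        stack = tifffile.imread(paths["stack"])
        assert montage.shape == (33, 33)
        assert stack.shape == (9, 11, 11)
        assert paths["montage"].name == "tcr_radMontage.tif"
        assert paths["stack"].name == "tcr_radStack.tif"
        assert paths["totav"].name == "tcr_radTotAv.tif"

    def test_single_cell_stack_montage_average_agree(self, tmp_path, rng):
        import tifffile

        paths = sm.build_group_outputs(self._images(1, rng=rng), "x", tmp_path)
        m = tifffile.imread(paths["montage"])
        s = np.squeeze(tifffile.imread(paths["stack"]))
        t = tifffile.imread(paths["totav"])
        np.testing.assert_allclose(m, s)
        np.testing.assert_allclose(m, t)

    def test_identical_planes_average_to_themselves(self, tmp_path):
        import tifffile

        paths = sm.build_group_outputs(self._images(4, value=3.5), "x", tmp_path)
        t = tifffile.imread(paths["totav"])
        np.testing.assert_allclose(t, 3.5)

    def test_zero_images_skipped_with_warning(self, tmp_path):
        assert sm.build_group_outputs([], "x", tmp_path) == {}
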