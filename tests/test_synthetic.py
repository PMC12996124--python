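"""The synthetic-synapse generator: determinism, geometry, correlation, bookkeeping."""

from __future__ import annotations

import math

import numpy as np
import pytest

import synmap as sm
from synmap.synthetic import (
    ChannelModel,
    ConditionSpec,
    SynapseSpec,
    correlated_pair,
    generate_dataset,
    render_synapse,
    truth_mask,
)


class TestRenderSynapse:
    def _spec(self, channels, radius=30.0, noise=0.0):
        for ch in channels:
            ch.noise_sd = noise
        return SynapseSpec(radius_px=radius, channels=channels)

    def test_fixed_seed_reproduces_tiles_exactly(self):
        spec = self._spec([ChannelModel("a", (1, 1, 1), fold=2.0)], noise=4.0)
        t1, m1, _ = render_synapse(spec, 42)
        t2, m2, _ = render_synapse(spec, 42)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(m1, m2)

    def test_central_channel_profile_peaks_at_center_and_decays(self):
        spec = self._spec([ChannelModel("tcr", (1, 0, 0), fold=3.0)])
        tile, mask, truth = render_synapse(spec, 0)
        info = truth["channels"]["tcr"]
        assert info["peak_radius_px"] == 0
        # signal above background vanishes beyond f_c*R plus the smoothing skirt
        from synmap.radial import radial_average
        from synmap.core import LabelMask

        _, prof = radial_average(tile[0], LabelMask(mask.astype(np.int32)), 1)
        # the Gaussian edge skirt (sigma 2) is negligible beyond ~5 sigma
        cutoff = int(math.ceil(spec.f_c * spec.radius_px + 10))
        tail = prof.values[cutoff:]
        assert np.all(np.abs(tail[np.isfinite(tail)] - spec.background) < 0.01)

    def test_corolla_channel_peaks_in_distal_ring(self):
        spec = self._spec([ChannelModel("cd2", (0, 0, 1), fold=3.0)])
        _, _, truth = render_synapse(spec, 0)
        peak = truth["channels"]["cd2"]["peak_radius_px"]
        assert spec.f_p * spec.radius_px <= peak <= spec.radius_px

    def test_mask_mean_enrichment_is_calibrated_exactly(self):
        spec = self._spec([ChannelModel("a", (1, 1, 1), fold=2.5)])
        tile, mask, truth = render_synapse(spec, 0)
        assert tile[0][mask].mean() == pytest.approx(2.5 * spec.background, rel=1e-9)
        assert truth["channels"]["a"]["expected_fold"] == 2.5

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SynapseSpec(radius_px=4.0, channels=[ChannelModel("a")])
        with pytest.raises(ValueError):
            SynapseSpec(radius_px=20.0, channels=[ChannelModel("a")], f_c=0.9, f_p=0.3)
        with pytest.raises(ValueError):
            ChannelModel("a", noise_sd=-1.0)


class TestCorrelatedPair:
    def test_rho_one_gives_identical_fields(self, rng):
        a, b = correlated_pair((64, 64), 1.0, rng)
        np.testing.assert_allclose(a, b)

    def test_rho_zero_within_clt_bound(self, rng):
        a, b = correlated_pair((128, 128), 0.0, rng)
        n = a.size
        assert abs(np.corrcoef(a.ravel(), b.ravel())[0, 1]) < 3 / math.sqrt(n)

    def test_rho_recovery_on_large_field(self, rng):
        a, b = correlated_pair((256, 256), 0.7, rng)
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert 0.68 <= r <= 0.72

    def test_invalid_rho_rejected(self, rng):
        with pytest.raises(ValueError):
            correlated_pair((16, 16), 1.5, rng)


class TestGenerateDataset:
    def test_bookkeeping_counts(self, tmp_path):
        conds = [
            ConditionSpec(
                lab, n_fields=3, cells_per_field=5,
                channels=[ChannelModel("a", (1, 1, 1), fold=2.0)],
                field_shape=(256, 256), radius_range=(10.0, 14.0),
            )
            for lab in ("x", "y")
        ]
        gt = generate_dataset(conds, tmp_path, seed=3)
        tiffs = sorted(tmp_path.rglob("*.tif"))
        assert len(tiffs) == 6
        assert len(gt) == 30
        assert set(gt["condition"]) == {"x", "y"}
        assert (tmp_path / "ground_truth.csv").exists()
        assert (tmp_path / "generation.json").exists()

    def test_deterministic_under_fixed_seed(self, tmp_path):
        conds = [
            ConditionSpec(
                "x", n_fields=1, cells_per_field=2,
                channels=[ChannelModel("a", (1, 1, 1), fold=2.0, noise_sd=5.0)],
                field_shape=(160, 160), radius_range=(10.0, 14.0),
            )
        ]
        generate_dataset(conds, tmp_path / "r1", seed=9)
        generate_dataset(conds, tmp_path / "r2", seed=9)
        f1 = sorted((tmp_path / "r1").rglob("*.tif"))[0]
        f2 = sorted((tmp_path / "r2").rglob("*.tif"))[0]
        assert f1.read_bytes() == f2.read_bytes()

    def test_written_fields_roundtrip_losslessly(self, tiny_dataset):
        root, gt = tiny_dataset
        path = sorted(root.rglob("*.tif"))[0]
        field = sm.read_field(path)
        sub = path.parent / "rt.tif"
        try:
            sm.write_field(field, sub)
            again = sm.read_field(sub)
            np.testing.assert_array_equal(field.as_stack(), again.as_stack())
        finally:
            sub.unlink(missing_ok=True)

    def test_noiseless_dataset_mfi_matches_ground_truth(self, tmp_path):
        channels = [
            ChannelModel("seg", (1, 1, 1), fold=3.0, noise_sd=0.0),
            ChannelModel("ctr", (1, 0, 0), fold=2.0, noise_sd=0.0),
        ]
        conds = [ConditionSpec("x", 1, 3, channels, field_shape=(256, 256), radius_range=(12.0, 18.0))]
        gt = generate_dataset(conds, tmp_path, seed=5)
        field = sm.read_field(sorted(tmp_path.rglob("*.tif"))[0])
        mask = truth_mask(
            field.shape,
            list(zip(gt["center_row"], gt["center_col"])),
            list(gt["radius_px"]),
        )
        recs = sm.compute_features(field, mask)
        for rec, (_, row) in zip(recs, gt.iterrows()):
            assert rec.mfi["seg"] == pytest.approx(row["mfi_seg"], rel=0.01)
            assert rec.mfi["ctr"] == pytest.approx(row["mfi_ctr"], rel=0.01)

    def test_ground_truth_columns_present(self, tiny_dataset):
        _, gt = tiny_dataset
        for col in ("condition", "fov_id", "replicate", "cell", "center_row", "center_col",
                    "radius_px", "area_px", "equiv_diameter_px", "mfi_actin", "fold_cd2",
                    "peak_radius_cd2", "profile_len_cd2", "rho"):
            assert col in gt.columns
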