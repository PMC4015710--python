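"""Segmentation and densitometry: thresholds, components, MLD, LAA%."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import airtrap as at
from airtrap.densitometry import EmptyMaskError, LungNotFoundError


def _box_volume(box_hu=-1000.0, body_hu=0.0, shape=(40, 40, 20)):
    """A -1000 HU box embedded in soft tissue, away from all borders."""
    vals = np.full(shape, body_hu, np.float32)
    box = np.zeros(shape, bool)
    box[10:30, 10:30, 5:15] = True
    vals[box] = box_hu
    return at.CTVolume(vals, (1, 1, 1)), box


class TestSegmentLung:
    def test_clean_box_recovered_exactly(self):
        vol, box = _box_volume()
        with pytest.warns(UserWarning, match="one lung"):
            mask = at.segment_lung(vol)
        assert np.array_equal(mask.mask, box)

    def test_all_soft_tissue_raises(self):
        vol = at.CTVolume(np.zeros((40, 40, 20), np.float32), (1, 1, 1))
        with pytest.raises(LungNotFoundError):
            at.segment_lung(vol)

    def test_border_touching_air_excluded(self):
        # air continuous with the lateral border is not lung
        vals = np.zeros((40, 40, 20), np.float32)
        vals[:15, :, :] = -1000.0  # touches x=0 border
        vals[20:30, 20:30, 5:15] = -800.0
        with pytest.warns(UserWarning):
            mask = at.segment_lung(at.CTVolume(vals, (1, 1, 1)))
        assert not mask.mask[:15, :, :].any()
        assert mask.mask[20:30, 20:30, 5:15].all()

    def test_phantom_jaccard(self, segmented_phantom):
        _, _, _, truth, mask = segmented_phantom
        inter = (mask.mask & truth.lung_mask).sum()
        union = (mask.mask | truth.lung_mask).sum()
        assert inter / union >= 0.95
        assert mask.n_components == 2

    def test_phantom_airway_excluded(self, segmented_phantom):
        _, _, _, truth, mask = segmented_phantom
        overlap = (mask.mask & truth.airway_mask).sum()
        assert 1 - overlap / truth.airway_mask.sum() >= 0.9

    def test_airway_only_phantom_no_lung(self):
        # a thorax with an air column but no lung parenchyma
        vals = np.zeros((40, 40, 20), np.float32)
        vals[18:22, 18:22, 0:10] = -1000.0  # touches top slice
        with pytest.raises(LungNotFoundError):
            at.segment_lung(at.CTVolume(vals, (1, 1, 1)))


class TestRemoveAirway:
    def test_no_low_voxel_at_top_unchanged(self):
        vol, box = _box_volume(box_hu=-800.0)
        with pytest.warns(UserWarning):
            mask = at.segment_lung(vol)
        out = at.remove_airway(mask, vol)
        assert np.array_equal(out.mask, mask.mask)

    def test_top_touching_column_removed(self):
        vals = np.zeros((40, 40, 20), np.float32)
        vals[10:30, 10:30, 5:15] = -800.0  # lung-like box
        vals[18:22, 5:8, 0:12] = -1000.0  # air column from the apex slice
        vol = at.CTVolume(vals, (1, 1, 1))
        cand = (vals >= -1024) & (vals <= -500)
        from airtrap.densitometry import _finalize_mask

        mask = _finalize_mask(cand)
        out = at.remove_airway(mask, vol)
        assert not out.mask[18:22, 5:8, :].any()
        assert out.mask[10:30, 10:30, 5:15].all()


class TestDensitometry:
    def test_mld_constant_and_symmetric(self):
        vals = np.full((10, 10, 4), -850.0, np.float32)
        vol = at.CTVolume(vals, (1, 1, 1))
        mask = np.ones(vals.shape, bool)
        assert at.mean_lung_density(vol, mask) == -850.0
        vals2 = vals.copy()
        vals2[:5] = -900.0
        vals2[5:] = -800.0
        assert at.mean_lung_density(at.CTVolume(vals2, (1, 1, 1)), mask) == -850.0

    def test_mld_clt_bound(self, rng):
        n = 10**6
        vals = rng.normal(-800.0, 50.0, n).reshape(100, 100, 100).astype(np.float64)
        vol = at.CTVolume(vals, (1, 1, 1))
        assert abs(at.mean_lung_density(vol, np.ones(vals.shape, bool)) + 800.0) < 0.15

    def test_laa_trivial_values(self):
        vals = np.full((10, 10, 2), -900.0, np.float32)
        mask = np.ones(vals.shape, bool)
        assert at.laa_percent(at.CTVolume(vals, (1, 1, 1)), mask, (-1024, -850)) == 100.0
        vals[:5] = -700.0
        assert at.laa_percent(at.CTVolume(vals, (1, 1, 1)), mask, (-1024, -850)) == 50.0

    def test_laa_gaussian_tail_oracle(self, rng):
        # N(-800, 50) below -850: one-sided standard normal tail at z=-1
        n = 500_000
        vals = rng.normal(-800.0, 50.0, n).reshape(100, 100, 50)
        vol = at.CTVolume(vals, (1, 1, 1))
        pct = at.laa_percent(vol, np.ones(vals.shape, bool), (-1024, -850))
        p = norm.cdf(-1.0)
        se = 100 * np.sqrt(p * (1 - p) / n)
        assert abs(pct - 100 * p) <= 3 * se

    def test_empty_mask_errors(self):
        vol = at.CTVolume(np.zeros((4, 4, 4), np.float32), (1, 1, 1))
        empty = np.zeros((4, 4, 4), bool)
        with pytest.raises(EmptyMaskError):
            at.mean_lung_density(vol, empty)
        with pytest.raises(EmptyMaskError):
            at.laa_percent(vol, empty, (-1024, -850))


class TestLevels:
    def test_left_right_pooled(self):
        vals = np.zeros((40, 40, 8), np.float32)
        vals[5:15, 15:25, :] = -900.0  # left lung, same area
        vals[25:35, 15:25, :] = -700.0  # right lung
        vol = at.CTVolume(vals, (1, 1, 1))
        mask = at.segment_lung(vol)
        assert mask.n_components == 2
        s = at.summarize_level(vol, mask, level_z=4)
        assert s.mld == pytest.approx(-800.0)

    def test_homogeneous_levels_mean_equals_each(self):
        vals = np.full((40, 40, 20), 0.0, np.float32)
        vals[10:30, 10:30, :] = -880.0
        vol = at.CTVolume(vals, (1, 1, 1))
        with pytest.warns(UserWarning):
            mask = at.segment_lung(vol)
        per, mean = at.summarize_volume(vol, mask, at.LevelSelection((4, 8, 12, 16)))
        assert mean.mld == pytest.approx(per[0].mld)
        assert all(s.mld == per[0].mld for s in per)
        assert mean.level_id == "mean"

    def test_mean_of_levels_unweighted(self):
        vals = np.zeros((40, 40, 20), np.float32)
        box = np.s_[10:30, 10:30]
        for z, hu in zip((4, 8, 12, 16), (-700.0, -750.0, -800.0, -850.0)):
            vals[box + (slice(z, z + 1),)] = hu
        vals[box + (slice(2, 18),)][vals[box + (slice(2, 18),)] == 0] = -600.0
        vol = at.CTVolume(vals, (1, 1, 1))
        with pytest.warns(UserWarning):
            mask = at.segment_lung(vol)
        per, mean = at.summarize_volume(vol, mask, at.LevelSelection((4, 8, 12, 16)))
        assert [s.mld for s in per] == [-700.0, -750.0, -800.0, -850.0]
        assert mean.mld == pytest.approx(-775.0)

    def test_gradient_phantom_levels_monotone(self):
        spec = at.PhantomSpec(grid_shape=(64, 64, 48), spacing=(2.5, 2.5, 2.5),
                              trapped_fraction=0.3, trapped_gradient=2.5, seed=21)
        _, exp, _ = at.generate_phantom(spec)
        mask = at.segment_lung(exp)
        per, _ = at.summarize_volume(exp, mask, spec.default_levels())
        laa = [s.laa_full_pct for s in per]
        assert laa == sorted(laa)

    def test_level_out_of_bounds(self):
        vol, _ = _box_volume()
        with pytest.warns(UserWarning):
            mask = at.segment_lung(vol)
        with pytest.raises(ValueError):
            at.summarize_level(vol, mask, level_z=99)

    def test_levels_must_be_ordered(self):
        with pytest.raises(ValueError):
            at.LevelSelection((5, 4, 10, 12))


class TestInvariantProperties:
    @given(shift=st.floats(-100, 100), seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_translation_property(self, shift, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(-800, 60, (8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.6
        mask[0, 0, 0] = True
        vol = at.CTVolume(vals, (1, 1, 1))
        vol2 = at.CTVolume(vals + shift, (1, 1, 1))
        assert at.mean_lung_density(vol2, mask) == pytest.approx(
            at.mean_lung_density(vol, mask) + shift, abs=1e-6
        )
        lo, hi = -1024.0, -850.0
        assert at.laa_percent(vol2, mask, (lo + shift, hi + shift)) == pytest.approx(
            at.laa_percent(vol, mask, (lo, hi))
        )

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_laa_nesting_and_range_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(-820, 80, (8, 8, 8))
        vol = at.CTVolume(vals, (1, 1, 1))
        mask = np.ones((8, 8, 8), bool)
        narrow = at.laa_percent(vol, mask, (-910, -850))
        full = at.laa_percent(vol, mask, (-1024, -850))
        wider = at.laa_percent(vol, mask, (-1024, -800))
        assert narrow <= full <= wider

    def test_noiseless_phantom_laa_recovers_fraction(self):
        # well-separated lung distributions: LAA_full% == trapped fraction
        spec = at.PhantomSpec(grid_shape=(64, 64, 48), spacing=(2.5, 2.5, 2.5),
                              lung_exp_sd=5.0, trapped_exp_sd=5.0, trapped_fraction=0.3,
                              seed=8)
        _, exp, truth = at.generate_phantom(spec)
        mask = at.segment_lung(exp)
        laa = at.laa_percent(exp, mask, (-1024.0, -850.0))
        assert abs(laa - 100 * spec.trapped_fraction) <= 0.5
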