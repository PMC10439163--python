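"""Occlusion/accumulation quantification and device-map inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowquant import accumulation as acc
from flowquant import fixtures as fx
from flowquant.io_media import FrameStack, InputError


class TestBinarizeChannels:
    def test_all_below_threshold_empty(self):
        stack = FrameStack(np.full((2, 8, 8, 3), 40.0))
        masks = acc.binarize_channels(stack, {0: 100.0})
        assert not masks[0].any()

    def test_threshold_zero_selects_nonzero_pixels(self):
        frames = np.zeros((1, 8, 8, 3))
        frames[0, 2:4, 2:4, 1] = 5.0
        masks = acc.binarize_channels(FrameStack(frames), {1: 0.0})
        assert masks[1].sum() == 4

    def test_known_coverage_mask_exact(self):
        stencil, _ = fx.make_comb_stencil(4)
        stack, truth = fx.render_occlusion_series(stencil, [0.25], seed=0)
        masks = acc.binarize_channels(stack, {0: 100.0})
        assert masks[0][0].sum() == truth.objects.signal_area_px[0]

    def test_absent_plane_rejected(self):
        with pytest.raises(InputError):
            acc.binarize_channels(FrameStack(np.zeros((1, 8, 8, 3))), {4: 10.0})


class TestBuildDeviceMap:
    def test_single_mask_identity(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:5, 3:8] = True
        dm = acc.build_device_map({0: m[None]}, map_threshold=1)
        np.testing.assert_array_equal(dm.mask, m)

    def test_union_semantics_any_timepoint(self):
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[0, 0] = True
        b[5, 5] = True
        dm = acc.build_device_map({0: np.stack([a, b])}, map_threshold=1)
        assert dm.mask[0, 0] and dm.mask[5, 5]

    def test_partial_coverage_union_recovers_full_y_stencil(self):
        stencil = fx.make_y_stencil()
        stack, _ = fx.render_occlusion_series(stencil, [0.4] * 10, seed=2,
                                              fill_mode="rotating")
        masks = acc.binarize_channels(stack, {0: 100.0})
        dm = acc.build_device_map(masks)
        np.testing.assert_array_equal(dm.mask, stencil)

    def test_map_never_shrinks_with_more_timepoints(self):
        stencil = fx.make_y_stencil()
        stack, _ = fx.render_occlusion_series(stencil, [0.3] * 8, seed=3,
                                              fill_mode="random")
        masks = acc.binarize_channels(stack, {0: 100.0})[0]
        prev = np.zeros_like(stencil)
        for t in range(1, 9):
            dm = acc.build_device_map({0: masks[:t]})
            assert (dm.mask | prev).sum() == dm.mask.sum()  # superset of prev
            prev = dm.mask

    def test_empty_union_rejected(self):
        with pytest.raises(InputError, match="no device signal"):
            acc.build_device_map({0: np.zeros((2, 6, 6), dtype=bool)})


class TestDetectMicrochannels:
    def test_solid_rectangle_constant_walls(self):
        m = np.zeros((20, 40), dtype=bool)
        m[5:12, 4:36] = True
        dm = acc.detect_microchannels(acc.DeviceMap(mask=m))
        assert len(dm.channels) == 1
        ch = dm.channels[0]
        assert (ch.y_top == 5).all() and (ch.y_bottom == 11).all()
        assert ch.x0 == 4 and ch.x1 == 35

    def test_comb_stencil_finds_32_channels(self):
        stencil, boxes = fx.make_comb_stencil(32)
        dm = acc.detect_microchannels(acc.DeviceMap(mask=stencil))
        assert len(dm.channels) == 32
        for ch, box in zip(dm.channels, boxes):  # top-to-bottom indexing
            assert (ch.y_top == box["y0"]).all()
            assert (ch.y_bottom == box["y1"]).all()

    def test_ragged_walls_smoothed_within_one_px(self):
        rect = np.zeros((40, 120), dtype=bool)
        rect[10:26, 10:110] = True
        ragged = rect.copy()
        rng = np.random.default_rng(0)
        for x in range(10, 110):  # ±1-px raggedness
            if rng.random() < 0.5:
                ragged[9, x] = True
            if rng.random() < 0.5:
                ragged[26, x] = True
        dm = acc.detect_microchannels(acc.DeviceMap(mask=ragged))
        ch = dm.channels[0]
        assert np.abs(ch.y_top - 10).max() <= 1
        assert np.abs(ch.y_bottom - 25).max() <= 1

    def test_single_column_gap_interpolated(self):
        m = np.zeros((20, 30), dtype=bool)
        m[5:10, 2:28] = True
        m[:, 15] = False  # one-column dropout
        dm = acc.detect_microchannels(acc.DeviceMap(mask=m))
        ch = dm.channels[0]
        i = 15 - ch.x0
        assert ch.y_top[i] == 5 and ch.y_bottom[i] == 9


class TestOcclusionAccumulation:
    def test_quarter_coverage_is_25pct(self):
        region = np.ones((10, 10), dtype=bool)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5, :5] = True
        series = acc.compute_occlusion_accumulation({0: mask[None]}, region, [0.0])
        assert series.table.occlusion_pct.iloc[0] == 25.0

    def test_constant_signal_zero_accumulation_and_rate(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        masks = {0: np.stack([mask] * 4)}
        series = acc.compute_occlusion_accumulation(masks, np.ones((8, 8), bool),
                                                    [0.0, 1.0, 2.0, 3.0])
        assert (series.table.accumulation_px2.dropna() == 0).all()
        assert series.rates_um2_per_min[0] == pytest.approx(0.0, abs=1e-9)

    def test_linear_growth_rate_in_physical_units(self):
        # 100 px²/timepoint at 1 min spacing, 0.5 µm/px -> 25 µm²/min
        region = np.ones((20, 50), dtype=bool)
        masks = []
        for t in range(5):
            m = np.zeros((20, 50), dtype=bool)
            m.flat[: 100 * t] = True
            masks.append(m)
        series = acc.compute_occlusion_accumulation(
            {0: np.stack(masks)}, region, [0, 1, 2, 3, 4], um_per_px=0.5
        )
        assert series.rates_um2_per_min[0] == pytest.approx(25.0)
        assert (series.table.accumulation_px2.dropna() == 100).all()

    def test_planted_schedule_recovered_exactly(self):
        stencil, _ = fx.make_comb_stencil(8)
        stack, _ = fx.render_occlusion_series(stencil, [0.0, 0.25, 0.5], seed=1)
        masks = acc.binarize_channels(stack, {0: 100.0})
        series = acc.compute_occlusion_accumulation(masks, stencil, [0, 1, 2])
        assert series.table.occlusion_pct.tolist() == [0.0, 25.0, 50.0]

    def test_non_increasing_timestamps_rejected(self):
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(InputError):
            acc.compute_occlusion_accumulation({0: np.stack([mask] * 2)}, mask,
                                               [1.0, 1.0])

    def test_zero_area_region_rejected(self):
        with pytest.raises(InputError):
            acc.compute_occlusion_accumulation(
                {0: np.ones((1, 4, 4), bool)}, np.zeros((4, 4), bool), [0.0]
            )

    def test_threshold_perturbation_keeps_occlusion_ordered(self):
        # monotone-intensity growth: curves for thresholds T and T+δ never cross
        stencil, _ = fx.make_comb_stencil(4)
        stack, _ = fx.render_occlusion_series(stencil, [0.1, 0.3, 0.6, 0.9], seed=5,
                                              amplitude=220.0, noise_sd=15.0)
        lo = acc.binarize_channels(stack, {0: 100.0})
        hi = acc.binarize_channels(stack, {0: 130.0})
        s_lo = acc.compute_occlusion_accumulation(lo, stencil, [0, 1, 2, 3])
        s_hi = acc.compute_occlusion_accumulation(hi, stencil, [0, 1, 2, 3])
        diff = s_lo.table.occlusion_pct.values - s_hi.table.occlusion_pct.values
        assert (diff >= 0).all()


class TestSpatialOcclusion:
    def _channel(self):
        m = np.zeros((20, 60), dtype=bool)
        m[5:15, 5:55] = True
        return acc.detect_microchannels(acc.DeviceMap(mask=m)).channels[0]

    def test_empty_and_full_columns(self):
        ch = self._channel()
        mask = np.zeros((20, 60), dtype=bool)
        mask[5:15, 30:] = True  # distal half fully occluded
        sp = acc.spatial_occlusion(mask, ch)
        assert sp.occlusion_pct.iloc[0] == 0.0
        assert sp.occlusion_pct.iloc[-1] == 100.0
        # step lands at the planted boundary ±1 px
        step_x = sp.x[sp.occlusion_pct.diff() > 50].iloc[0]
        assert abs(step_x - 30) <= 1

    def test_span_weighted_mean_equals_whole_channel_occlusion(self):
        ch = self._channel()
        rng = np.random.default_rng(7)
        mask = rng.random((20, 60)) < 0.4
        sp = acc.spatial_occlusion(mask, ch)
        w = sp.wall_span_px.values
        weighted = float((sp.occlusion_pct.values * w).sum() / w.sum())
        series = acc.compute_occlusion_accumulation({0: mask[None]}, ch, [0.0])
        assert weighted == pytest.approx(series.table.occlusion_pct.iloc[0], abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
def test_occlusion_bounded_and_saturates_only_on_superset(seed, density):
    """0 <= occlusion <= 100 for arbitrary masks; 100 iff mask covers region."""
    rng = np.random.default_rng(seed)
    region = rng.random((12, 12)) < 0.7
    if not region.any():
        region[0, 0] = True
    mask = rng.random((12, 12)) < density
    series = acc.compute_occlusion_accumulation({0: mask[None]}, region, [0.0])
    pct = series.table.occlusion_pct.iloc[0]
    assert 0.0 <= pct <= 100.0
    assert (pct == 100.0) == bool((mask | ~region).all())
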