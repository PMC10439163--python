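"""Adhered-cell morphology, fluorescence functionality, protrusions, dwell time."""

import math

import numpy as np
import pytest

from flowquant import adhesion as adh
from flowquant import fixtures as fx
from flowquant.io_media import InputError

STAR = dict(r_in=7.0, r_out=16.0)


def _star_scene(k, frame=100):
    c = frame // 2
    spec = fx.CellShapeSpec(center=(c, c), shape=("star", k, STAR["r_in"], STAR["r_out"]))
    stack, truth = fx.render_adhesion_scene([spec], frame_shape=(frame, frame))
    return stack.frames[0][..., 0] > 50, truth, (c, c)


class TestBrightfieldMorphology:
    def test_disk_area_and_circularity(self):
        scene, _ = fx.render_adhesion_scene(
            [fx.CellShapeSpec(center=(30, 30), shape=("disk", 10))], frame_shape=(60, 60)
        )
        records, density = adh.measure_brightfield_cells(
            scene.frames[0][..., 0], 21, um_per_px=0.5
        )
        assert len(records) == 1
        r = records[0]
        assert r.circularity < 0.1
        # rasterized-disk oracle: 317 px² at 0.25 µm²/px
        assert r.area_um2 == pytest.approx(317 * 0.25, rel=0.10)
        assert density == pytest.approx(1 / (60 * 60 * 0.25 * 1e-6))

    def test_area_window_excludes_small_regions(self):
        specs = [
            fx.CellShapeSpec(center=(25, 25), shape=("disk", 10)),
            fx.CellShapeSpec(center=(70, 70), shape=("disk", 3)),
        ]
        scene, _ = fx.render_adhesion_scene(specs, frame_shape=(100, 100))
        img = scene.frames[0][..., 0]
        all_cells, _ = adh.measure_brightfield_cells(img, 21, um_per_px=1.0)
        assert len(all_cells) == 2
        big_only, _ = adh.measure_brightfield_cells(img, 21, min_area_um2=100.0,
                                                    um_per_px=1.0)
        assert len(big_only) == 1

    def test_ellipse_eccentricity_matches_moment_oracle(self):
        scene, truth = fx.render_adhesion_scene(
            [fx.CellShapeSpec(center=(30, 30), shape=("ellipse", 8, 4))],
            frame_shape=(60, 60),
        )
        records, _ = adh.measure_brightfield_cells(scene.frames[0][..., 0], 21)
        assert records[0].circularity == pytest.approx(truth.objects.eccentricity[0],
                                                       abs=0.05)

    def test_dilated_shape_has_larger_area(self):
        areas = []
        for r in (6, 8, 10):
            scene, _ = fx.render_adhesion_scene(
                [fx.CellShapeSpec(center=(30, 30), shape=("disk", r))], frame_shape=(60, 60)
            )
            recs, _ = adh.measure_brightfield_cells(scene.frames[0][..., 0], 25)
            areas.append(recs[0].area_um2)
        assert areas[0] < areas[1] < areas[2]


class TestFluorescentCells:
    @pytest.fixture()
    def scene(self):
        specs = [
            fx.CellShapeSpec(center=(25, 25), shape=("disk", 10),
                             membrane_intensity=180.0, secondary_intensity=90.0,
                             secondary_frac=0.4),
            fx.CellShapeSpec(center=(70, 65), shape=("ellipse", 12, 6),
                             membrane_intensity=140.0),
        ]
        return fx.render_adhesion_scene(specs, frame_shape=(100, 100))

    def test_region_measurements_match_truth(self, scene):
        stack, truth = scene
        records = adh.measure_fluorescent_cells(stack, 0, 50.0, secondary_channel=1,
                                                secondary_threshold=10.0)
        assert len(records) == 2
        by_pos = sorted(records, key=lambda r: r.x)
        t = truth.objects.sort_values("x").reset_index()
        for rec, (_, tr) in zip(by_pos, t.iterrows()):
            assert rec.area_px == tr.area_px
            assert rec.circularity == pytest.approx(tr.eccentricity, abs=0.02)
            assert rec.secondary_sum == pytest.approx(tr.secondary_sum)

    def test_uniform_region_texture_is_zero(self, scene):
        stack, _ = scene
        records = adh.measure_fluorescent_cells(stack, 0, 50.0)
        for r in records:
            assert r.membrane_texture == 0.0

    def test_secondary_all_below_threshold_sums_zero(self, scene):
        stack, _ = scene
        records = adh.measure_fluorescent_cells(stack, 0, 50.0, secondary_channel=1,
                                                secondary_threshold=1e6)
        assert all(r.secondary_sum == 0.0 for r in records)

    @pytest.mark.parametrize("n_lobes", [1, 2, 3, 4, 5])
    def test_lobe_counts_recovered(self, n_lobes):
        spec = fx.CellShapeSpec(center=(40, 40), shape=("disk", 14),
                                lobe_count=n_lobes, lobe_sep_px=12.0)
        stack, _ = fx.render_adhesion_scene([spec], frame_shape=(80, 80))
        records = adh.measure_fluorescent_cells(stack, 0, 50.0, lobe_channel=2,
                                                lobe_threshold=30.0, min_peak_sep_px=8)
        assert records[0].lobe_count == n_lobes

    def test_three_lobes_at_12px_with_sep_8(self):
        spec = fx.CellShapeSpec(center=(40, 40), shape=("disk", 14),
                                lobe_count=3, lobe_sep_px=12.0)
        stack, truth = fx.render_adhesion_scene([spec], frame_shape=(80, 80))
        records = adh.measure_fluorescent_cells(stack, 0, 50.0, lobe_channel=2,
                                                lobe_threshold=30.0, min_peak_sep_px=8)
        assert records[0].lobe_count == truth.objects.lobe_count[0] == 3

    def test_missing_channel_rejected(self, scene):
        stack, _ = scene
        with pytest.raises(InputError):
            adh.measure_fluorescent_cells(stack, 5, 50.0)

    def test_raising_threshold_monotone_in_area_and_count(self):
        # nested intensities: bright core inside a dimmer corona
        img = np.zeros((60, 60, 3))
        yy, xx = np.mgrid[0:60, 0:60]
        img[..., 0] += np.where((xx - 30) ** 2 + (yy - 30) ** 2 <= 15**2, 80.0, 0.0)
        img[..., 0] += np.where((xx - 30) ** 2 + (yy - 30) ** 2 <= 8**2, 100.0, 0.0)
        prev_area = math.inf
        prev_count = math.inf
        for thr in (50.0, 90.0, 170.0):
            recs = adh.measure_fluorescent_cells(img, 0, thr)
            count = len(recs)
            area = sum(r.area_px for r in recs)
            assert count <= prev_count and area <= prev_area
            prev_area, prev_count = area, count


class TestCountProtrusions:
    @pytest.mark.parametrize("k", [3, 4, 5, 6, 7, 8])
    def test_star_order_recovered_exactly(self, k):
        mask, truth, _ = _star_scene(k)
        n, dmin, dmean, dmax = adh.count_protrusions(mask, 0.15, 6)
        assert n == truth.objects.protrusion_count[0] == k

    def test_five_star_tip_distances_match_rasterized_tips(self):
        mask, _, (cx, cy) = _star_scene(5)
        n, dmin, dmean, dmax = adh.count_protrusions(mask, 0.15, 6)
        assert n == 5
        # oracle: per-tip extremity of the rasterized star
        ys, xs = np.nonzero(mask)
        ang = np.arctan2(ys - cy, xs - cx)
        rad = np.hypot(xs - cx, ys - cy)
        tip_extents = []
        for j in range(5):
            th = -math.pi / 2 + 2 * math.pi * j / 5
            sector = np.abs(np.angle(np.exp(1j * (ang - th)))) < math.pi / 10
            tip_extents.append(rad[sector].max())
        assert dmin >= min(tip_extents) - 1.0
        assert dmax <= max(tip_extents) + 1.0

    def test_smooth_disk_has_no_protrusions(self):
        scene, _ = fx.render_adhesion_scene(
            [fx.CellShapeSpec(center=(30, 30), shape=("disk", 12))], frame_shape=(60, 60)
        )
        n, *_ = adh.count_protrusions(scene.frames[0][..., 0] > 50, 0.15, 6)
        assert n == 0

    def test_close_tips_merge_under_min_separation(self):
        # a 5-star with an extra tip 4 px from one tip: 6 planted protrusions,
        # min_separation 6 merges the close pair -> planted - 1
        verts = fx.star_vertices(5, STAR["r_in"], STAR["r_out"])
        a0, da = -math.pi / 2, 4.0 / STAR["r_out"]
        extra = (STAR["r_out"] * math.cos(a0 + da), STAR["r_out"] * math.sin(a0 + da))
        spec = fx.CellShapeSpec(center=(50, 50), shape=("polygon", [verts[0], extra] + verts[1:]),
                                protrusions=6)
        stack, truth = fx.render_adhesion_scene([spec], frame_shape=(100, 100))
        mask = stack.frames[0][..., 0] > 50
        n, *_ = adh.count_protrusions(mask, 0.15, 6)
        assert n == truth.objects.protrusion_count[0] - 1 == 5

    def test_degenerate_region_counts_zero(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 10] = True
        assert adh.count_protrusions(mask, 0.15, 6)[0] == 0


class TestTransientAdhesion:
    @pytest.fixture()
    def video(self):
        """5 stationary cells present for different frame spans + 1 bright debris."""
        n_frames = 40
        frames = np.zeros((n_frames, 64, 160))
        spans = [(0, 39), (5, 29), (10, 34), (8, 15), (20, 27)]
        xs = [20, 45, 70, 95, 120]
        for (f0, f1), x in zip(spans, xs):
            for t in range(f0, f1 + 1):
                fx._add_gaussian(frames[t], x, 32.0, 2.0, 150.0)
        for t in range(n_frames):  # debris: far brighter integrated mass
            fx._add_gaussian(frames[t], 145.0, 32.0, 2.0, 3000.0)
        from flowquant.io_media import FrameStack

        return FrameStack(frames, fps=25.0, um_per_px=1.0), spans

    def test_adhesion_times_match_planted_spans(self, video):
        stack, spans = video
        records = adh.measure_transient_adhesion(stack, 7, min_mass=100.0,
                                                 max_intensity=5_000.0, min_frames=3,
                                                 fps=25.0)
        assert len(records) == 5
        times = sorted(r.adhesion_time_s for r in records)
        expected = sorted((f1 - f0 + 1) / 25.0 for f0, f1 in spans)
        assert times == pytest.approx(expected)

    def test_times_are_multiples_of_frame_interval(self, video):
        stack, _ = video
        records = adh.measure_transient_adhesion(stack, 7, min_mass=100.0,
                                                 max_intensity=5_000.0, fps=25.0)
        for r in records:
            n = r.adhesion_time_s * 25.0
            assert n == pytest.approx(round(n), abs=1e-9)

    def test_cell_present_25_frames_at_25fps_is_one_second(self, video):
        stack, _ = video
        records = adh.measure_transient_adhesion(stack, 7, min_mass=100.0,
                                                 max_intensity=5_000.0, fps=25.0)
        by_x = sorted(records, key=lambda r: r.x)
        assert by_x[2].adhesion_time_s == pytest.approx(1.0)  # frames 10-34

    def test_min_frames_excludes_brief_events(self, video):
        stack, _ = video
        records = adh.measure_transient_adhesion(stack, 7, min_mass=100.0,
                                                 max_intensity=5_000.0, min_frames=10,
                                                 fps=25.0)
        assert len(records) == 3  # both 8-frame events are gone

    def test_missing_fps_rejected(self, video):
        stack, _ = video
        from dataclasses import replace

        with pytest.raises(InputError):
            adh.measure_transient_adhesion(replace(stack, fps=None), 7, fps=None)
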