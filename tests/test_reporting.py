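"""Tabular export, media annotation, graphs, workflow orchestration, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from flowquant import adhesion as adh
from flowquant import clustering as clu
from flowquant import fixtures as fx
from flowquant import reporting as rep
from flowquant.cli import main as cli_main
from flowquant.io_media import InputError


@pytest.fixture()
def records():
    return [
        adh.CellRecord(cell_id=i, x=10.0 + 15 * i, y=20.0, area_um2=30.0 + i,
                       circularity=0.1 * i, adhesion_time_s=0.2 * (i + 1))
        for i in range(5)
    ]


class TestExportTabular:
    def test_indexed_rows_and_stats_block(self, records, tmp_path):
        files = rep.export_tabular(records, tmp_path / "cells.csv")
        table = pd.read_csv(files[0])
        stats = pd.read_csv(files[1])
        assert len(table) == 5
        assert table["index"].tolist() == [0, 1, 2, 3, 4]
        assert (stats.n == 5).all()
        assert {"mean", "s.d.", "min", "25%", "50%", "75%", "max"} <= set(stats.columns)

    def test_constant_column_stats(self, tmp_path):
        df = pd.DataFrame({"v": [7.0] * 6})
        files = rep.export_tabular(df, tmp_path / "t.csv")
        stats = pd.read_csv(files[1]).set_index("column")
        assert stats.loc["v", "mean"] == 7.0
        assert stats.loc["v", "s.d."] == 0.0

    def test_xlsx_has_two_sheets(self, records, tmp_path):
        files = rep.export_tabular(records, tmp_path / "cells.xlsx")
        sheets = pd.read_excel(files[0], sheet_name=None)
        assert set(sheets) == {"events", "statistics"}

    def test_roundtrip_into_feature_matrix(self, records, tmp_path):
        files = rep.export_tabular(records, tmp_path / "sample_a.csv")
        m = clu.assemble_feature_matrix([files[0]], ["area_um2", "adhesion_time_s"],
                                        standardize=False)
        assert m.n_points == 5
        np.testing.assert_allclose(m.points[:, 0], [30.0, 31.0, 32.0, 33.0, 34.0])
        assert (m.sample_labels == "sample_a").all()

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(InputError):
            rep.export_tabular([], tmp_path / "x.csv")


class TestAnnotateMedia:
    def test_labels_rendered_at_centroids(self, tmp_path):
        from flowquant.io_media import FrameStack

        stack = FrameStack(np.zeros((1, 64, 128)))
        recs = [adh.CellRecord(cell_id=i, x=20.0 + 30 * i, y=32.0) for i in range(3)]
        out = rep.annotate_media(stack, recs, tmp_path / "ann")
        img = np.asarray(__import__("PIL.Image", fromlist=["open"]).open(out))
        for r in recs:  # centroid marker pixels set in cyan
            patch = img[int(r.y) - 2 : int(r.y) + 3, int(r.x) - 2 : int(r.x) + 3]
            assert patch[..., 1].max() == 255 and patch[..., 2].max() == 255

    def test_empty_records_copy_unmodified(self, tmp_path):
        from flowquant.io_media import FrameStack

        frame = np.random.default_rng(0).integers(0, 255, (32, 32)).astype(float)
        stack = FrameStack(frame[None])
        out = rep.annotate_media(stack, [], tmp_path / "ann")
        img = np.asarray(__import__("PIL.Image", fromlist=["open"]).open(out))
        np.testing.assert_array_equal(img[..., 0], frame.astype(np.uint8))

    def test_label_text_matches_record_index(self, records, tmp_path):
        from flowquant.io_media import FrameStack

        stack = FrameStack(np.zeros((1, 64, 128)))
        files = rep.export_tabular(records, tmp_path / "cells.csv")
        table = pd.read_csv(files[0])
        assert table["index"].tolist() == [r.cell_id for r in records]

    def test_offframe_event_skipped_with_warning(self, tmp_path):
        from flowquant.io_media import FrameStack

        stack = FrameStack(np.zeros((1, 32, 32)))
        recs = [adh.CellRecord(cell_id=0, x=500.0, y=500.0)]
        with pytest.warns(UserWarning):
            rep.annotate_media(stack, recs, tmp_path / "ann")


class TestMakeGraphs:
    def test_histogram_files_written(self, tmp_path):
        df = pd.DataFrame({"velocity_um_s": np.random.default_rng(1).normal(100, 10, 100)})
        written = rep.make_graphs(df, "histogram", tmp_path)
        assert all(p.exists() for p in written.values())

    def test_pairplot_grid_structure(self):
        df = pd.DataFrame(np.random.default_rng(2).normal(size=(40, 3)),
                          columns=["a", "b", "c"])
        grid = rep._pair_grid(df, ["a", "b", "c"])
        assert grid.axes.shape == (3, 3)
        for i in range(3):  # histogram panels on the diagonal
            assert len(grid.diag_axes[i].patches) > 0

    def test_timecourse_one_line_per_plane(self, tmp_path):
        df = pd.DataFrame({
            "time_min": [0, 1, 2] * 2,
            "plane": [0, 0, 0, 1, 1, 1],
            "occlusion_pct": [0, 10, 20, 5, 15, 25],
        })
        written = rep.make_graphs(df, "timecourse", tmp_path)
        assert written["timecourse"].exists()

    def test_non_numeric_column_rejected(self, tmp_path):
        df = pd.DataFrame({"name": ["a", "b"], "v": [1.0, 2.0]})
        with pytest.raises(InputError):
            rep.make_graphs(df, "histogram", tmp_path, columns=["name"])


class TestRunConfig:
    def test_roundtrip_idempotent(self, tmp_path):
        cfg = rep.RunConfig(workflow="track", inputs=["a.tif"], seed=3,
                            params={"diameter": 7, "min_mass": 50.0})
        p1, p2 = tmp_path / "c1.yaml", tmp_path / "c2.yaml"
        cfg.to_file(p1)
        again = rep.RunConfig.from_file(p1)
        again.to_file(p2)
        assert p1.read_text() == p2.read_text()
        assert again.params == cfg.params and again.workflow == cfg.workflow

    def test_unknown_workflow_fails_before_compute(self):
        with pytest.raises(InputError, match="unknown workflow"):
            rep.run_workflow(rep.RunConfig(workflow="nope"))


@pytest.fixture(scope="module")
def tracking_fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("trackfix")
    stack, truth = fx.render_moving_cells(6, 125.0, n_frames=25, fps=25.0,
                                          um_per_px=1.0, seed=21)
    fx.save_fixture(stack, truth, d)
    return d


class TestWorkflows:
    def _cfg(self, d, out, seed=0):
        return rep.RunConfig(
            workflow="track", inputs=[str(d)], output_dir=str(out), seed=seed,
            params={"diameter": 7, "min_mass": 50.0, "search_range": 8.0,
                    "min_frames": 5, "fps": 25.0, "um_per_px": 1.0},
        )

    def test_track_workflow_end_to_end(self, tracking_fixture_dir, tmp_path):
        result = rep.run_workflow(self._cfg(tracking_fixture_dir, tmp_path / "out"))
        table = result["table"]
        assert len(table) == 6
        np.testing.assert_allclose(table.velocity_um_s, 125.0, rtol=0.02)
        assert (tmp_path / "out" / "run_log.txt").exists()
        assert (tmp_path / "out" / "cells.csv").exists()

    def test_rerun_same_seed_byte_identical_tables(self, tracking_fixture_dir, tmp_path):
        rep.run_workflow(self._cfg(tracking_fixture_dir, tmp_path / "a"))
        rep.run_workflow(self._cfg(tracking_fixture_dir, tmp_path / "b"))
        assert (tmp_path / "a" / "cells.csv").read_bytes() == \
               (tmp_path / "b" / "cells.csv").read_bytes()

    def test_occlusion_workflow(self, tmp_path):
        stencil, chans = fx.make_comb_stencil(4)
        stack, _ = fx.render_occlusion_series(stencil, [0.0, 0.25, 0.5, 1.0], seed=2,
                                              channels=chans)
        d = tmp_path / "occfix"
        fx.save_fixture(stack, fx.FixtureTruth(objects=pd.DataFrame({"a": [0]})), d)
        cfg = rep.RunConfig(workflow="occlusion", inputs=[str(d)],
                            output_dir=str(tmp_path / "out"),
                            params={"threshold_r": 100.0, "variant": "microchannel"})
        result = rep.run_workflow(cfg)
        assert len(result["device_map"].channels) == 4
        final = result["table"].query("timepoint == 3")
        assert final.occlusion_pct.iloc[0] == pytest.approx(100.0)
        assert (tmp_path / "out" / "spatial_occlusion.csv").exists()

    def test_parameter_sweep_membrane_threshold_monotone(self, tmp_path):
        # nested-intensity scene: higher threshold can only shrink regions
        specs = [
            fx.CellShapeSpec(center=(25, 25), shape=("disk", 8), membrane_intensity=70.0),
            fx.CellShapeSpec(center=(70, 40), shape=("disk", 8), membrane_intensity=90.0),
            fx.CellShapeSpec(center=(40, 70), shape=("disk", 8), membrane_intensity=110.0),
        ]
        scene, _ = fx.render_adhesion_scene(specs, frame_shape=(100, 100))
        d = tmp_path / "scene"
        fx.save_fixture(scene, fx.FixtureTruth(objects=pd.DataFrame({"a": [0]})), d)
        cfg = rep.RunConfig(
            workflow="adhesion_fluorescent",
            inputs=[str(d / "frame_0000.tif")],
            output_dir=str(tmp_path / "out"),
            params={"membrane_channel": 0, "membrane_threshold": 60.0},
        )
        sweep = rep.parameter_sweep(cfg, {"membrane_threshold": [60.0, 80.0, 100.0]})
        counts = sweep.query("quantity == 'n_records'").sort_values(
            "membrane_threshold"
        ).value.tolist()
        assert counts == [3, 2, 1]

    def test_sweep_rejects_unknown_parameter(self, tracking_fixture_dir, tmp_path):
        cfg = self._cfg(tracking_fixture_dir, tmp_path / "out")
        with pytest.raises(InputError):
            rep.parameter_sweep(cfg, {"not_a_param": [1, 2]})


class TestCli:
    def test_track_subcommand(self, tracking_fixture_dir, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cli_out"
        result = runner.invoke(cli_main, [
            "track", "--input", str(tracking_fixture_dir), "--output-dir", str(out),
            "diameter=7", "min_mass=50.0", "search_range=8.0", "min_frames=5",
            "fps=25.0", "um_per_px=1.0",
        ])
        assert result.exit_code == 0, result.output
        assert (out / "cells.csv").exists()

    def test_cluster_subcommand(self, tmp_path):
        rng = np.random.default_rng(3)
        for name, mu in (("ctrl", 0.0), ("case", 12.0)):
            pd.DataFrame({"v": rng.normal(mu, 1, 60), "s": rng.normal(mu, 1, 60)}).to_csv(
                tmp_path / f"{name}.csv", index=False
            )
        out = tmp_path / "cl_out"
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "cluster", "--input", str(tmp_path / "ctrl.csv"),
            "--input", str(tmp_path / "case.csv"), "--output-dir", str(out),
            "--seed", "0", "features=v,s", "k=2",
        ])
        assert result.exit_code == 0, result.output
        freq = pd.read_csv(out / "frequency_table.csv", index_col=0)
        assert freq.values.sum() == 120

    def test_unreadable_input_reports_input_error(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "track", "--input", str(tmp_path / "missing_dir"),
            "fps=25.0", "um_per_px=1.0",
        ])
        assert result.exit_code == 2
        assert "input error" in result.output
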