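"""Tabular export, media annotation, standard graphs, and workflow orchestration.

Every workflow ends the same way: an indexed event table with descriptive
statistics, the input imaging annotated with the same per-event indices, and
a set of standard graphs — so a table row, a label in the image, and a point
in a plot always refer to the same event.

:func:`run_workflow` executes a named pipeline end-to-end from a
:class:`RunConfig`; :func:`parameter_sweep` re-runs it over a parameter grid
and tabulates summary outputs against parameter values, the harness used to
check that results are robust to parameter choice.

Config files are flat YAML mappings (``key: value`` per line): the keys
``workflow``, ``inputs``, ``output_dir``, ``seed`` and ``log_level`` are
reserved; every other key is passed to the workflow as a parameter.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
import yaml
from PIL import Image, ImageDraw

from . import accumulation as acc
from . import adhesion as adh
from . import clustering as clu
from . import fixtures as fix
from . import suspension as susp
from . import tracking as trk
from .io_media import FrameStack, InputError, ROI, crop_roi, load_stack, subtract_background

__all__ = [
    "RunConfig",
    "export_tabular",
    "annotate_media",
    "make_graphs",
    "run_workflow",
    "parameter_sweep",
    "WORKFLOWS",
]


@dataclass
class RunConfig:
    """A fully specified, reproducible workflow run."""

    workflow: str
    inputs: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    output_dir: str = "flowquant_out"
    seed: int = 0
    log_level: str = "info"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "workflow" not in raw:
            raise InputError(f"config {path} has no 'workflow' key")
        inputs = raw.pop("inputs", [])
        if isinstance(inputs, str):
            inputs = [p for p in (s.strip() for s in inputs.split(",")) if p]
        return cls(
            workflow=raw.pop("workflow"),
            inputs=list(inputs),
            output_dir=str(raw.pop("output_dir", "flowquant_out")),
            seed=int(raw.pop("seed", 0)),
            log_level=str(raw.pop("log_level", "info")),
            params=raw,
        )

    def to_file(self, path) -> None:
        data = {
            "workflow": self.workflow,
            "inputs": list(self.inputs),
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        data.update(self.params)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True, default_flow_style=False)


# ---------------------------------------------------------------------------
# Tabular export


def _describe(df: pd.DataFrame) -> pd.DataFrame:
    num = df.select_dtypes(include=[np.number])
    stats = num.describe().T
    stats.index.name = "column"
    return stats.rename(columns={"count": "n", "std": "s.d."}).reset_index()


def export_tabular(records, path) -> list[Path]:
    """Write an indexed event table plus a descriptive-statistics block.

    ``records`` is a DataFrame or a list of :class:`~flowquant.adhesion.CellRecord`.
    ``.xlsx`` paths get two sheets (``events``, ``statistics``); any other
    suffix writes ``<stem>.csv`` and ``<stem>_stats.csv``.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = adh.records_to_frame(list(records))
    if df.empty:
        raise InputError("export_tabular: no records to export")
    if "index" not in df.columns:
        df.insert(0, "index", df["cell_id"].values if "cell_id" in df.columns
                  else np.arange(len(df)))
    stats = _describe(df.drop(columns=["index"], errors="ignore"))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".xlsx":
        try:
            with pd.ExcelWriter(path, engine="openpyxl") as writer:
                df.to_excel(writer, sheet_name="events", index=False)
                stats.to_excel(writer, sheet_name="statistics", index=False)
            return [path]
        except Exception:
            path = path.with_suffix(".csv")  # CSV fallback for very large tables
    stats_path = path.with_name(path.stem + "_stats.csv")
    df.to_csv(path, index=False)
    stats.to_csv(stats_path, index=False)
    return [path, stats_path]


# ---------------------------------------------------------------------------
# Media annotation


def _to_uint8_rgb(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=float)
    top = f.max() if f.max() > 0 else 1.0
    scale = 255.0 / max(top, 255.0) if top > 255 else 1.0
    f = np.clip(f * scale, 0, 255).astype(np.uint8)
    if f.ndim == 2:
        f = np.stack([f] * 3, axis=-1)
    return f


_LABEL_COLOR = (0, 255, 255)  # cyan, as used for trajectory overlays


def annotate_media(stack: FrameStack, records_or_trajectories, path) -> Path:
    """Overlay each event's index at its centroid; draw trajectory paths.

    Accepts a list of :class:`~flowquant.adhesion.CellRecord` (static scenes:
    the same labels on every frame) or of
    :class:`~flowquant.tracking.Trajectory` (paths drawn as cyan polylines,
    the index at the first detection).  Events whose coordinates fall outside
    the frame are skipped with a warning.  Single-frame stacks are written as
    PNG, longer stacks as multi-page TIFF.
    """
    import warnings

    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    h, w = stack.height, stack.width
    out_frames = []
    items = list(records_or_trajectories)
    trajectories = items and isinstance(items[0], trk.Trajectory)

    for t in range(stack.n_frames):
        img = Image.fromarray(_to_uint8_rgb(stack.frame(t)))
        draw = ImageDraw.Draw(img)
        if trajectories:
            for traj in items:
                pts = [(d.x, d.y) for d in traj.detections if d.frame <= t]
                if len(pts) >= 2:
                    draw.line(pts, fill=_LABEL_COLOR, width=1)
                here = [d for d in traj.detections if d.frame == t]
                if here:
                    d0 = here[0]
                    _draw_label(draw, d0.x, d0.y, str(traj.cell_id), (h, w), warnings)
        else:
            for rec in items:
                _draw_label(draw, rec.x, rec.y, str(rec.cell_id), (h, w), warnings)
        out_frames.append(np.asarray(img))

    if len(out_frames) == 1:
        Image.fromarray(out_frames[0]).save(path.with_suffix(".png"))
        return path.with_suffix(".png")
    tifffile.imwrite(path.with_suffix(".tif"), np.stack(out_frames))
    return path.with_suffix(".tif")


def _draw_label(draw, x, y, text, shape_hw, warnings_mod) -> None:
    h, w = shape_hw
    if not (0 <= x < w and 0 <= y < h):
        warnings_mod.warn(f"event {text} at ({x:.1f}, {y:.1f}) outside frame; skipped")
        return
    xi, yi = int(round(x)), int(round(y))
    # centroid marker: small plus sign
    draw.line([(xi - 2, yi), (xi + 2, yi)], fill=_LABEL_COLOR)
    draw.line([(xi, yi - 2), (xi, yi + 2)], fill=_LABEL_COLOR)
    draw.text((min(xi + 4, w - 8), max(yi - 10, 0)), text, fill=_LABEL_COLOR)


# ---------------------------------------------------------------------------
# Graphs


def _pair_grid(df: pd.DataFrame, columns: list[str]):
    return sns.pairplot(df[columns], diag_kind="hist", corner=False,
                        plot_kws={"s": 12}, height=2.0)


def make_graphs(records, kinds, out_dir, columns: list[str] | None = None) -> dict[str, Path]:
    """Write one deterministic figure file per requested kind.

    ``histogram`` writes one file per numeric column; ``scatter`` plots the
    first two columns; ``pairplot`` builds a seaborn grid with histograms on
    the diagonal; ``timecourse`` expects an occlusion/velocity table with a
    time-like first column and draws one line per plane/series; ``profile``
    draws mean velocity against bin center.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = adh.records_to_frame(list(records))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    numeric = [c for c in df.columns
               if pd.api.types.is_numeric_dtype(df[c]) and c not in ("index", "cell_id")]
    if columns:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise InputError(f"requested columns not present: {missing}")
        bad = [c for c in columns if not pd.api.types.is_numeric_dtype(df[c])]
        if bad:
            raise InputError(f"requested columns are not numeric: {bad}")
        numeric = columns
    written: dict[str, Path] = {}
    if isinstance(kinds, str):
        kinds = [kinds]
    for kind in kinds:
        if kind == "histogram":
            for col in numeric:
                fig, ax = plt.subplots(figsize=(4, 3))
                data = df[col].dropna()
                spread = float(data.max() - data.min()) if len(data) else 0.0
                if spread < 1e-6:  # effectively constant: fixed-width bin
                    v = float(data.iloc[0]) if len(data) else 0.0
                    bins = np.linspace(v - 0.5, v + 0.5, 3)
                else:
                    bins = 20
                ax.hist(data, bins=bins, color="#4878d0")
                ax.set_xlabel(col)
                ax.set_ylabel("count")
                fig.tight_layout()
                p = out_dir / f"hist_{col}.png"
                fig.savefig(p, dpi=110)
                plt.close(fig)
                written[f"histogram:{col}"] = p
        elif kind == "scatter":
            if len(numeric) < 2:
                raise InputError("scatter needs at least two numeric columns")
            a, b = numeric[:2]
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.scatter(df[a], df[b], s=12, color="#4878d0")
            ax.set_xlabel(a)
            ax.set_ylabel(b)
            fig.tight_layout()
            p = out_dir / f"scatter_{a}_vs_{b}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written["scatter"] = p
        elif kind == "pairplot":
            grid = _pair_grid(df, numeric)
            p = out_dir / "pairplot.png"
            grid.savefig(p, dpi=110)
            plt.close(grid.figure)
            written["pairplot"] = p
        elif kind == "timecourse":
            tcol = df.columns[0]
            fig, ax = plt.subplots(figsize=(4.5, 3))
            if "plane" in df.columns:
                for plane, grp in df.groupby("plane"):
                    ycol = [c for c in numeric if c not in (tcol, "plane")][0]
                    ax.plot(grp[tcol], grp[ycol], marker="o", label=f"plane {plane}")
                ax.legend()
            else:
                for col in numeric[1:] or numeric:
                    ax.plot(df[tcol], df[col], marker="o", label=col)
                ax.legend()
            ax.set_xlabel(str(tcol))
            fig.tight_layout()
            p = out_dir / "timecourse.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written["timecourse"] = p
        elif kind == "profile":
            fig, ax = plt.subplots(figsize=(4.5, 3))
            xcol = "bin_center_um" if "bin_center_um" in df.columns else df.columns[0]
            ycol = ("mean_velocity_um_s" if "mean_velocity_um_s" in df.columns
                    else numeric[-1])
            ax.plot(df[xcol], df[ycol], marker="o", color="#4878d0")
            ax.set_xlabel("distance from channel center (µm)")
            ax.set_ylabel("mean velocity (µm/s)")
            fig.tight_layout()
            p = out_dir / "profile.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written["profile"] = p
        else:
            raise InputError(f"unknown graph kind {kind!r}")
    return written


# ---------------------------------------------------------------------------
# Workflow orchestration


def _load_inputs(cfg: RunConfig) -> FrameStack:
    if not cfg.inputs:
        raise InputError(f"workflow {cfg.workflow!r} needs at least one input path")
    p = cfg.params
    if len(cfg.inputs) == 1:
        stack = load_stack(cfg.inputs[0], fps=p.get("fps"), um_per_px=p.get("um_per_px"))
    else:
        stack = load_stack(cfg.inputs, fps=p.get("fps"), um_per_px=p.get("um_per_px"))
    if all(k in p for k in ("roi_x0", "roi_y0", "roi_width", "roi_height")):
        stack = crop_roi(stack, ROI(int(p["roi_x0"]), int(p["roi_y0"]),
                                    int(p["roi_width"]), int(p["roi_height"])))
    if p.get("background") in ("static-median", "rolling"):
        stack = subtract_background(stack, method=p["background"])
    return stack


def _wf_track(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params
    stack = _load_inputs(cfg)
    dets = trk.detect_stack(
        stack, int(p.get("diameter", 7)),
        min_mass=float(p.get("min_mass", 0.0)),
        max_diameter_px=p.get("max_diameter"),
        min_intensity=p.get("min_intensity"),
        invert=bool(p.get("invert", False)),
    )
    trajs = trk.link_and_filter(
        dets, float(p.get("search_range", 10.0)),
        memory_frames=int(p.get("memory", 0)),
        min_frames=int(p.get("min_frames", 3)),
        min_distance_px=float(p.get("min_distance", 0.0)),
    )
    rows = []
    for t in trajs:
        vel = trk.compute_cell_velocity(t, stack.require_fps(), stack.require_um_per_px(),
                                        mode=p.get("mode", "free"))
        row = {"cell_id": t.cell_id, "n_frames_present": t.n_frames_present,
               "path_distance_px": t.path_distance,
               "net_displacement_px": t.net_displacement,
               "mean_mass": t.mean_mass, **vel}
        if p.get("fluorescence_channel") is not None:
            row["mean_fluorescence_sum"] = trk.measure_cell_fluorescence(
                t, stack, int(p["fluorescence_channel"]),
                float(p.get("aperture_radius", 2 * int(p.get("diameter", 7)))),
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    outputs = {"trajectories": trajs, "table": df}
    if not df.empty:
        outputs["files"] = export_tabular(df, out / "cells.csv")
        outputs["annotated"] = annotate_media(stack, trajs, out / "annotated")
        outputs["graphs"] = make_graphs(
            df, ["histogram", "scatter"],
            out / "graphs", columns=["velocity_um_s", "area_um2"],
        )
    return outputs


def _wf_profile(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params
    stack = _load_inputs(cfg)
    feats = susp.detect_and_track_flow(
        stack,
        max_features=int(p.get("max_features", 200)),
        quality=float(p.get("quality", 0.05)),
        min_corner_sep_px=int(p.get("min_corner_sep", 7)),
        window_size_px=int(p.get("window", 15)),
        reseed_every=int(p.get("reseed_every", 10)),
    )
    fps = stack.require_fps()
    um = stack.require_um_per_px()
    timecourse = susp.summarize_timecourse(feats, fps, um,
                                           min_step_px=float(p.get("min_step", 0.0)))
    span = None
    if "channel_top" in p and "channel_bottom" in p:
        span = (float(p["channel_top"]), float(p["channel_bottom"]))
    profile = susp.build_velocity_profile(
        feats, float(p.get("bin_width", 10.0)), fps, um, channel_span=span,
    )
    files = export_tabular(timecourse, out / "timecourse.csv")
    files += export_tabular(profile.table.fillna(0), out / "profile.csv")
    graphs = make_graphs(profile.table.dropna(), "profile", out / "graphs")
    return {"features": feats, "timecourse": timecourse, "profile": profile,
            "table": timecourse, "files": files, "graphs": graphs}


def _wf_adhesion_brightfield(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params
    stack = _load_inputs(cfg)
    records, density = adh.measure_brightfield_cells(
        stack.gray()[0], int(p.get("diameter", 11)),
        min_area_um2=float(p.get("min_area", 0.0)),
        max_area_um2=float(p.get("max_area", np.inf)),
        invert=bool(p.get("invert", False)),
        um_per_px=stack.require_um_per_px(),
        min_mass=float(p.get("min_mass", 0.0)),
    )
    df = adh.records_to_frame(records)
    outputs = {"records": records, "field_density_per_mm2": density, "table": df}
    if records:
        outputs["files"] = export_tabular(df, out / "cells.csv")
        outputs["annotated"] = annotate_media(stack, records, out / "annotated")
        outputs["graphs"] = make_graphs(df, "histogram", out / "graphs",
                                        columns=["area_um2", "circularity"])
    return outputs


def _wf_adhesion_fluorescent(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params
    stack = _load_inputs(cfg)
    records = adh.measure_fluorescent_cells(
        stack,
        membrane_channel=int(p.get("membrane_channel", 0)),
        membrane_threshold=float(p.get("membrane_threshold", 0.0)),
        secondary_channel=(int(p["secondary_channel"])
                           if p.get("secondary_channel") is not None else None),
        secondary_threshold=float(p.get("secondary_threshold", 0.0)),
        lobe_channel=(int(p["lobe_channel"]) if p.get("lobe_channel") is not None else None),
        lobe_threshold=float(p.get("lobe_threshold", 0.0)),
        min_peak_sep_px=int(p.get("min_peak_sep", 8)),
        min_area_um2=float(p.get("min_area", 0.0)),
        max_area_um2=float(p.get("max_area", np.inf)),
        um_per_px=stack.um_per_px or 1.0,
    )
    if bool(p.get("count_protrusions", False)):
        membrane = stack.frames[0][..., int(p.get("membrane_channel", 0))]
        mask = membrane > float(p.get("membrane_threshold", 0.0))
        from skimage.measure import label as sk_label

        labels = sk_label(mask, connectivity=2)
        for rec in records:
            region = labels == rec.extra.get("label")
            n, dmin, dmean, dmax = adh.count_protrusions(
                region,
                corner_sharpness=float(p.get("sharpness", 0.15)),
                min_separation_px=int(p.get("min_protrusion_sep", 6)),
                um_per_px=stack.um_per_px or 1.0,
            )
            rec.protrusion_count = n
            rec.protrusion_dist_min_um = dmin
            rec.protrusion_dist_mean_um = dmean
            rec.protrusion_dist_max_um = dmax
    df = adh.records_to_frame(records)
    outputs = {"records": records, "table": df}
    if records:
        outputs["files"] = export_tabular(df, out / "cells.csv")
        outputs["annotated"] = annotate_media(stack, records, out / "annotated")
    return outputs


def _wf_adhesion_transient(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params
    stack = _load_inputs(cfg)
    records = adh.measure_transient_adhesion(
        stack, int(p.get("diameter", 7)),
        min_mass=float(p.get("min_mass", 0.0)),
        max_intensity=float(p.get("max_intensity", np.inf)),
        min_frames=int(p.get("min_frames", 3)),
        fps=stack.require_fps(),
        search_range_px=float(p.get("search_range", 5.0)),
        memory_frames=int(p.get("memory", 0)),
        invert=bool(p.get("invert", False)),
    )
    df = adh.records_to_frame(records)
    outputs = {"records": records, "table": df}
    if records:
        outputs["files"] = export_tabular(df, out / "cells.csv")
        outputs["annotated"] = annotate_media(stack, records, out / "annotated")
        outputs["graphs"] = make_graphs(df, "histogram", out / "graphs",
                                        columns=["adhesion_time_s"])
    return outputs


def _occlusion_common(cfg: RunConfig):
    p = cfg.params
    stack = _load_inputs(cfg)
    thresholds = {}
    for plane, key in ((0, "threshold_r"), (1, "threshold_g"), (2, "threshold_b")):
        if p.get(key) is not None:
            thresholds[plane] = float(p[key])
    if not thresholds:
        thresholds = {0: float(p.get("threshold", 0.0))}
    masks = acc.binarize_channels(stack, thresholds)
    times = p.get("timestamps")
    if times is None:
        dt = float(p.get("minutes_per_frame", 1.0))
        times = [t * dt for t in range(stack.n_frames)]
    elif isinstance(times, str):
        times = [float(s) for s in times.split(",")]
    return stack, masks, list(times)


def _wf_occlusion(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params
    variant = p.get("variant", "device")
    stack, masks, times = _occlusion_common(cfg)
    um = stack.um_per_px or 1.0
    if variant == "surface":
        region = np.ones((stack.height, stack.width), dtype=bool)
        device = acc.DeviceMap(mask=region)
    else:
        device = acc.build_device_map(masks, map_threshold=int(p.get("map_threshold", 1)))
        device = acc.detect_microchannels(device)
    series = acc.compute_occlusion_accumulation(masks, device, times, um_per_px=um)
    outputs = {"device_map": device, "series": series, "table": series.table}
    files = export_tabular(series.table, out / "occlusion.csv")
    if variant == "microchannel" and device.channels:
        spatial_frames = []
        for ch in device.channels:
            for plane, m in masks.items():
                last = np.asarray(m)[-1]
                sp = acc.spatial_occlusion(last, ch)
                sp.insert(0, "channel_id", ch.channel_id)
                sp.insert(1, "plane", plane)
                spatial_frames.append(sp)
        spatial = pd.concat(spatial_frames, ignore_index=True)
        files += export_tabular(spatial, out / "spatial_occlusion.csv")
        outputs["spatial"] = spatial
    Image.fromarray((device.mask * 255).astype(np.uint8)).save(out / "device_map.png")
    graphs = make_graphs(
        series.table[["time_min", "plane", "occlusion_pct"]],
        "timecourse", out / "graphs",
    )
    outputs.update({"files": files, "graphs": graphs})
    return outputs


def _wf_cluster(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params
    features = p.get("features")
    if isinstance(features, str):
        features = [s.strip() for s in features.split(",")]
    matrix = clu.assemble_feature_matrix(
        cfg.inputs, features, standardize=not bool(p.get("no_standardize", False)),
    )
    k_max = int(p.get("k_max", 8))
    inertia, suggested_k = clu.scree_analysis(matrix, k_max, seed=cfg.seed)
    k = int(p.get("k", suggested_k))
    result = clu.cluster_kmeans(matrix, max(k, 2), seed=cfg.seed)
    labeled = pd.DataFrame(matrix.points, columns=matrix.feature_names)
    labeled.insert(0, "sample", matrix.sample_labels)
    labeled["cluster"] = result.labels
    files = export_tabular(labeled, out / "labeled_points.csv")
    result.frequency_table.to_csv(out / "frequency_table.csv")
    pd.DataFrame({"k": np.arange(1, k_max + 1), "inertia": inertia}).to_csv(
        out / "scree.csv", index=False
    )
    corr = labeled[matrix.feature_names].corr()
    corr.to_csv(out / "feature_correlation.csv")
    return {"matrix": matrix, "result": result, "suggested_k": suggested_k,
            "inertia": inertia, "table": labeled, "files": files}


def _wf_fixtures(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params
    kind = p.get("kind", "moving_cells")
    if kind == "moving_cells":
        stack, truth = fix.render_moving_cells(
            n_cells=int(p.get("n_cells", 10)),
            velocity_um_s=float(p.get("velocity", 125.0)),
            noise_sd=float(p.get("noise_sd", 0.0)),
            n_frames=int(p.get("n_frames", 50)),
            fps=float(p.get("fps", 25.0)),
            um_per_px=float(p.get("um_per_px", 1.0)),
            seed=cfg.seed,
        )
    elif kind == "suspension":
        vmax = float(p.get("vmax", 300.0))
        h_um = None

        def parabola(y_um, vmax=vmax):
            nonlocal h_um
            return vmax * (1 - (2 * y_um / h_um) ** 2)

        shape = (int(p.get("height", 96)), int(p.get("width", 256)))
        h_um = shape[0] * float(p.get("um_per_px", 1.0))
        stack, truth = fix.render_suspension_flow(
            parabola, n_frames=int(p.get("n_frames", 20)),
            fps=float(p.get("fps", 100.0)), um_per_px=float(p.get("um_per_px", 1.0)),
            frame_shape=shape, seed=cfg.seed,
        )
    elif kind == "occlusion":
        stencil, channels = fix.make_comb_stencil(n_channels=int(p.get("n_channels", 8)))
        schedule = [float(s) for s in str(p.get("schedule", "0,0.25,0.5")).split(",")]
        stack, truth = fix.render_occlusion_series(stencil, schedule, seed=cfg.seed,
                                                   channels=channels)
    else:
        raise InputError(f"unknown fixture kind {kind!r}")
    fix.save_fixture(stack, truth, out / "fixture")
    return {"stack": stack, "truth": truth, "table": truth.objects}


WORKFLOWS = {
    "track": _wf_track,
    "profile": _wf_profile,
    "adhesion_brightfield": _wf_adhesion_brightfield,
    "adhesion_fluorescent": _wf_adhesion_fluorescent,
    "adhesion_transient": _wf_adhesion_transient,
    "occlusion": _wf_occlusion,
    "cluster": _wf_cluster,
    "fixtures": _wf_fixtures,
}


def _log_run(cfg: RunConfig, out: Path) -> None:
    import importlib.metadata as md

    lines = [f"workflow: {cfg.workflow}", f"seed: {cfg.seed}",
             f"inputs: {cfg.inputs}", "parameters:"]
    lines += [f"  {k}: {v}" for k, v in sorted(cfg.params.items())]
    lines.append("versions:")
    for pkg in ("numpy", "scipy", "pandas", "scikit-image", "scikit-learn"):
        try:
            lines.append(f"  {pkg}: {md.version(pkg)}")
        except md.PackageNotFoundError:
            pass
    lines.append(f"  python: {sys.version.split()[0]}")
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def run_workflow(config: RunConfig) -> dict:
    """Execute a named pipeline end-to-end and write all outputs.

    The effective parameters and library versions are logged to
    ``run_log.txt`` in the output directory.  Unknown workflow names fail
    before any computation.
    """
    if config.workflow not in WORKFLOWS:
        raise InputError(
            f"unknown workflow {config.workflow!r}; available: {sorted(WORKFLOWS)}"
        )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log_run(config, out)
    return WORKFLOWS[config.workflow](config, out)


def parameter_sweep(config: RunConfig, param_grid: dict[str, list]) -> pd.DataFrame:
    """Re-run a workflow over a parameter grid; tabulate summary outputs.

    Returns a long-format table: one row per (grid point, summary quantity),
    with the swept parameter values as columns.  Summaries are the record
    count plus the mean of each numeric column of the workflow's main table.
    """
    import itertools

    for key in param_grid:
        if key == "seed":
            continue
        if key not in config.params:
            raise InputError(
                f"sweep parameter {key!r} is not set in the base config; "
                "set a default value first so its domain is explicit"
            )
    names = list(param_grid)
    rows = []
    for combo in itertools.product(*(param_grid[k] for k in names)):
        cfg = RunConfig(
            workflow=config.workflow,
            inputs=list(config.inputs),
            params={**config.params},
            output_dir=str(Path(config.output_dir) /
                           ("sweep_" + "_".join(f"{k}{v}" for k, v in zip(names, combo)))),
            seed=config.seed,
        )
        for k, v in zip(names, combo):
            if k == "seed":
                cfg.seed = int(v)
            else:
                cfg.params[k] = v
        result = run_workflow(cfg)
        table = result.get("table")
        summaries = {"n_records": 0 if table is None else int(len(table))}
        if table is not None and len(table):
            for col in table.select_dtypes(include=[np.number]).columns:
                summaries[f"mean_{col}"] = float(table[col].mean())
        for qty, val in summaries.items():
            row = dict(zip(names, combo))
            row.update({"quantity": qty, "value": val})
            rows.append(row)
    return pd.DataFrame(rows)
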