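"""Adhered-cell quantification: morphology, functionality, protrusions, dwell time.

Four workflows share the :class:`CellRecord` row type:

* brightfield morphology — cells found as Gaussian-like particles; the
  gyration radius doubles as an effective cell radius, and the moment
  eccentricity is reported as "circularity" (0 = circular);
* fluorescence morphology/functionality — a user-thresholded membrane channel
  is segmented into 8-connected regions; per-region texture (intensity s.d.),
  summed secondary-stain signal, and nuclear lobe counts (peak finding) are
  added;
* protrusion counting — Harris corners on the binarized region's convex
  circumference count filopodia-like extensions and report their lengths from
  the centroid;
* transient adhesion — particles linked through a video give the time each
  flowing cell remains detectable at the surface.

Thresholding convention: a pixel strictly greater than the threshold is
signal.  Intensities are arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull
from skimage.feature import corner_harris, corner_peaks, peak_local_max
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .io_media import FrameStack, InputError
from .tracking import detect_particles, detect_stack, link_and_filter

__all__ = [
    "CellRecord",
    "records_to_frame",
    "measure_brightfield_cells",
    "measure_fluorescent_cells",
    "count_protrusions",
    "measure_transient_adhesion",
]


@dataclass
class CellRecord:
    """One indexed cell/event; only the fields the workflow measures are set."""

    cell_id: int
    x: float
    y: float
    area_px: float | None = None
    area_um2: float | None = None
    circularity: float | None = None      # moment eccentricity, 0 = circle
    radius_um: float | None = None
    membrane_texture: float | None = None  # s.d. of membrane intensity, a.u.
    secondary_sum: float | None = None
    lobe_count: int | None = None
    protrusion_count: int | None = None
    protrusion_dist_min_um: float | None = None
    protrusion_dist_mean_um: float | None = None
    protrusion_dist_max_um: float | None = None
    adhesion_time_s: float | None = None
    path_distance_px: float | None = None
    mean_mass: float | None = None
    extra: dict = field(default_factory=dict)


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Tabulate records, dropping all-empty columns."""
    rows = []
    for r in records:
        d = {k: v for k, v in r.__dict__.items() if k != "extra"}
        d.update(r.extra)
        rows.append(d)
    df = pd.DataFrame(rows)
    return df.dropna(axis=1, how="all")


# ---------------------------------------------------------------------------
# Brightfield morphology


def measure_brightfield_cells(
    image: np.ndarray,
    expected_diameter_px: int,
    min_area_um2: float = 0.0,
    max_area_um2: float = np.inf,
    invert: bool = False,
    um_per_px: float = 1.0,
    min_mass: float = 0.0,
) -> tuple[list[CellRecord], float]:
    """Locate adhered cells in one brightfield image and measure morphology.

    The effective radius is the uniform-disk equivalent √2·Rg (a disk of
    radius r has gyration radius r/√2), so the reported area π·r_eff² is
    exact for flat disk-like cells; cells outside [min_area, max_area] are
    excluded.  Returns the records and the field density in cells/mm².
    """
    if um_per_px <= 0:
        raise InputError("um_per_px must be > 0")
    image = np.asarray(image, dtype=float)
    dets = detect_particles(image, expected_diameter_px, min_mass=min_mass, invert=invert)
    records = []
    for d in dets:
        radius_um = math.sqrt(2.0) * d.size * um_per_px
        area = math.pi * radius_um**2
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        records.append(
            CellRecord(
                cell_id=0, x=d.x, y=d.y,
                area_px=area / um_per_px**2, area_um2=area,
                circularity=d.eccentricity, radius_um=radius_um,
                mean_mass=d.mass,
            )
        )
    records.sort(key=lambda r: (r.y, r.x))
    for i, r in enumerate(records):
        r.cell_id = i
    field_mm2 = image.shape[0] * image.shape[1] * um_per_px**2 / 1e6
    density = len(records) / field_mm2
    return records, density


# ---------------------------------------------------------------------------
# Fluorescence morphology / functionality


def measure_fluorescent_cells(
    stack: FrameStack | np.ndarray,
    membrane_channel: int,
    membrane_threshold: float,
    secondary_channel: int | None = None,
    secondary_threshold: float = 0.0,
    lobe_channel: int | None = None,
    lobe_threshold: float = 0.0,
    min_peak_sep_px: int = 8,
    min_area_um2: float = 0.0,
    max_area_um2: float = np.inf,
    um_per_px: float = 1.0,
) -> list[CellRecord]:
    """Segment fluorescently stained cells and measure per-region features.

    The membrane channel is binarized (pixel > threshold = signal) and
    8-connected regions are labeled.  Per region: area, centroid, moment
    eccentricity, equivalent-disk radius, texture (s.d. of membrane intensity
    over region pixels), summed above-threshold secondary-stain intensity,
    and the number of lobe-channel local maxima separated by at least
    ``min_peak_sep_px`` and brighter than ``lobe_threshold``.
    """
    if isinstance(stack, FrameStack):
        if stack.n_frames != 1:
            raise InputError("fluorescence morphology operates on a single image")
        frame = stack.frames[0]
        if um_per_px == 1.0 and stack.um_per_px is not None:
            um_per_px = stack.um_per_px
    else:
        frame = np.asarray(stack)
    if frame.ndim != 3:
        raise InputError("expected a multi-plane (H, W, C) image")
    n_planes = frame.shape[-1]

    def _plane(idx, name):
        if idx is None:
            return None
        if not 0 <= idx < n_planes:
            raise InputError(f"{name} channel {idx} not present (image has {n_planes} planes)")
        return frame[..., idx].astype(float)

    membrane = _plane(membrane_channel, "membrane")
    secondary = _plane(secondary_channel, "secondary")
    lobes = _plane(lobe_channel, "lobe")

    mask = membrane > membrane_threshold
    labels = sk_label(mask, connectivity=2)
    records = []
    for prop in regionprops(labels, intensity_image=membrane):
        area_px = float(prop.area)
        area_um2 = area_px * um_per_px**2
        if not (min_area_um2 <= area_um2 <= max_area_um2):
            continue
        region_mask = labels == prop.label
        texture = float(membrane[region_mask].std())
        sec_sum = None
        if secondary is not None:
            sec = secondary[region_mask]
            sec_sum = float(sec[sec > secondary_threshold].sum())
        lobe_count = None
        if lobes is not None:
            # candidate maxima first, then Euclidean spacing (peak_local_max's
            # min_distance is a square footprint, which over-suppresses
            # diagonal neighbors)
            peaks = peak_local_max(
                lobes,
                min_distance=1,
                threshold_abs=lobe_threshold if lobe_threshold > 0 else None,
                labels=region_mask.astype(int),
                exclude_border=False,
            )
            lobe_count = len(_enforce_spacing(peaks, lobes, float(min_peak_sep_px)))
        cy, cx = prop.centroid
        records.append(
            CellRecord(
                cell_id=0, x=float(cx), y=float(cy),
                area_px=area_px, area_um2=area_um2,
                circularity=float(prop.eccentricity),
                radius_um=math.sqrt(area_px / math.pi) * um_per_px,
                membrane_texture=texture,
                secondary_sum=sec_sum,
                lobe_count=lobe_count,
                extra={"label": int(prop.label)},
            )
        )
    records.sort(key=lambda r: (r.y, r.x))
    for i, r in enumerate(records):
        r.cell_id = i
    return records


def _enforce_spacing(peaks: np.ndarray, intensity: np.ndarray,
                     min_sep: float) -> np.ndarray:
    """Greedy Euclidean spacing: keep strongest peaks at pairwise >= min_sep."""
    if len(peaks) == 0:
        return peaks
    vals = intensity[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(vals, kind="stable")[::-1]
    kept: list[np.ndarray] = []
    for i in order:
        p = peaks[i]
        if all(np.hypot(*(p - q)) >= min_sep for q in kept):
            kept.append(p)
    return np.array(kept)


# ---------------------------------------------------------------------------
# Protrusion counting

# Harris response on a unit-height smoothed mask is scale-free; responses on a
# smooth (circular) boundary stay well below this floor while sharp tips
# exceed it by orders of magnitude.
_MIN_CORNER_RESPONSE = 1e-3


def _hull_vertex_distance(points: np.ndarray, hull_pts: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest convex-hull vertex.

    Protrusion tips coincide with hull vertices while concave notches lie
    strictly inside the hull, so vertex proximity separates the two even when
    the Harris response peaks a few pixels inside a sharp tip.
    """
    hull = ConvexHull(hull_pts)
    verts = hull_pts[hull.vertices]
    diff = points[:, None, :] - verts[None, :, :]
    return np.sqrt((diff**2).sum(-1)).min(axis=1)


def count_protrusions(
    region_mask: np.ndarray,
    corner_sharpness: float = 0.15,
    min_separation_px: int = 6,
    um_per_px: float = 1.0,
    membrane_image: np.ndarray | None = None,
) -> tuple[int, float, float, float]:
    """Count filopodia-like protrusions of one binarized cell region.

    A Harris corner response (3-px local window, sensitivity k = 0.04) is
    computed on the lightly smoothed binary region.  Candidates must reach
    ``corner_sharpness`` × the maximum response, sit on the convex
    circumference of the region, and be separated by ``min_separation_px``
    (closer candidates merge, keeping the strongest).  Each retained corner is
    snapped to the locally farthest boundary pixel — the protrusion end — and
    centroid-to-end distances (µm) are summarized.

    Returns ``(count, dist_min, dist_mean, dist_max)``; distances are NaN when
    no protrusion is found.
    """
    mask = np.asarray(region_mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if len(ys) < 4:
        return 0, float("nan"), float("nan"), float("nan")
    cx, cy = float(xs.mean()), float(ys.mean())

    smoothed = gaussian_filter(mask.astype(float), 1.0)
    response = corner_harris(smoothed, method="k", k=0.04, sigma=1.0)
    if response.max() < _MIN_CORNER_RESPONSE:
        return 0, float("nan"), float("nan"), float("nan")
    # all candidate corners above the absolute floor; concave notches respond
    # too, so the sharpness fraction is applied after restricting to the
    # convex circumference
    peaks = corner_peaks(
        response, min_distance=2, threshold_abs=_MIN_CORNER_RESPONSE, threshold_rel=0.0
    )
    if len(peaks) == 0:
        return 0, float("nan"), float("nan"), float("nan")

    # keep only corners on the convex circumference (tips, not notches)
    boundary = mask & ~(
        np.roll(mask, 1, 0) & np.roll(mask, -1, 0) & np.roll(mask, 1, 1) & np.roll(mask, -1, 1)
    )
    bys, bxs = np.nonzero(boundary)
    hull_pts = np.column_stack([bxs, bys]).astype(float)
    pts_xy = np.column_stack([peaks[:, 1], peaks[:, 0]]).astype(float)
    try:
        dist = _hull_vertex_distance(pts_xy, hull_pts)
    except Exception:
        dist = np.zeros(len(pts_xy))
    peaks = peaks[dist <= 5.0]
    if len(peaks) == 0:
        return 0, float("nan"), float("nan"), float("nan")

    # sharpness threshold relative to the strongest convex-boundary corner,
    # then merge candidates closer than the separation (strongest wins)
    vals = response[peaks[:, 0], peaks[:, 1]]
    peaks = peaks[vals >= corner_sharpness * vals.max()]
    peaks = _enforce_spacing(peaks, response, float(min_separation_px))
    pts = np.column_stack([peaks[:, 1], peaks[:, 0]]).astype(float)
    if len(pts) == 0:
        return 0, float("nan"), float("nan"), float("nan")

    # snap each corner to the farthest-from-centroid boundary pixel nearby
    bpts = np.column_stack([bxs, bys]).astype(float)
    dists = []
    for px, py in pts:
        near = np.hypot(bpts[:, 0] - px, bpts[:, 1] - py) <= 5.0
        cand = bpts[near] if near.any() else np.array([[px, py]])
        r = np.hypot(cand[:, 0] - cx, cand[:, 1] - cy)
        dists.append(float(r.max()) * um_per_px)
    dists = np.asarray(dists)
    return len(pts), float(dists.min()), float(dists.mean()), float(dists.max())


# ---------------------------------------------------------------------------
# Transient adhesion under flow


def measure_transient_adhesion(
    stack: FrameStack,
    expected_diameter_px: int,
    min_mass: float = 0.0,
    max_intensity: float = np.inf,
    min_frames: int = 3,
    fps: float | None = None,
    search_range_px: float = 5.0,
    memory_frames: int = 0,
    invert: bool = False,
) -> list[CellRecord]:
    """Time each transiently adhering cell remains detectable at the surface.

    Cells are detected per frame, detections brighter than ``max_intensity``
    (integrated mass) are discarded as debris, and the rest are linked into
    trajectories; tracks present in fewer than ``min_frames`` frames are
    treated as noise.  The adhesion time is the inclusive frame span over the
    imaging rate, so every reported time is a multiple of 1/fps.  The total
    path distance is also reported, so a transit-time reading of the same
    trajectories stays recoverable.
    """
    fps = fps if fps is not None else stack.fps
    if fps is None or fps <= 0:
        raise InputError("transient adhesion needs a positive fps calibration")
    dets = detect_stack(stack, expected_diameter_px, min_mass=min_mass, invert=invert)
    dets = [[d for d in frame_dets if d.mass <= max_intensity] for frame_dets in dets]
    trajs = link_and_filter(
        dets, search_range_px=search_range_px, memory_frames=memory_frames,
        min_frames=max(min_frames, 2),
    )
    records = []
    for t in trajs:
        first, last = t.detections[0].frame, t.detections[-1].frame
        xs = [d.x for d in t.detections]
        ys = [d.y for d in t.detections]
        records.append(
            CellRecord(
                cell_id=t.cell_id,
                x=float(np.mean(xs)), y=float(np.mean(ys)),
                adhesion_time_s=(last - first + 1) / fps,
                path_distance_px=t.path_distance,
                mean_mass=t.mean_mass,
                radius_um=(t.mean_size_px * stack.um_per_px) if stack.um_per_px else None,
                extra={"first_frame": first, "last_frame": last,
                       "n_frames_present": t.n_frames_present},
            )
        )
    records.sort(key=lambda r: (r.y, r.x))
    for i, r in enumerate(records):
        r.cell_id = i
    return records
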