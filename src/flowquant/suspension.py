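"""Cell-suspension velocimetry: corner features + pyramidal optical flow.

Texture in a flowing suspension (pixel-intensity patterns formed by groups of
cells) is detected with Shi-Tomasi corner detection and followed frame to
frame with a pyramidal Kanade–Lucas–Tomasi least-squares patch alignment.
Feature velocities yield per-frame mean/max time courses and, binned by each
feature's initial distance from the channel center, a spatial velocity
profile whose bluntness (wall-to-maximum velocity ratio) is a rheology
readout.

The ``window_size_px`` parameter is the maximum distance a feature may travel
between consecutive frames: recovered steps larger than the window are marked
invalid and the feature is dropped from that point, so flows faster than the
window under-sample by design — choose a window larger than the expected
per-frame displacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import corner_peaks, corner_shi_tomasi
from skimage.transform import pyramid_reduce

from .io_media import FrameStack, InputError

__all__ = [
    "FlowFeature",
    "VelocityProfile",
    "detect_and_track_flow",
    "summarize_timecourse",
    "build_velocity_profile",
]


@dataclass
class FlowFeature:
    """One tracked texture feature.

    ``positions[k]`` is the (x, y) location at frame ``start_frame + k``;
    ``valid[k]`` states whether step k -> k+1 was tracked successfully and
    stayed within the window.
    """

    feature_id: int
    start_frame: int
    y0_px: float          # signed distance from channel center at seeding, px
    positions: list = field(default_factory=list)   # [(x, y), ...]
    valid: list = field(default_factory=list)       # per-step flags

    @property
    def step_displacements_px(self) -> np.ndarray:
        p = np.asarray(self.positions)
        if len(p) < 2:
            return np.empty(0)
        return np.hypot(*np.diff(p, axis=0).T)

    def n_valid_steps(self) -> int:
        return int(np.sum(self.valid))


@dataclass
class VelocityProfile:
    """Binned spatial velocity profile across the channel height."""

    table: pd.DataFrame          # bin_center_um, mean_velocity_um_s, n_features
    bluntness_ratio: float       # mean wall velocity / frame maximum velocity
    frame_max_velocity_um_s: float


# ---------------------------------------------------------------------------
# Pyramidal Lucas–Kanade


def _sample(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Bilinear sampling at continuous coordinates (assumed in-bounds)."""
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    h, w = img.shape
    y0 = np.clip(y0, 0, h - 2)
    x0 = np.clip(x0, 0, w - 2)
    fy = ys - y0
    fx = xs - x0
    return (
        img[y0, x0] * (1 - fy) * (1 - fx)
        + img[y0, x0 + 1] * (1 - fy) * fx
        + img[y0 + 1, x0] * fy * (1 - fx)
        + img[y0 + 1, x0 + 1] * fy * fx
    )


class _LKTracker:
    """3-level pyramidal Lucas–Kanade step tracker for a frame pair."""

    def __init__(self, window_size_px: int, levels: int = 3,
                 max_iter: int = 12, eps: float = 0.01):
        if window_size_px < 3:
            raise InputError("window_size_px must be >= 3")
        self.window = int(window_size_px) | 1  # odd
        self.levels = levels
        self.max_iter = max_iter
        self.eps = eps
        half = self.window // 2
        self._oy, self._ox = np.mgrid[-half:half + 1, -half:half + 1].astype(float)

    def _pyramids(self, img: np.ndarray):
        pyr = [img.astype(np.float64)]
        for _ in range(self.levels - 1):
            if min(pyr[-1].shape) < 2 * self.window:
                break
            pyr.append(pyr[-1] if min(pyr[-1].shape) <= 4 else
                       pyramid_reduce(pyr[-1], downscale=2, preserve_range=True))
        grads = [np.gradient(p) for p in pyr]  # (gy, gx) per level
        return pyr, grads

    def track(self, img0: np.ndarray, img1: np.ndarray,
              points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Track ``points`` (N, 2 as x, y) from img0 to img1.

        Returns (new_points, status).  status is False where alignment failed
        (ill-conditioned texture, divergence, or leaving the frame).
        """
        pyr0, grads0 = self._pyramids(img0)
        pyr1, _ = self._pyramids(img1)
        n_levels = min(len(pyr0), len(pyr1))
        half = self.window // 2
        new_pts = np.array(points, dtype=float)
        status = np.ones(len(points), dtype=bool)

        for i, (x, y) in enumerate(np.atleast_2d(points)):
            g = np.zeros(2)  # accumulated guess, finest-level-of-current px
            ok = True
            for L in reversed(range(n_levels)):
                scale = 2.0**L
                px_, py_ = x / scale, y / scale
                h, w = pyr0[L].shape
                # patches may overhang the frame (sampling clamps at the edge);
                # only a center outside the level's bounds is fatal
                if not (0 <= px_ <= w - 1 and 0 <= py_ <= h - 1):
                    if L == 0:
                        ok = False
                    g *= 2.0
                    continue
                ys = py_ + self._oy
                xs = px_ + self._ox
                patch0 = _sample(pyr0[L], ys, xs)
                gy = _sample(grads0[L][0], ys, xs)
                gx = _sample(grads0[L][1], ys, xs)
                gxx = float((gx * gx).sum())
                gyy = float((gy * gy).sum())
                gxy = float((gx * gy).sum())
                det = gxx * gyy - gxy * gxy
                tr = gxx + gyy
                min_eig = tr / 2 - np.sqrt(max(tr * tr / 4 - det, 0.0))
                if min_eig < 1e-4 or det <= 0:
                    ok = False
                    break
                v = g.copy()
                for _ in range(self.max_iter):
                    tx = px_ + v[0]
                    ty = py_ + v[1]
                    if not (0 <= tx <= w - 1 and 0 <= ty <= h - 1):
                        ok = False
                        break
                    patch1 = _sample(pyr1[L], ty + self._oy, tx + self._ox)
                    it = patch0 - patch1
                    bx = float((it * gx).sum())
                    by = float((it * gy).sum())
                    dx = (gyy * bx - gxy * by) / det
                    dy = (gxx * by - gxy * bx) / det
                    v += (dx, dy)
                    if dx * dx + dy * dy < self.eps**2:
                        break
                if not ok:
                    break
                g = 2.0 * v if L > 0 else v
            if not ok:
                status[i] = False
                continue
            nx, ny = x + g[0], y + g[1]
            h0, w0 = img1.shape
            if not (0 <= nx <= w0 - 1 and 0 <= ny <= h0 - 1):
                status[i] = False
                continue
            new_pts[i] = (nx, ny)
        return new_pts, status


# ---------------------------------------------------------------------------
# Feature detection + tracking over a video


def detect_and_track_flow(
    stack: FrameStack,
    max_features: int = 200,
    quality: float = 0.05,
    min_corner_sep_px: int = 7,
    window_size_px: int = 15,
    reseed_every: int = 10,
    center_row: float | None = None,
) -> list[FlowFeature]:
    """Seed Shi-Tomasi corners and track them with pyramidal optical flow.

    Corners are detected on frame 0 and re-seeded every ``reseed_every``
    frames (skipping locations already occupied by live features), so fast
    flow does not deplete the tracked set.  A feature's track ends at the
    first failed or over-window step; subsequent steps are not reported.
    """
    if stack.n_frames < 2:
        raise InputError("optical-flow tracking needs at least 2 frames")
    gray = stack.gray().astype(np.float64)
    n_frames = gray.shape[0]
    center = (gray.shape[1] - 1) / 2.0 if center_row is None else center_row
    tracker = _LKTracker(window_size_px)

    features: list[FlowFeature] = []
    live: list[FlowFeature] = []
    next_id = 0
    for t in range(n_frames - 1):
        if t % reseed_every == 0:
            # a featureless frame has no spatial intensity differences to
            # seed from (border responses on constant frames are artifacts)
            if float(gray[t].std()) <= 1e-9 * max(float(gray[t].max()), 1.0):
                if t == 0:
                    warnings.warn("no trackable texture found on the first frame")
                continue
            response = corner_shi_tomasi(gray[t])
            peaks = corner_peaks(
                response,
                min_distance=int(min_corner_sep_px),
                threshold_rel=quality,
                num_peaks=max_features,
                exclude_border=1,  # keep wall-adjacent rows sampled
            )
            occupied = np.array([f.positions[-1] for f in live]) if live else np.empty((0, 2))
            for py, px in peaks:
                if len(live) >= max_features:
                    break
                if len(occupied) and np.min(
                    np.hypot(occupied[:, 0] - px, occupied[:, 1] - py)
                ) < min_corner_sep_px:
                    continue
                f = FlowFeature(feature_id=next_id, start_frame=t,
                                y0_px=float(py - center), positions=[(float(px), float(py))])
                next_id += 1
                live.append(f)
                features.append(f)
            if t == 0 and not live:
                warnings.warn("no trackable texture found on the first frame")

        if not live:
            continue
        pts = np.array([f.positions[-1] for f in live])
        new_pts, status = tracker.track(gray[t], gray[t + 1], pts)
        still_live = []
        for f, (nx, ny), ok in zip(live, new_pts, status):
            step = float(np.hypot(nx - f.positions[-1][0], ny - f.positions[-1][1]))
            if ok and step <= window_size_px:
                f.positions.append((float(nx), float(ny)))
                f.valid.append(True)
                still_live.append(f)
            else:
                # lost, or moved farther than the window allows: invalid step
                f.positions.append((float(nx), float(ny)))
                f.valid.append(False)
        live = still_live
    return features


def summarize_timecourse(
    features: list[FlowFeature],
    fps: float,
    um_per_px: float,
    min_step_px: float = 0.0,
) -> pd.DataFrame:
    """Per-frame mean and maximum feature velocity in µm/s.

    A step from frame t to t+1 is attributed to frame t.  Steps shorter than
    ``min_step_px`` are excluded as noise.  Frames with no valid feature are
    absent from the table (missing, not zero).
    """
    if not fps or fps <= 0 or not um_per_px or um_per_px <= 0:
        raise InputError("summarize_timecourse requires positive fps and um_per_px")
    scale = um_per_px * fps
    rows = []
    for f in features:
        p = np.asarray(f.positions)
        for k, ok in enumerate(f.valid):
            if not ok:
                continue
            step = float(np.hypot(*(p[k + 1] - p[k])))
            if step < min_step_px:
                continue
            rows.append({"frame": f.start_frame + k, "feature_id": f.feature_id,
                         "step_px": step, "velocity_um_s": step * scale})
    if not rows:
        return pd.DataFrame(columns=["frame", "mean_velocity_um_s",
                                     "max_velocity_um_s", "n_features"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("frame")["velocity_um_s"]
        .agg(mean_velocity_um_s="mean", max_velocity_um_s="max", n_features="count")
        .reset_index()
    )
    return out


def build_velocity_profile(
    features: list[FlowFeature],
    bin_width_um: float,
    fps: float,
    um_per_px: float,
    channel_span: tuple[float, float] | None = None,
    center_row: float | None = None,
    min_valid_steps: int = 1,
) -> VelocityProfile:
    """Bin feature velocities by initial signed distance from channel center.

    Each feature contributes its mean valid-step velocity to the bin holding
    its seeding position ``y0``.  The bluntness ratio is the mean of the two
    outermost non-empty bins' velocities divided by the overall frame maximum
    velocity — near 1 for plug flow, small for a parabolic profile.
    """
    if bin_width_um <= 0:
        raise InputError("bin_width_um must be > 0")
    scale = um_per_px * fps
    ys, vs = [], []
    for f in features:
        if f.n_valid_steps() < min_valid_steps:
            continue
        p = np.asarray(f.positions)
        steps = np.hypot(*np.diff(p, axis=0).T)
        ok = np.asarray(f.valid, dtype=bool)
        v = float(np.mean(steps[ok])) * scale
        y0 = f.y0_px
        if center_row is not None:
            y0 = (f.positions[0][1] - center_row)
        ys.append(y0 * um_per_px)
        vs.append(v)
    if not ys:
        raise InputError("no features with valid steps: velocity profile is empty")
    ys = np.asarray(ys)
    vs = np.asarray(vs)

    if channel_span is not None:
        y_top, y_bottom = channel_span
        c = center_row if center_row is not None else (y_top + y_bottom) / 2.0
        lo = (y_top - c) * um_per_px
        hi = (y_bottom - c) * um_per_px
    else:
        lo, hi = float(ys.min()), float(ys.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width_um)))
    edges = lo + bin_width_um * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(ys, edges) - 1, 0, n_bins - 1)

    centers = (edges[:-1] + edges[1:]) / 2
    mean_v = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            mean_v[b] = float(vs[sel].mean())
    table = pd.DataFrame(
        {"bin_center_um": centers, "mean_velocity_um_s": mean_v, "n_features": counts}
    )

    nonempty = np.nonzero(counts)[0]
    wall_v = float(np.mean([mean_v[nonempty[0]], mean_v[nonempty[-1]]]))

    # frame maximum velocity: per-frame max over valid steps, aggregated as a
    # median across frames so a single mismatched feature cannot inflate it
    frame_max: dict[int, float] = {}
    for f in features:
        p = np.asarray(f.positions)
        for k, ok in enumerate(f.valid):
            if not ok:
                continue
            v = float(np.hypot(*(p[k + 1] - p[k]))) * scale
            fr = f.start_frame + k
            frame_max[fr] = max(frame_max.get(fr, 0.0), v)
    vmax = float(np.median(list(frame_max.values()))) if frame_max else float(vs.max())
    return VelocityProfile(table=table, bluntness_ratio=wall_v / vmax,
                           frame_max_velocity_um_s=vmax)
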