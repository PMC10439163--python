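"""Single-cell detection, trajectory linking, and velocimetry.

Cells are modelled as compact particles with a 2-D Gaussian-like brightness
distribution.  Detection follows the classic centroid-finding recipe:

1. spatial bandpass — short-scale Gaussian smoothing minus a boxcar average at
   the expected particle diameter, clipped at zero;
2. candidate peaks — grayscale-dilation local maxima, brighter-peak-wins
   suppression within one diameter;
3. sub-pixel refinement — iterative intensity-weighted centroid inside a
   circular window, re-centering while the offset exceeds half a pixel.

Each detection carries its integrated brightness ("mass"), radius of gyration
and moment eccentricity, which downstream filters use to reject debris (low
mass / low intensity) and aggregates (large gyration diameter).

Linking solves, frame by frame, a linear assignment problem that minimises the
total squared displacement over all candidate links within the search range;
tracks missing for up to ``memory_frames`` frames may be bridged.  The result
is deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .io_media import FrameStack, InputError

__all__ = [
    "Detection",
    "Trajectory",
    "detect_particles",
    "detect_stack",
    "link_and_filter",
    "compute_cell_velocity",
    "measure_cell_fluorescence",
]


@dataclass
class Detection:
    """One sub-pixel particle detection in one frame."""

    frame: int
    x: float
    y: float
    mass: float          # integrated bandpassed intensity, a.u.
    size: float          # radius of gyration, px
    eccentricity: float  # 0 = circular
    peak_intensity: float  # raw image intensity at the centroid pixel


@dataclass
class Trajectory:
    """A linked cell track with derived kinematic summaries."""

    cell_id: int
    detections: list[Detection] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def n_frames_present(self) -> int:
        return len(self.detections)

    @property
    def frame_span(self) -> int:
        return self.detections[-1].frame - self.detections[0].frame

    @property
    def path_distance(self) -> float:
        """Total inter-detection displacement, px."""
        xs = np.array([d.x for d in self.detections])
        ys = np.array([d.y for d in self.detections])
        return float(np.hypot(np.diff(xs), np.diff(ys)).sum())

    @property
    def net_displacement(self) -> float:
        a, b = self.detections[0], self.detections[-1]
        return float(math.hypot(b.x - a.x, b.y - a.y))

    @property
    def mean_mass(self) -> float:
        return float(np.mean([d.mass for d in self.detections]))

    @property
    def mean_size_px(self) -> float:
        return float(np.mean([d.size for d in self.detections]))

    @property
    def mean_eccentricity(self) -> float:
        return float(np.mean([d.eccentricity for d in self.detections]))


# ---------------------------------------------------------------------------
# Detection


def _bandpass(frame: np.ndarray, diameter: int, short_sigma: float = 1.0) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(frame.astype(np.float64), short_sigma, mode="nearest")
    background = ndimage.uniform_filter(frame.astype(np.float64), diameter, mode="nearest")
    return np.clip(smoothed - background, 0.0, None)


def detect_particles(
    frame: np.ndarray,
    expected_diameter_px: int,
    min_mass: float = 0.0,
    max_diameter_px: float | None = None,
    min_intensity: float | None = None,
    invert: bool = False,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect Gaussian-like particles in one grayscale frame.

    Parameters
    ----------
    expected_diameter_px : odd int >= 3
        Approximate particle diameter; sets the bandpass scale, the local
        maxima suppression distance and the refinement window.
    min_mass : float
        Minimum integrated (bandpassed) brightness — rejects noise.
    max_diameter_px : float, optional
        Maximum gyration diameter (2·Rg) — rejects cell clusters.
    min_intensity : float, optional
        Minimum raw peak intensity at the centroid — rejects dim debris.
    invert : bool
        Invert intensities first, for dark-on-light cells (dense RBCs,
        platelets in brightfield).
    """
    if expected_diameter_px < 3 or expected_diameter_px % 2 == 0:
        raise InputError(f"expected_diameter_px must be an odd integer >= 3; "
                         f"got {expected_diameter_px}")
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise InputError(f"detect_particles needs a 2-D frame; got shape {frame.shape}")
    raw = frame.max() - frame if invert else frame
    bp = _bandpass(raw, expected_diameter_px)

    radius = expected_diameter_px // 2
    footprint = np.ones((expected_diameter_px, expected_diameter_px))
    dilated = ndimage.grey_dilation(bp, footprint=footprint, mode="nearest")
    # floor scaled to the image keeps numerical dust from the bandpass out
    floor = 1e-6 * max(float(raw.max()), 1.0)
    is_peak = (bp == dilated) & (bp > floor)
    # exclude peaks whose refinement window would leave the frame
    is_peak[:radius, :] = is_peak[-radius:, :] = False
    is_peak[:, :radius] = is_peak[:, -radius:] = False
    py, px = np.nonzero(is_peak)
    if len(py) == 0:
        return []

    # brighter-peak-wins suppression within one diameter
    order = np.argsort(bp[py, px], kind="stable")[::-1]
    kept: list[tuple[int, int]] = []
    sep2 = float(expected_diameter_px) ** 2
    for idx in order:
        y, x = int(py[idx]), int(px[idx])
        if all((y - ky) ** 2 + (x - kx) ** 2 > sep2 for ky, kx in kept):
            kept.append((y, x))

    # circular refinement mask and coordinate offsets
    rr = np.arange(-radius, radius + 1)
    oy, ox = np.meshgrid(rr, rr, indexing="ij")
    in_disk = (oy**2 + ox**2) <= radius**2

    detections: list[Detection] = []
    h, w = bp.shape
    for y0, x0 in kept:
        cy, cx = y0, x0
        dy = dx = 0.0
        for _ in range(10):
            win = bp[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1] * in_disk
            m = win.sum()
            if m <= 0:
                break
            dy = float((win * oy).sum() / m)
            dx = float((win * ox).sum() / m)
            moved = False
            if dy > 0.5 and cy + radius + 1 < h:
                cy += 1
                moved = True
            elif dy < -0.5 and cy - radius > 0:
                cy -= 1
                moved = True
            if dx > 0.5 and cx + radius + 1 < w:
                cx += 1
                moved = True
            elif dx < -0.5 and cx - radius > 0:
                cx -= 1
                moved = True
            if not moved:
                break
        win = bp[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1] * in_disk
        mass = float(win.sum())
        if mass <= 0:
            continue
        dy = float((win * oy).sum() / mass)
        dx = float((win * ox).sum() / mass)
        yc, xc = cy + dy, cx + dx
        r2 = (oy - dy) ** 2 + (ox - dx) ** 2
        rg = math.sqrt(float((win * r2).sum() / mass))
        mu20 = float((win * (ox - dx) ** 2).sum() / mass)
        mu02 = float((win * (oy - dy) ** 2).sum() / mass)
        mu11 = float((win * (ox - dx) * (oy - dy)).sum() / mass)
        common = math.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11**2, 0.0))
        l1 = (mu20 + mu02 + common) / 2
        l2 = (mu20 + mu02 - common) / 2
        ecc = math.sqrt(max(1.0 - l2 / l1, 0.0)) if l1 > 0 else 0.0
        peak = float(raw[int(round(yc)), int(round(xc))])

        if mass < min_mass:
            continue
        if min_intensity is not None and peak < min_intensity:
            continue
        if max_diameter_px is not None and 2 * rg > max_diameter_px:
            continue
        detections.append(Detection(frame=frame_index, x=xc, y=yc, mass=mass,
                                    size=rg, eccentricity=ecc, peak_intensity=peak))
    detections.sort(key=lambda d: (d.y, d.x))
    return detections


def detect_stack(stack: FrameStack, expected_diameter_px: int, **kwargs) -> list[list[Detection]]:
    """Run :func:`detect_particles` on every frame of a stack."""
    gray = stack.gray()
    return [
        detect_particles(gray[t], expected_diameter_px, frame_index=t, **kwargs)
        for t in range(stack.n_frames)
    ]


# ---------------------------------------------------------------------------
# Linking


def _assign_frame(
    track_pos: np.ndarray, det_pos: np.ndarray, search_range: float
) -> list[tuple[int, int]]:
    """Globally optimal (min total squared displacement) track↔detection pairing.

    Augmented LAP: every track and detection may also remain unmatched at cost
    ``search_range**2``; candidate links farther than the search range are
    forbidden.
    """
    nt, nd = len(track_pos), len(det_pos)
    if nt == 0 or nd == 0:
        return []
    d2 = ((track_pos[:, None, :] - det_pos[None, :, :]) ** 2).sum(-1)
    big = 1e12
    penalty = search_range**2
    cost = np.full((nt + nd, nd + nt), 0.0)
    link = np.where(d2 <= penalty, d2, big)
    cost[:nt, :nd] = link
    cost[:nt, nd:] = big
    cost[nt:, :nd] = big
    np.fill_diagonal(cost[:nt, nd:], penalty)
    np.fill_diagonal(cost[nt:, :nd], penalty)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < nt and c < nd and d2[r, c] <= penalty]


def link_and_filter(
    detections,
    search_range_px: float,
    memory_frames: int = 0,
    min_frames: int = 2,
    min_distance_px: float = 0.0,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories and apply quality filters.

    Candidate links are restricted to displacements <= ``search_range_px``;
    tracks unseen for up to ``memory_frames`` consecutive frames are kept
    alive and may be re-linked (gap bridging).  Trajectories observed in fewer
    than ``min_frames`` frames or travelling less than ``min_distance_px``
    total path distance are discarded — raising either threshold can only
    shrink the result set.
    """
    if search_range_px <= 0:
        raise InputError("search_range_px must be > 0")
    if min_frames < 2:
        raise InputError("min_frames must be >= 2")

    # accept either per-frame lists or a flat iterable of detections
    if detections and isinstance(detections[0], Detection):
        by_frame: dict[int, list[Detection]] = {}
        for d in detections:
            by_frame.setdefault(d.frame, []).append(d)
    else:
        by_frame = {}
        for dets in detections:
            for d in dets:
                by_frame.setdefault(d.frame, []).append(d)
    if not by_frame:
        return []

    f_min, f_max = min(by_frame), max(by_frame)
    active: list[dict] = []
    finished: list[Trajectory] = []
    next_id = 0
    for f in range(f_min, f_max + 1):
        dets = by_frame.get(f, [])
        still_active = []
        for tr in active:
            if f - tr["last_frame"] > memory_frames + 1:
                finished.append(tr["traj"])
            else:
                still_active.append(tr)
        active = still_active

        if dets:
            track_pos = np.array([[t["x"], t["y"]] for t in active]) if active else np.empty((0, 2))
            det_pos = np.array([[d.x, d.y] for d in dets])
            pairs = _assign_frame(track_pos, det_pos, search_range_px)
            matched_t = {r for r, _ in pairs}
            matched_d = {c for _, c in pairs}
            for r, c in pairs:
                tr = active[r]
                tr["traj"].detections.append(dets[c])
                tr["x"], tr["y"], tr["last_frame"] = dets[c].x, dets[c].y, f
            for c, d in enumerate(dets):
                if c not in matched_d:
                    traj = Trajectory(cell_id=next_id, detections=[d])
                    next_id += 1
                    active.append({"traj": traj, "x": d.x, "y": d.y, "last_frame": f})
    finished.extend(t["traj"] for t in active)

    out = [
        t
        for t in sorted(finished, key=lambda t: t.cell_id)
        if t.n_frames_present >= min_frames and t.path_distance >= min_distance_px
    ]
    for new_id, t in enumerate(out):
        t.cell_id = new_id
    return out


# ---------------------------------------------------------------------------
# Per-cell kinematics and fluorescence


def compute_cell_velocity(
    traj: Trajectory,
    fps: float,
    um_per_px: float,
    mode: str = "free",
) -> dict:
    """Mean cell speed from displacement and the imaging rate.

    ``free`` mode divides the total path distance by the elapsed time
    (frame span / fps), so gap-bridged frames count toward time.
    ``x_channel_flow`` mode uses the net x-displacement instead — the readout
    for straight-channel transit/deformability assays; negative x-velocities
    are flagged rather than silently clipped.
    """
    if fps is None or not fps > 0:
        raise InputError("compute_cell_velocity requires fps > 0")
    if um_per_px is None or not um_per_px > 0:
        raise InputError("compute_cell_velocity requires um_per_px > 0")
    if traj.frame_span < 1:
        raise InputError("trajectory must span at least 2 frames")
    elapsed_s = traj.frame_span / fps
    if mode == "free":
        v = traj.path_distance * um_per_px / elapsed_s
        negative_x = False
    elif mode == "x_channel_flow":
        dx = traj.detections[-1].x - traj.detections[0].x
        v = dx * um_per_px / elapsed_s
        negative_x = v < 0
    else:
        raise InputError(f"unknown velocity mode {mode!r}")
    size = traj.mean_size_px
    # uniform-disk equivalence: a disk of radius r has Rg = r/sqrt(2), so the
    # effective geometric radius is sqrt(2)*Rg and the area 2*pi*Rg^2
    radius_um = math.sqrt(2.0) * size * um_per_px
    return {
        "velocity_um_s": float(v),
        "negative_x_flag": bool(negative_x),
        "size_px": size,
        "radius_um": radius_um,
        "area_um2": math.pi * radius_um**2,
    }


def measure_cell_fluorescence(
    traj: Trajectory,
    stack: FrameStack,
    channel: int,
    aperture_radius_px: float,
) -> float:
    """Mean per-frame summed intensity in a circular aperture about the cell.

    For every frame the cell was detected, pixel intensities of ``channel``
    within ``aperture_radius_px`` of the centroid are summed; the mean of
    those per-frame sums is returned.  Frames where the aperture leaves the
    image are skipped with a warning; if all are skipped, an error is raised.
    """
    plane = stack.plane(channel)
    h, w = plane.shape[1:]
    sums = []
    r = aperture_radius_px
    for d in traj.detections:
        if d.x - r < -0.5 or d.x + r > w - 0.5 or d.y - r < -0.5 or d.y + r > h - 0.5:
            warnings.warn(
                f"aperture off-frame for cell {traj.cell_id} at frame {d.frame}; skipped"
            )
            continue
        x0, x1 = int(math.floor(d.x - r)), int(math.ceil(d.x + r)) + 1
        y0, y1 = int(math.floor(d.y - r)), int(math.ceil(d.y + r)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        in_ap = ((xs[None, :] - d.x) ** 2 + (ys[:, None] - d.y) ** 2) <= r * r
        sums.append(float(plane[d.frame, y0:y1, x0:x1][in_ap].sum()))
    if not sums:
        raise InputError("aperture off-frame for every detection of this trajectory")
    return float(np.mean(sums))
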