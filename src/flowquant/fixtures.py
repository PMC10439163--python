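"""Ground-truthed synthetic microscopy renderers.

Each renderer emits a :class:`~flowquant.io_media.FrameStack` together with a
:class:`FixtureTruth` holding analytically-known quantities (centroids,
velocities, areas, protrusion/lobe counts, signal areas), so every analysis
workflow can be validated without external data.  Truth values are computed by
construction or by exhaustive rasterization — never by the analysis modules
they are meant to test.

Sub-pixel motion is rendered by evaluating Gaussians/speckles at continuous
positions; nothing is snapped to the pixel grid.  Noise is additive Gaussian,
clipped at zero.
All renders are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon

from .io_media import FrameStack, InputError

__all__ = [
    "FixtureTruth",
    "CellShapeSpec",
    "render_moving_cells",
    "render_adhesion_scene",
    "render_suspension_flow",
    "render_occlusion_series",
    "make_comb_stencil",
    "make_y_stencil",
    "star_vertices",
    "save_fixture",
]


@dataclass
class FixtureTruth:
    """Ground truth accompanying a rendered fixture.

    ``objects`` has one row per rendered object (areas, counts, velocities…);
    ``positions`` holds per-frame true centroids for moving fixtures;
    ``scene`` carries scene-level truth (stencil mask, per-frame signal areas,
    the velocity-profile function, …).
    """

    objects: pd.DataFrame
    positions: pd.DataFrame | None = None
    scene: dict = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _add_gaussian(img: np.ndarray, x: float, y: float, sigma: float, amp: float) -> float:
    """Accumulate a 2-D Gaussian spot at continuous (x, y); returns its pixel sum."""
    h, w = img.shape
    r = max(3, int(math.ceil(4 * sigma)))
    x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
    y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return 0.0
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
    patch = amp * gy[:, None] * gx[None, :]
    img[y0c:y1c, x0c:x1c] += patch
    return float(patch.sum())


def _apply_noise(frames: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return np.clip(frames, 0.0, None)


# ---------------------------------------------------------------------------
# Moving Gaussian-blob cells (single-cell tracking fixtures)


def render_moving_cells(
    n_cells: int,
    velocity_um_s: float | Sequence[float],
    blob_sigma_px: float = 2.0,
    amplitude: float = 200.0,
    noise_sd: float = 0.0,
    n_frames: int = 50,
    fps: float = 25.0,
    um_per_px: float = 1.0,
    seed: int = 0,
    frame_shape: tuple[int, int] | None = None,
    stain_amplitude: float = 0.0,
    stain_sigma_px: float | None = None,
) -> tuple[FrameStack, FixtureTruth]:
    """Render cells as 2-D Gaussian spots translating along +x.

    Each cell keeps its own row of the channel (rows separated by more than
    4·``blob_sigma_px`` so spots never overlap) and advances at its specified
    velocity, converted to px/frame via the fps and µm/px calibrations.

    If ``stain_amplitude`` > 0 an RGB stack is produced with the membrane
    signal in plane 0 and a co-moving fluorescent stain of known integrated
    signal in plane 1; the per-frame stain sum is recorded in the truth table.
    """
    velocities = np.broadcast_to(np.asarray(velocity_um_s, dtype=float), (n_cells,)).copy()
    rng = _rng(seed)
    px_per_frame = velocities / (um_per_px * fps)

    sep = 4.0 * blob_sigma_px
    row_pitch = sep + 2.0
    margin = 4 * blob_sigma_px + 2
    height = int(math.ceil(2 * margin + n_cells * row_pitch))
    travel = float(np.max(np.abs(px_per_frame))) * (n_frames - 1)
    start_span = 30.0
    width = int(math.ceil(2 * margin + start_span + max(travel, 0.0)))
    if frame_shape is not None:
        height, width = frame_shape
        if height < 2 * margin + n_cells * row_pitch - 2.0:
            raise InputError(
                f"frame height {height} cannot hold {n_cells} cells with pairwise "
                f"separation > {sep:.1f} px"
            )

    ys = margin + row_pitch * (np.arange(n_cells) + 0.5) + rng.uniform(-1, 1, n_cells)
    order = rng.permutation(n_cells)
    ys = ys[order]
    xs0 = margin + rng.uniform(0, start_span, n_cells)
    for_back = px_per_frame < 0  # negative-velocity cells start on the right
    xs0[for_back] = width - margin - rng.uniform(0, start_span, int(for_back.sum()))

    stain_sigma = stain_sigma_px if stain_sigma_px is not None else blob_sigma_px
    rgb = stain_amplitude > 0
    frames = np.zeros((n_frames, height, width, 3) if rgb else (n_frames, height, width))

    pos_rows = []
    for t in range(n_frames):
        for i in range(n_cells):
            x = xs0[i] + px_per_frame[i] * t
            y = ys[i]
            if rgb:
                _add_gaussian(frames[t, :, :, 0], x, y, blob_sigma_px, amplitude)
                stain_sum = _add_gaussian(frames[t, :, :, 1], x, y, stain_sigma, stain_amplitude)
            else:
                _add_gaussian(frames[t], x, y, blob_sigma_px, amplitude)
                stain_sum = np.nan
            pos_rows.append({"frame": t, "cell_id": i, "x": x, "y": y, "stain_sum": stain_sum})

    frames = _apply_noise(frames, noise_sd, rng)
    positions = pd.DataFrame(pos_rows)
    objects = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "velocity_um_s": velocities,
            "px_per_frame": px_per_frame,
            "sigma_px": blob_sigma_px,
            "amplitude": amplitude,
            "y_row": ys,
            "x_start": xs0,
            "mean_stain_sum": positions.groupby("cell_id")["stain_sum"].mean().values
            if rgb
            else np.nan,
        }
    )
    stack = FrameStack(frames, fps=fps, um_per_px=um_per_px)
    return stack, FixtureTruth(objects=objects, positions=positions,
                               scene={"noise_sd": noise_sd, "seed": seed})


# ---------------------------------------------------------------------------
# Adherent-cell scenes (morphology / functionality / protrusion fixtures)


@dataclass
class CellShapeSpec:
    """One adherent cell to render.

    ``shape`` is ``("disk", r)``, ``("ellipse", a, b)`` (semi-axes, a along x),
    ``("star", k, r_inner, r_outer)``, or ``("polygon", vertices)`` with
    vertices as (x, y) pairs relative to ``center``.  For polygons the caller
    states the true protrusion count via ``protrusions``.
    """

    center: tuple[float, float]
    shape: tuple
    membrane_intensity: float = 180.0
    secondary_intensity: float = 0.0
    secondary_frac: float = 0.5
    lobe_count: int = 0
    lobe_sep_px: float = 12.0
    lobe_intensity: float = 200.0
    lobe_sigma_px: float = 2.0
    protrusions: int | None = None


def star_vertices(k: int, r_inner: float, r_outer: float,
                  phase: float = -math.pi / 2) -> list[tuple[float, float]]:
    """Vertices of a k-pointed star (2k alternating outer/inner radii)."""
    verts = []
    for j in range(2 * k):
        r = r_outer if j % 2 == 0 else r_inner
        a = phase + math.pi * j / k
        verts.append((r * math.cos(a), r * math.sin(a)))
    return verts


def _rasterize_shape(spec: CellShapeSpec, shape_hw: tuple[int, int]) -> np.ndarray:
    h, w = shape_hw
    cx, cy = spec.center
    mask = np.zeros((h, w), dtype=bool)
    kind = spec.shape[0]
    yy, xx = np.mgrid[0:h, 0:w]
    if kind == "disk":
        r = spec.shape[1]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    elif kind == "ellipse":
        a, b = spec.shape[1], spec.shape[2]
        mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    elif kind in ("star", "polygon"):
        if kind == "star":
            k, r_in, r_out = spec.shape[1], spec.shape[2], spec.shape[3]
            verts = star_vertices(k, r_in, r_out)
        else:
            verts = list(spec.shape[1])
        vx = np.array([cx + v[0] for v in verts])
        vy = np.array([cy + v[1] for v in verts])
        rr, cc = _draw_polygon(vy, vx, shape=(h, w))
        mask[rr, cc] = True
    else:
        raise InputError(f"unknown shape kind {kind!r}")
    return mask


def _mask_eccentricity(mask: np.ndarray) -> float:
    """Second-moment eccentricity of a binary region (0 = circle)."""
    ys, xs = np.nonzero(mask)
    x0, y0 = xs.mean(), ys.mean()
    mu20 = np.mean((xs - x0) ** 2)
    mu02 = np.mean((ys - y0) ** 2)
    mu11 = np.mean((xs - x0) * (ys - y0))
    common = math.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11**2, 0.0))
    l1 = (mu20 + mu02 + common) / 2
    l2 = (mu20 + mu02 - common) / 2
    if l1 <= 0:
        return 0.0
    return math.sqrt(max(1.0 - l2 / l1, 0.0))


def _lobe_positions(n: int, sep: float, center: tuple[float, float]) -> list[tuple[float, float]]:
    cx, cy = center
    if n <= 0:
        return []
    if n == 1:
        return [(cx, cy)]
    if n == 2:
        return [(cx - sep / 2, cy), (cx + sep / 2, cy)]
    # regular n-gon with side length = sep, so pairwise separation >= sep
    radius = sep / (2 * math.sin(math.pi / n))
    return [
        (cx + radius * math.cos(2 * math.pi * j / n),
         cy + radius * math.sin(2 * math.pi * j / n))
        for j in range(n)
    ]


def render_adhesion_scene(
    cell_specs: Sequence[CellShapeSpec],
    frame_shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FrameStack, FixtureTruth]:
    """Render non-overlapping adherent cells into a 3-plane fluorescence image.

    Plane 0 carries the membrane stain, plane 1 the secondary (functional)
    stain, plane 2 the nuclear/lobe stain.  Truth records exhaustively
    rasterized area, moment eccentricity, planted protrusion and lobe counts,
    and the rendered secondary-stain sum per cell.
    """
    h, w = frame_shape
    rng = _rng(seed)
    membrane = np.zeros((h, w))
    secondary = np.zeros((h, w))
    lobes = np.zeros((h, w))
    occupied = np.zeros((h, w), dtype=bool)

    rows = []
    for i, spec in enumerate(cell_specs):
        mask = _rasterize_shape(spec, (h, w))
        if not mask.any():
            raise InputError(f"cell {i} rasterizes to an empty region")
        if (mask & occupied).any():
            raise InputError(f"cell {i} overlaps a previously placed cell")
        occupied |= mask
        membrane[mask] += spec.membrane_intensity

        sec_sum = 0.0
        if spec.secondary_intensity > 0 and spec.secondary_frac > 0:
            ys, xs = np.nonzero(mask)
            cx, cy = xs.mean(), ys.mean()
            d2 = (xs - cx) ** 2 + (ys - cy) ** 2
            n_sec = max(1, int(round(spec.secondary_frac * mask.sum())))
            order = np.argsort(d2, kind="stable")[:n_sec]  # central core carries the stain
            secondary[ys[order], xs[order]] += spec.secondary_intensity
            sec_sum = float(n_sec * spec.secondary_intensity)

        for lx, ly in _lobe_positions(spec.lobe_count, spec.lobe_sep_px, spec.center):
            _add_gaussian(lobes, lx, ly, spec.lobe_sigma_px, spec.lobe_intensity)

        kind = spec.shape[0]
        if spec.protrusions is not None:
            n_prot = spec.protrusions
        elif kind == "star":
            n_prot = spec.shape[1]
        else:
            n_prot = 0
        tip_r = spec.shape[3] if kind == "star" else np.nan

        ys, xs = np.nonzero(mask)
        rows.append(
            {
                "cell_id": i,
                "x": float(xs.mean()),
                "y": float(ys.mean()),
                "area_px": int(mask.sum()),
                "eccentricity": _mask_eccentricity(mask),
                "protrusion_count": n_prot,
                "tip_radius_px": tip_r,
                "lobe_count": spec.lobe_count,
                "secondary_sum": sec_sum,
                "membrane_intensity": spec.membrane_intensity,
            }
        )

    frames = np.stack([membrane, secondary, lobes], axis=-1)[None]
    frames = _apply_noise(frames, noise_sd, rng)
    stack = FrameStack(frames, um_per_px=None)
    truth = FixtureTruth(objects=pd.DataFrame(rows), scene={"occupied_mask": occupied})
    return stack, truth


# ---------------------------------------------------------------------------
# Flowing suspension with a prescribed velocity profile


def render_suspension_flow(
    profile: Callable[[np.ndarray], np.ndarray],
    texture_density: float = 0.02,
    n_frames: int = 20,
    fps: float = 100.0,
    um_per_px: float = 1.0,
    frame_shape: tuple[int, int] = (96, 256),
    speckle_sigma_px: float = 1.3,
    noise_sd: float = 0.0,
    seed: int = 0,
    time_scale: Callable[[int], float] | None = None,
) -> tuple[FrameStack, FixtureTruth]:
    """Render speckle texture advected horizontally by a velocity profile.

    ``profile`` maps signed distance from the channel center (µm, positive
    downward) to velocity (µm/s).  The channel spans the full frame height.
    Speckles live at continuous positions and wrap periodically in x, so
    arbitrary total displacement is representable; ``time_scale`` optionally
    modulates speed frame-by-frame (e.g. a linear ramp to zero).
    """
    h, w = frame_shape
    rng = _rng(seed)
    n_spots = int(round(texture_density * h * w))
    if n_spots < 1:
        raise InputError("texture_density too low: no speckles to render")
    xs = rng.uniform(0, w, n_spots)
    ys = rng.uniform(1, h - 1, n_spots)
    amps = rng.uniform(90, 180, n_spots)

    center = (h - 1) / 2.0
    y_um = (ys - center) * um_per_px
    v_um_s = np.asarray(profile(y_um), dtype=float)
    px_per_frame = v_um_s / (um_per_px * fps)
    max_disp = float(np.max(np.abs(px_per_frame)))
    if max_disp >= w:
        raise InputError("per-frame displacement exceeds frame width")

    frames = np.zeros((n_frames, h, w))
    disp = np.zeros(n_spots)
    for t in range(n_frames):
        if t > 0:
            scale = time_scale(t - 1) if time_scale is not None else 1.0
            disp = disp + px_per_frame * scale
        for i in range(n_spots):
            x = (xs[i] + disp[i]) % w
            _add_gaussian(frames[t], x, ys[i], speckle_sigma_px, amps[i])
            # render the wrap-around ghost so the texture is truly periodic
            if x < 6:
                _add_gaussian(frames[t], x + w, ys[i], speckle_sigma_px, amps[i])
            elif x > w - 6:
                _add_gaussian(frames[t], x - w, ys[i], speckle_sigma_px, amps[i])
    frames = _apply_noise(frames, noise_sd, rng)

    objects = pd.DataFrame(
        {"spot_id": np.arange(n_spots), "x0": xs, "y": ys,
         "y_um_from_center": y_um, "velocity_um_s": v_um_s,
         "px_per_frame": px_per_frame}
    )
    scene = {
        "profile": profile,
        "center_row": center,
        "channel_height_um": h * um_per_px,
        "time_scale": time_scale,
    }
    stack = FrameStack(frames, fps=fps, um_per_px=um_per_px)
    return stack, FixtureTruth(objects=objects, scene=scene)


# ---------------------------------------------------------------------------
# Occlusion / accumulation time series inside a device stencil


def make_comb_stencil(
    n_channels: int = 32,
    channel_height: int = 6,
    gap: int = 4,
    channel_length: int = 120,
    margin: int = 5,
) -> tuple[np.ndarray, list[dict]]:
    """Binary comb stencil: ``n_channels`` parallel horizontal microchannels.

    Returns the mask and a list of channel boxes
    ``{"x0", "x1", "y0", "y1"}`` (inclusive bounds).
    """
    h = 2 * margin + n_channels * channel_height + (n_channels - 1) * gap
    w = 2 * margin + channel_length
    mask = np.zeros((h, w), dtype=bool)
    channels = []
    for i in range(n_channels):
        y0 = margin + i * (channel_height + gap)
        y1 = y0 + channel_height - 1
        mask[y0 : y1 + 1, margin : margin + channel_length] = True
        channels.append({"x0": margin, "x1": margin + channel_length - 1, "y0": y0, "y1": y1})
    return mask, channels


def make_y_stencil(size: tuple[int, int] = (120, 160), arm_width: int = 12) -> np.ndarray:
    """Binary Y-junction stencil: one stem splitting into two diagonal arms."""
    h, w = size
    mask = np.zeros((h, w), dtype=bool)
    cy = h // 2
    stem_end = w // 2
    mask[cy - arm_width // 2 : cy + arm_width // 2, 5:stem_end] = True
    for sign in (-1, 1):
        x0, y0 = stem_end, cy
        x1, y1 = w - 6, cy + sign * (h // 2 - 10)
        n = 2 * (x1 - x0)
        for t in np.linspace(0, 1, n):
            x = int(round(x0 + t * (x1 - x0)))
            y = int(round(y0 + t * (y1 - y0)))
            mask[max(y - arm_width // 2, 0) : y + arm_width // 2, x : x + 2] = True
    return mask


def render_occlusion_series(
    stencil: np.ndarray,
    growth_schedule,
    seed: int = 0,
    fill_mode: str = "left",
    amplitude: float = 220.0,
    noise_sd: float = 0.0,
    channels: list[dict] | None = None,
) -> tuple[FrameStack, FixtureTruth]:
    """Render a multi-channel fluorescence time series growing inside a stencil.

    ``growth_schedule`` is either a sequence of signal-area fractions (applied
    to color plane 0) or a mapping plane index -> sequence; all sequences must
    share length (the number of timepoints) and lie in [0, 1].

    ``fill_mode`` fixes which stencil pixels light up first: ``"left"`` fills
    columns from the inlet, ``"right"`` from the outlet, ``"random"`` in a
    seeded random order, and ``"rotating"`` slides a window over a seeded
    permutation so that the union over timepoints covers the whole stencil.
    """
    stencil = np.asarray(stencil, dtype=bool)
    area = int(stencil.sum())
    if area == 0:
        raise InputError("stencil is empty")
    if isinstance(growth_schedule, dict):
        schedule = {int(k): np.asarray(v, dtype=float) for k, v in growth_schedule.items()}
    else:
        schedule = {0: np.asarray(growth_schedule, dtype=float)}
    lengths = {len(v) for v in schedule.values()}
    if len(lengths) != 1:
        raise InputError("all per-plane growth schedules must share one length")
    n_t = lengths.pop()
    for plane, fracs in schedule.items():
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise InputError(f"growth fractions for plane {plane} must lie in [0, 1]")

    rng = _rng(seed)
    ys, xs = np.nonzero(stencil)
    if fill_mode == "left":
        order = np.lexsort((ys, xs))
    elif fill_mode == "right":
        order = np.lexsort((ys, -xs))
    elif fill_mode in ("random", "rotating"):
        order = rng.permutation(area)
    else:
        raise InputError(f"unknown fill_mode {fill_mode!r}")
    oy, ox = ys[order], xs[order]

    h, w = stencil.shape
    frames = np.zeros((n_t, h, w, 3))
    truth_rows = []
    for t in range(n_t):
        for plane, fracs in schedule.items():
            count = int(round(fracs[t] * area))
            if fill_mode == "rotating":
                start = (t * max(area // max(n_t, 1), 1)) % area
                idx = (start + np.arange(count)) % area
                sel_y, sel_x = oy[idx], ox[idx]
            else:
                sel_y, sel_x = oy[:count], ox[:count]
            frames[t, sel_y, sel_x, plane] = amplitude
            truth_rows.append(
                {"timepoint": t, "plane": plane, "signal_area_px": count,
                 "occlusion_pct": 100.0 * count / area}
            )
    frames = _apply_noise(frames, noise_sd, rng)
    objects = pd.DataFrame(truth_rows)
    scene = {"stencil": stencil, "stencil_area_px": area, "channels": channels or []}
    return FrameStack(frames), FixtureTruth(objects=objects, scene=scene)


# ---------------------------------------------------------------------------
# Persistence (lets any CLI path be exercised end-to-end from disk)


def save_fixture(stack: FrameStack, truth: FixtureTruth, out_dir) -> Path:
    """Persist a fixture as numbered TIFF frames plus truth CSV tables."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = stack.frames
    scaled = np.clip(arr, 0, 65535).astype(np.uint16)
    for t in range(stack.n_frames):
        tifffile.imwrite(out / f"frame_{t:04d}.tif", scaled[t])
    truth.objects.to_csv(out / "truth_objects.csv", index=False)
    if truth.positions is not None:
        truth.positions.to_csv(out / "truth_positions.csv", index=False)
    return out
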