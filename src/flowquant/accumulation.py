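"""Multi-channel occlusion and accumulation quantification in microfluidics.

Fluorescence color planes are binarized with per-plane user thresholds; the
wetted device geometry is inferred as the count-thresholded union of all
signal masks across planes and timepoints (the "device map").  Occlusion is
the percentage of a device region (or a single microchannel) covered by
signal; accumulation is the change in signal area between timepoints, and
the accumulation rate is the least-squares slope of signal area versus time.

Microchannels are assumed horizontal (flow along x); within each detected
channel the walls y_top(x)/y_bottom(x) are smoothed by a short median filter,
and a spatial occlusion percentage is reported at every x along the channel,
with x measured from the inlet (proximal end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label

from .io_media import FrameStack, InputError

__all__ = [
    "DeviceMap",
    "Microchannel",
    "OcclusionSeries",
    "binarize_channels",
    "build_device_map",
    "detect_microchannels",
    "compute_occlusion_accumulation",
    "spatial_occlusion",
]


@dataclass
class Microchannel:
    """One straight microchannel: x-range plus smoothed wall curves."""

    channel_id: int
    x0: int
    x1: int                      # inclusive
    y_top: np.ndarray            # per-x upper wall row
    y_bottom: np.ndarray         # per-x lower wall row

    @property
    def xs(self) -> np.ndarray:
        return np.arange(self.x0, self.x1 + 1)

    @property
    def spans(self) -> np.ndarray:
        """Per-x wall-to-wall height in pixels (inclusive)."""
        return self.y_bottom - self.y_top + 1

    def region_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of the area between the smoothed walls."""
        mask = np.zeros(shape, dtype=bool)
        for i, x in enumerate(self.xs):
            mask[int(self.y_top[i]) : int(self.y_bottom[i]) + 1, x] = True
        return mask


@dataclass
class DeviceMap:
    """Binary device-region mask with optional microchannel sub-regions."""

    mask: np.ndarray
    channels: list[Microchannel] = field(default_factory=list)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class OcclusionSeries:
    """Per-timepoint, per-plane occlusion/accumulation of one device region."""

    table: pd.DataFrame          # timepoint, time_min, plane, signal_area_px,
                                 # signal_area_um2, occlusion_pct, accumulation_px2
    rates_um2_per_min: dict      # plane -> least-squares slope
    region_area_px: int


# ---------------------------------------------------------------------------


def binarize_channels(
    stack: FrameStack | np.ndarray, thresholds: dict[int, float]
) -> dict[int, np.ndarray]:
    """Binarize selected color planes: pixel > threshold = signal.

    Returns a mapping plane index -> (T, H, W) boolean mask array.
    """
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    if frames.ndim == 3:  # grayscale: only plane 0 exists
        frames = frames[..., None]
    n_planes = frames.shape[-1]
    masks = {}
    for plane, thr in thresholds.items():
        if not 0 <= plane < n_planes:
            raise InputError(f"threshold given for absent color plane {plane} "
                             f"(image has {n_planes})")
        masks[int(plane)] = frames[..., plane] > thr
    if not masks:
        raise InputError("no thresholds given")
    return masks


def build_device_map(masks: dict[int, np.ndarray], map_threshold: int = 1) -> DeviceMap:
    """Infer the wetted device region from all signal masks.

    Per-pixel signal occurrences are counted across every plane and timepoint;
    pixels reaching ``map_threshold`` occurrences form the device mask
    (threshold 1 = plain union, the "any signal ever" reading).
    """
    if map_threshold < 1:
        raise InputError("map_threshold must be >= 1")
    count = None
    for plane_masks in masks.values():
        arr = np.asarray(plane_masks)
        if arr.ndim == 2:
            arr = arr[None]
        s = arr.sum(axis=0).astype(np.int64)
        count = s if count is None else count + s
    if count is None:
        raise InputError("no masks supplied")
    mask = count >= map_threshold
    if not mask.any():
        raise InputError("no device signal found: the union of all masks is empty")
    return DeviceMap(mask=mask)


def detect_microchannels(device_map: DeviceMap, smooth_window: int = 5) -> DeviceMap:
    """Label connected regions as microchannels and smooth their walls.

    For each channel and each x in its range the walls are the min/max row of
    region pixels at that column; single-column gaps are filled by linear
    interpolation between neighboring wall values, then a short median filter
    (``smooth_window`` columns) removes ragged single-pixel wall noise.
    Channels are indexed top-to-bottom, left-to-right.
    """
    from scipy.ndimage import binary_closing, median_filter

    # close single-column dropouts along x so they do not sever a channel;
    # walls are still measured on the original mask and interpolated across
    closed = binary_closing(device_map.mask, structure=np.ones((1, 3), dtype=bool))
    labels = sk_label(closed, connectivity=2)
    channels = []
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero((labels == lab) & device_map.mask)
        x0, x1 = int(xs.min()), int(xs.max())
        n = x1 - x0 + 1
        top = np.full(n, np.nan)
        bot = np.full(n, np.nan)
        for x in range(x0, x1 + 1):
            col = ys[xs == x]
            if len(col):
                top[x - x0] = col.min()
                bot[x - x0] = col.max()
        # fill interior gaps by linear interpolation
        for arr in (top, bot):
            bad = np.isnan(arr)
            if bad.any():
                good = ~bad
                arr[bad] = np.interp(np.nonzero(bad)[0], np.nonzero(good)[0], arr[good])
        if smooth_window >= 3 and n >= smooth_window:
            top = median_filter(top, size=smooth_window, mode="nearest")
            bot = median_filter(bot, size=smooth_window, mode="nearest")
        top_i = np.rint(top).astype(int)
        bot_i = np.rint(bot).astype(int)
        bot_i = np.maximum(bot_i, top_i)
        channels.append(Microchannel(channel_id=0, x0=x0, x1=x1, y_top=top_i, y_bottom=bot_i))
    channels.sort(key=lambda c: (int(c.y_top.mean()), c.x0))
    for i, c in enumerate(channels):
        c.channel_id = i
    return DeviceMap(mask=device_map.mask, channels=channels)


def compute_occlusion_accumulation(
    masks: dict[int, np.ndarray],
    region,
    timestamps_min,
    um_per_px: float = 1.0,
) -> OcclusionSeries:
    """Occlusion %, per-interval accumulation, and accumulation rate.

    ``region`` is a :class:`DeviceMap`, a :class:`Microchannel`, or a binary
    mask.  Per timepoint and plane the signal area is the mask∩region pixel
    count; occlusion is its percentage of the region area; accumulation is
    the signal-area change from the previous timepoint; the rate is the
    least-squares slope of signal area (µm²) against time (minutes).
    """
    timestamps = np.asarray(timestamps_min, dtype=float)
    if len(timestamps) > 1 and not np.all(np.diff(timestamps) > 0):
        raise InputError("timestamps must be strictly increasing")
    if um_per_px <= 0:
        raise InputError("um_per_px must be > 0")

    if isinstance(region, DeviceMap):
        region_mask = region.mask
    elif isinstance(region, Microchannel):
        first = next(iter(masks.values()))
        shape = np.asarray(first).shape[-2:]
        region_mask = region.region_mask(shape)
    else:
        region_mask = np.asarray(region, dtype=bool)
    region_area = int(region_mask.sum())
    if region_area == 0:
        raise InputError("region has zero area")

    px2_to_um2 = um_per_px**2
    rows = []
    rates = {}
    for plane, plane_masks in sorted(masks.items()):
        arr = np.asarray(plane_masks)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.shape[0] != len(timestamps):
            raise InputError(
                f"plane {plane}: {arr.shape[0]} masks but {len(timestamps)} timestamps"
            )
        areas = np.array([int((m & region_mask).sum()) for m in arr], dtype=float)
        occl = 100.0 * areas / region_area
        accum = np.concatenate([[np.nan], np.diff(areas)])
        for t in range(len(timestamps)):
            rows.append(
                {
                    "timepoint": t,
                    "time_min": timestamps[t],
                    "plane": plane,
                    "signal_area_px": areas[t],
                    "signal_area_um2": areas[t] * px2_to_um2,
                    "occlusion_pct": occl[t],
                    "accumulation_px2": accum[t],
                }
            )
        if len(timestamps) >= 2:
            slope = np.polyfit(timestamps, areas * px2_to_um2, 1)[0]
        else:
            slope = np.nan
        rates[plane] = float(slope)
    return OcclusionSeries(table=pd.DataFrame(rows), rates_um2_per_min=rates,
                           region_area_px=region_area)


def spatial_occlusion(mask: np.ndarray, channel: Microchannel) -> pd.DataFrame:
    """Per-x occlusion percentage along one microchannel.

    At each column x of the channel the occlusion is the percentage of pixels
    between the smoothed walls that carry signal.  ``x_from_inlet`` counts
    from the channel's proximal (smallest-x) end.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        raise InputError("spatial_occlusion expects a single-timepoint (H, W) mask")
    pct = np.empty(channel.x1 - channel.x0 + 1)
    for i, x in enumerate(channel.xs):
        yt, yb = int(channel.y_top[i]), int(channel.y_bottom[i])
        span = yb - yt + 1
        pct[i] = 100.0 * mask[yt : yb + 1, x].sum() / span
    return pd.DataFrame(
        {
            "x": channel.xs,
            "x_from_inlet": channel.xs - channel.x0,
            "occlusion_pct": pct,
            "wall_span_px": channel.spans,
        }
    )
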