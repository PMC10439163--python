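"""Loading, calibration, cropping and background correction of imaging data.

Every workflow in :mod:`flowquant` consumes a :class:`FrameStack` — an ordered
set of frames (grayscale or RGB) with the physical calibration needed to turn
pixel measurements into micrometers and seconds.  Pixel intensities are treated
as arbitrary units throughout: no automatic rescaling is ever applied.

Coordinate convention: 0-based, ``x`` = column index increasing rightward,
``y`` = row index increasing downward.  Regions of interest are half-open,
``[x0, x0 + width) × [y0, y0 + height)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = ["FrameStack", "ROI", "load_stack", "crop_roi", "subtract_background"]


class InputError(ValueError):
    """Raised for unreadable, inconsistent, or out-of-bounds input data."""


@dataclass
class FrameStack:
    """An ordered stack of microscopy frames with physical calibration.

    Parameters
    ----------
    frames : ndarray
        ``(T, H, W)`` grayscale or ``(T, H, W, 3)`` RGB array, intensities in
        arbitrary units >= 0.
    fps : float, optional
        Frames per second (videomicroscopy only). Must be > 0 when set.
    um_per_px : float, optional
        Micrometers per pixel. Must be > 0 when set.
    channel_tags : mapping, optional
        Color-plane index -> semantic stain label (e.g. ``{0: "CD41"}``).
    """

    frames: np.ndarray
    fps: float | None = None
    um_per_px: float | None = None
    channel_tags: Mapping[int, str] | None = None
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise InputError(
                f"frames must be (T, H, W) or (T, H, W, 3); got shape {self.frames.shape}"
            )
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise InputError(f"RGB stacks need exactly 3 planes; got {self.frames.shape[-1]}")
        if not np.all(np.isfinite(self.frames)):
            raise InputError("pixel values must be finite")
        if self.fps is not None and not self.fps > 0:
            raise InputError(f"fps must be > 0; got {self.fps}")
        if self.um_per_px is not None and not self.um_per_px > 0:
            raise InputError(f"um_per_px must be > 0; got {self.um_per_px}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def is_rgb(self) -> bool:
        return self.frames.ndim == 4

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]

    def plane(self, channel: int) -> np.ndarray:
        """Return one color plane as a (T, H, W) grayscale stack."""
        if not self.is_rgb:
            if channel == 0:
                return self.frames
            raise InputError(f"grayscale stack has no plane {channel}")
        if not 0 <= channel < 3:
            raise InputError(f"plane index {channel} out of range for RGB stack")
        return self.frames[..., channel]

    def gray(self) -> np.ndarray:
        """Collapse to (T, H, W) grayscale (mean over planes for RGB)."""
        if self.is_rgb:
            return self.frames.mean(axis=-1)
        return self.frames

    def require_fps(self) -> float:
        if self.fps is None:
            raise InputError("this operation needs a frames-per-second calibration (fps)")
        return self.fps

    def require_um_per_px(self) -> float:
        if self.um_per_px is None:
            raise InputError("this operation needs a micrometers-per-pixel calibration")
        return self.um_per_px

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        return replace(self, frames=frames)


@dataclass(frozen=True)
class ROI:
    """A rectangular region of interest: half-open pixel box.

    ``x0``/``y0`` are the 0-based top-left column/row; the box spans
    ``[x0, x0+width) × [y0, y0+height)``.
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise InputError(f"ROI must be at least 1×1; got {self.width}×{self.height}")
        if self.x0 < 0 or self.y0 < 0:
            raise InputError(f"ROI origin must be non-negative; got ({self.x0}, {self.y0})")


# ---------------------------------------------------------------------------
# Loading


_NUM_RE = re.compile(r"(\d+)")


def _numeric_sort_key(path: Path):
    """Sort filenames by their embedded integer(s), then lexically."""
    parts = _NUM_RE.split(path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _read_image(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.mode not in ("L", "I", "I;16", "RGB"):
                    im = im.convert("RGB") if ("A" in im.mode or im.mode == "P") else im.convert("L")
                arr = np.asarray(im)
    except Exception as exc:  # decode failures name the offending file
        raise InputError(f"could not read image file {path}: {exc}") from exc
    return arr


def load_stack(
    path_or_paths,
    kind: str = "auto",
    fps: float | None = None,
    um_per_px: float | None = None,
    channel_tags: Mapping[int, str] | None = None,
) -> FrameStack:
    """Load a single image, an ordered image sequence, or a video.

    Parameters
    ----------
    path_or_paths
        A file path, a directory of numbered frames, or an explicit list of
        frame paths.
    kind : {"auto", "image", "sequence", "video"}
        ``auto`` infers from the path: directory/list -> sequence, ``.avi`` ->
        video, otherwise image (multi-page TIFFs load as one stack).

    Sequences are ordered by the numeric components of their filenames, so
    ``frame_2.tif`` precedes ``frame_10.tif``.  All frames must share height,
    width and plane count; a mismatch or unreadable frame raises
    :class:`InputError` naming the offending file.
    """
    if isinstance(path_or_paths, (list, tuple)):
        paths = [Path(p) for p in path_or_paths]
        return _load_sequence(paths, fps, um_per_px, channel_tags)

    path = Path(path_or_paths)
    if kind == "auto":
        if path.is_dir():
            kind = "sequence"
        elif path.suffix.lower() == ".avi":
            kind = "video"
        else:
            kind = "image"

    if kind == "sequence":
        if path.is_dir():
            paths = sorted(
                (p for p in path.iterdir()
                 if p.suffix.lower() in (".tif", ".tiff", ".png")),
                key=_numeric_sort_key,
            )
            if not paths:
                raise InputError(f"no TIFF/PNG frames found in directory {path}")
        else:
            paths = [path]
        return _load_sequence(paths, fps, um_per_px, channel_tags)

    if kind == "video":
        return _load_video(path, fps, um_per_px, channel_tags)

    if not path.exists():
        raise InputError(f"input file does not exist: {path}")
    arr = _read_image(path)
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[-1] == 3):
        frames = arr[None]
    elif arr.ndim == 3:  # multi-page grayscale TIFF
        frames = arr
    elif arr.ndim == 4 and arr.shape[-1] == 3:
        frames = arr
    else:
        raise InputError(f"unsupported image shape {arr.shape} in {path}")
    return FrameStack(np.ascontiguousarray(frames), fps=fps, um_per_px=um_per_px,
                      channel_tags=channel_tags, source=str(path))


def _load_sequence(paths: Sequence[Path], fps, um_per_px, channel_tags) -> FrameStack:
    frames = []
    shape = None
    for p in paths:
        if not p.exists():
            raise InputError(f"frame file does not exist: {p}")
        arr = _read_image(p)
        if arr.ndim not in (2, 3):
            raise InputError(f"unsupported frame shape {arr.shape} in {p}")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise InputError(
                f"frame {p} has shape {arr.shape}, expected {shape} (mixed-size sequence)"
            )
        frames.append(arr)
    stack = np.stack(frames)
    return FrameStack(stack, fps=fps, um_per_px=um_per_px, channel_tags=channel_tags,
                      source=str(paths[0].parent))


def _load_video(path: Path, fps, um_per_px, channel_tags) -> FrameStack:
    if not path.exists():
        raise InputError(f"video file does not exist: {path}")
    try:
        import imageio.v3 as iio

        frames = iio.imread(path, plugin="pyav") if False else iio.imread(path)
    except Exception as exc:
        raise InputError(
            f"could not decode video {path}: {exc}. "
            "Install an AVI-capable imageio plugin, or convert the video to a "
            "numbered TIFF/PNG frame sequence and load with kind='sequence'."
        ) from exc
    frames = np.asarray(frames)
    if frames.ndim == 3 and frames.shape[-1] == 3:  # single frame decoded
        frames = frames[None]
    if frames.ndim == 4 and frames.shape[-1] == 4:
        frames = frames[..., :3]
    return FrameStack(frames, fps=fps, um_per_px=um_per_px, channel_tags=channel_tags,
                      source=str(path))


# ---------------------------------------------------------------------------
# Cropping and background subtraction


def crop_roi(stack: FrameStack, roi: ROI) -> FrameStack:
    """Crop every frame to ``roi``; calibration metadata is unchanged."""
    if roi.x0 + roi.width > stack.width or roi.y0 + roi.height > stack.height:
        raise InputError(
            f"ROI {roi} extends past the {stack.width}×{stack.height} frame bounds"
        )
    sub = stack.frames[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return stack.with_frames(np.ascontiguousarray(sub))


def subtract_background(
    stack: FrameStack, method: str = "static-median", window: int = 11
) -> FrameStack:
    """Suppress static structures (channel walls) while keeping moving objects.

    ``static-median`` subtracts the per-pixel median over all frames —
    deterministic and appropriate when the camera and device are fixed.
    ``rolling`` subtracts a per-pixel rolling median over ``window`` frames,
    tolerating slow drift.  Output is clipped at 0.
    """
    if stack.n_frames < 2:
        raise InputError("background subtraction needs at least 2 frames")
    frames = stack.frames.astype(np.float64)
    if method == "static-median":
        bg = np.median(frames, axis=0)
        out = frames - bg[None]
    elif method == "rolling":
        from scipy.ndimage import median_filter

        if window < 3:
            raise InputError("rolling window must be >= 3 frames")
        size = (min(window, stack.n_frames),) + (1,) * (frames.ndim - 1)
        bg = median_filter(frames, size=size, mode="nearest")
        out = frames - bg
    else:
        raise InputError(f"unknown background method {method!r}")
    return stack.with_frames(np.clip(out, 0.0, None))
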