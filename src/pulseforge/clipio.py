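"""Video clip I/O: loading, normalization, cropping, resizing, segmentation.

Facial video arrives either as a directory of image frames, an NPZ/HDF5 array
stack (the package's fixture format), or an in-memory array.  All pixel data
is normalized to [0, 1] floats in D x C x H x W layout, with D the frame
count.  Ground-truth blood-volume-pulse (BVP) label series travel alongside
clips in :class:`BVPRecord`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "FrameClip", "ClipBatch", "BVPRecord", "ROISpec",
    "load_frames", "resize_clip", "segment_clips",
    "save_fixture", "load_fixture",
]

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class ROISpec:
    """Rectangular region of interest, 0-based, half-open pixel coordinates."""

    x0: int
    y0: int
    width: int
    height: int

    def validate(self, frame_h: int, frame_w: int) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"ROI must have positive size, got {self}")
        if (self.x0 < 0 or self.y0 < 0 or self.x0 + self.width > frame_w
                or self.y0 + self.height > frame_h):
            raise ValueError(
                f"ROI {self} falls outside a {frame_h}x{frame_w} frame")


@dataclass
class FrameClip:
    """A fixed-length pixel clip: frames (D, C, H, W) in [0, 1] at ``fps`` Hz."""

    frames: np.ndarray
    fps: float
    subject_id: str = ""
    clip_id: str = ""
    t0: int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be DxCxHxW, got shape {self.frames.shape}")
        d, c, _, _ = self.frames.shape
        if d < 1 or c not in (1, 3):
            raise ValueError(f"need D >= 1 and C in {{1, 3}}, got D={d}, C={c}")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"pixel values must lie in [0, 1], got [{lo}, {hi}]")

    @property
    def d(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.frames.shape


@dataclass
class BVPRecord:
    """Ground-truth pulse wave paired with a clip (same length, same fps)."""

    wave: np.ndarray
    fps: float
    hr_ref: float | None = None

    def __post_init__(self):
        self.wave = np.asarray(self.wave, dtype=np.float64).ravel()
        if not np.isfinite(self.wave).all():
            raise ValueError("BVP wave contains non-finite values")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")


@dataclass
class ClipBatch:
    """N clips of identical geometry; the flattened frame axis B = N * D."""

    clips: list[FrameClip] = field(default_factory=list)

    def __post_init__(self):
        if self.clips:
            shape, fps = self.clips[0].shape, self.clips[0].fps
            for c in self.clips[1:]:
                if c.shape != shape or c.fps != fps:
                    raise ValueError("all clips in a batch must share shape and fps")

    def __len__(self) -> int:
        return len(self.clips)

    @property
    def n(self) -> int:
        return len(self.clips)

    @property
    def d(self) -> int:
        return self.clips[0].d

    @property
    def b(self) -> int:
        return self.n * self.d

    def stack(self) -> np.ndarray:
        """(N, D, C, H, W) float32 array."""
        return np.stack([c.frames for c in self.clips])


def _normalize_pixels(arr: np.ndarray) -> np.ndarray:
    """Scale integer pixel data by its dtype maximum; floats pass through."""
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(np.float32) / scale
    out = arr.astype(np.float32)
    if out.size and out.max() > 1.0 + 1e-6:
        # float data on a 0..255 scale: treat like 8-bit
        out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def _frames_from_dir(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
    if not files:
        raise IOError(f"no image frames found in {path}")
    imgs = [np.asarray(iio.imread(f)) for f in files]
    arr = np.stack(imgs)                       # (D, H, W[, C])
    if arr.ndim == 3:
        arr = arr[:, :, :, None]
    return arr.transpose(0, 3, 1, 2)           # -> (D, C, H, W)


def load_frames(source, roi: ROISpec | None = None, fps: float | None = None,
                subject_id: str = "", clip_id: str = "") -> FrameClip:
    """Load a frame sequence and return a normalized :class:`FrameClip`.

    ``source`` may be a directory of image frames, an ``.npz``/``.h5`` fixture
    written by :func:`save_fixture`, or an array of shape (D, C, H, W) or
    (D, H, W, C).  ``fps`` is read from fixture metadata when available and
    must be supplied otherwise (default 30 for raw arrays/frame directories).
    """
    meta_fps = None
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        if path.is_dir():
            arr = _frames_from_dir(path)
        elif path.suffix.lower() in {".h5", ".hdf5", ".npz"}:
            fix = load_fixture(path)
            arr, meta_fps = fix.clip.frames, fix.clip.fps
            subject_id = subject_id or fix.clip.subject_id
            clip_id = clip_id or fix.clip.clip_id
        elif path.suffix.lower() in {".mp4", ".avi", ".mov", ".mkv", ".webm"}:
            raise IOError(
                f"no video-container decoder is available for {path.name}; "
                "extract frames to a directory of PNGs or use the array-stack "
                "fixture format instead")
        else:
            raise IOError(f"cannot decode frame source {path}")
    else:
        arr = np.asarray(source)
        if arr.ndim != 4:
            raise IOError(f"array source must be 4-D, got shape {arr.shape}")
        if arr.shape[1] not in (1, 3) and arr.shape[3] in (1, 3):
            arr = arr.transpose(0, 3, 1, 2)    # DHWC -> DCHW

    frames = _normalize_pixels(arr)
    if roi is not None:
        h, w = frames.shape[2], frames.shape[3]
        roi.validate(h, w)
        frames = frames[:, :, roi.y0:roi.y0 + roi.height, roi.x0:roi.x0 + roi.width]
    use_fps = fps if fps is not None else (meta_fps if meta_fps is not None else 30.0)
    return FrameClip(frames=frames, fps=use_fps, subject_id=subject_id,
                     clip_id=clip_id)


def resize_clip(clip: FrameClip, h: int, w: int, order: int = 1) -> FrameClip:
    """Resize every frame to ``h`` x ``w`` (bilinear by default; ``order=0``
    for nearest-neighbor).  Values are clamped back to [0, 1] afterwards."""
    from skimage.transform import resize as _resize

    if h <= 0 or w <= 0:
        raise ValueError("target size must be positive")
    if clip.frames.shape[2:] == (h, w):
        return replace(clip, frames=clip.frames.copy())
    # resize per clip in one call: move channels to the trailing axis
    src = clip.frames.transpose(0, 2, 3, 1)
    out = _resize(src, (src.shape[0], h, w, src.shape[3]), order=order,
                  mode="edge", anti_aliasing=order > 0, preserve_range=True)
    out = np.clip(out, 0.0, 1.0).astype(np.float32).transpose(0, 3, 1, 2)
    return replace(clip, frames=out)


def segment_clips(frames: np.ndarray, d: int, stride: int | None = None,
                  fps: float = 30.0, subject_id: str = "",
                  clip_prefix: str = "clip") -> list[FrameClip]:
    """Cut a long (L, C, H, W) sequence into fixed-length windows.

    Windows start at multiples of ``stride`` (default ``d``: non-overlapping)
    and a trailing partial window is discarded.  Sequences shorter than ``d``
    yield an empty list.
    """
    if d < 1:
        raise ValueError("clip length d must be >= 1")
    stride = d if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = np.asarray(frames)
    out: list[FrameClip] = []
    k = 0
    while k * stride + d <= frames.shape[0]:
        t0 = k * stride
        out.append(FrameClip(frames=_normalize_pixels(frames[t0:t0 + d]),
                             fps=fps, subject_id=subject_id,
                             clip_id=f"{clip_prefix}{k:04d}", t0=t0))
        k += 1
    return out


@dataclass
class FixtureSample:
    clip: FrameClip
    bvp: BVPRecord | None


def save_fixture(path, clip: FrameClip, bvp: BVPRecord | None = None) -> None:
    """Write a clip (and optional BVP label) to the HDF5 fixture format.

    Layout: datasets ``frames`` (D, C, H, W) float32 and optional ``bvp``
    (D,) float32; root attrs ``fps``, ``subject_id``, ``clip_id``, ``t0``.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=clip.frames.astype(np.float32))
        if bvp is not None:
            f.create_dataset("bvp", data=bvp.wave.astype(np.float32))
            if bvp.hr_ref is not None:
                f.attrs["hr_ref"] = float(bvp.hr_ref)
        f.attrs["fps"] = float(clip.fps)
        f.attrs["subject_id"] = clip.subject_id
        f.attrs["clip_id"] = clip.clip_id
        f.attrs["t0"] = int(clip.t0)


def load_fixture(path) -> FixtureSample:
    """Inverse of :func:`save_fixture` (bit-exact round trip for pixels)."""
    path = Path(path)
    if path.suffix.lower() == ".npz":
        z = np.load(path)
        clip = FrameClip(frames=z["frames"], fps=float(z["fps"]),
                         subject_id=str(z.get("subject_id", "")),
                         clip_id=str(z.get("clip_id", "")))
        bvp = None
        if "bvp" in z:
            bvp = BVPRecord(wave=z["bvp"], fps=clip.fps)
        return FixtureSample(clip=clip, bvp=bvp)
    with h5py.File(path, "r") as f:
        clip = FrameClip(frames=f["frames"][...], fps=float(f.attrs["fps"]),
                         subject_id=str(f.attrs.get("subject_id", "")),
                         clip_id=str(f.attrs.get("clip_id", "")),
                         t0=int(f.attrs.get("t0", 0)))
        bvp = None
        if "bvp" in f:
            hr = f.attrs.get("hr_ref")
            bvp = BVPRecord(wave=f["bvp"][...], fps=clip.fps,
                            hr_ref=float(hr) if hr is not None else None)
    return FixtureSample(clip=clip, bvp=bvp)
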