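"""Video ingestion and export.

Recordings enter the pipeline as a :class:`VideoSequence` — an ordered stack
of 8-bit frames plus a frame rate.  Sources can be a directory of lexically
ordered image files (PNG/TIFF, bit-exact), a multi-page TIFF stack
(lossless container), or any container imageio can decode with the plugins
available at run time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["VideoSequence", "read_video", "write_video", "to_grayscale", "VideoFormatError"]

#: Default frame rate (Hz) of the home-video corpus this tool was designed
#: around; used only when a source carries no rate metadata.
DEFAULT_FPS = 12.5

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


class VideoFormatError(ValueError):
    """Raised for unreadable, empty or inconsistently sized frame sources."""


@dataclass
class VideoSequence:
    """Ordered frames plus acquisition metadata.

    frames : (n_frames, H, W) or (n_frames, H, W, 3) uint8 array
    fps : sampling rate in Hz (must be > 0)
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise VideoFormatError(
                f"frames must be (N,H,W) or (N,H,W,3), got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise VideoFormatError(f"fps must be positive, got {self.fps}")

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
    def is_color(self) -> bool:
        return self.frames.ndim == 4

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]

    def gray(self, t: int) -> np.ndarray:
        """Frame ``t`` as float32 grayscale."""
        return to_grayscale(self.frames[t]).astype(np.float32)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame to single-channel luma.

    Uses ITU-R BT.601 weights (0.299 R + 0.587 G + 0.114 B), the standard
    definition of luminance for 8-bit video.  Grayscale input is returned
    unchanged, which makes the operation idempotent.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 3:
        luma = frame @ np.array([0.299, 0.587, 0.114])
        return np.round(luma).astype(frame.dtype) if frame.dtype == np.uint8 else luma
    raise VideoFormatError(f"expected HxW or HxWx3 frame, got shape {frame.shape}")


def _read_image_dir(path: Path) -> np.ndarray:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
    if not files:
        raise VideoFormatError(f"no image files found in directory {path}")
    frames = [iio.imread(f) for f in files]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise VideoFormatError(f"mixed frame sizes in {path}: {sorted(shapes)}")
    return np.stack(frames)


def read_video(path: str | os.PathLike, fps_override: float | None = None) -> VideoSequence:
    """Read a video container, TIFF stack, or image-sequence directory.

    ``fps_override`` takes precedence over any container metadata; sources
    without rate metadata (image directories, plain TIFF stacks) fall back
    to 12.5 Hz when no override is given.
    """
    path = Path(path)
    if not path.exists():
        raise VideoFormatError(f"no such video source: {path}")

    fps_meta: float | None = None
    if path.is_dir():
        frames = _read_image_dir(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            try:
                fps_meta = tf.shaped_metadata[0].get("fps")  # type: ignore[union-attr]
            except (TypeError, IndexError, AttributeError):
                fps_meta = None
        if frames.ndim == 2:
            frames = frames[None]
    else:
        try:
            frames = iio.imread(path)
            meta = iio.immeta(path)
            fps_meta = meta.get("fps")
        except Exception as exc:  # codec plugin missing or corrupt file
            raise VideoFormatError(f"cannot decode {path}: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
    if frames.shape[0] < 1:
        raise VideoFormatError(f"empty video source: {path}")
    fps = fps_override if fps_override is not None else (fps_meta or DEFAULT_FPS)
    return VideoSequence(frames=np.ascontiguousarray(frames), fps=float(fps))


def write_video(seq: VideoSequence, path: str | os.PathLike) -> None:
    """Write a sequence losslessly.

    ``.tif``/``.tiff`` targets become a multi-page TIFF stack (fps stored in
    the shaped metadata); a directory target becomes a zero-padded PNG
    sequence.  Both round-trip bit-exactly through :func:`read_video`.
    """
    if seq.n_frames == 0:
        raise VideoFormatError("refusing to write an empty sequence")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, seq.frames, metadata={"fps": seq.fps})
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(5, len(str(seq.n_frames)))
        for t in range(seq.n_frames):
            iio.imwrite(path / f"frame_{t:0{width}d}.png", seq.frames[t])
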