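"""Image-stack container and TIFF input/output.

Conventions used throughout the package:

* frames are indexed ``(frame, row, col)``, 0-based;
* sub-pixel positions use the pixel-centre convention -- the integer
  coordinate ``(i, j)`` is the centre of pixel ``(i, j)``;
* all internal computation is in pixels; physical lengths in output
  tables are micrometres (pixels times ``pixel_width_um``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """An ordered grayscale time-lapse with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``; converted to
        ``float64`` on construction.
    pixel_width_um
        Physical width of one pixel in micrometres.
    frame_interval_s
        Time between successive frames in seconds.
    """

    frames: np.ndarray
    pixel_width_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (frame, row, col); got shape {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise ValueError("stack must contain at least 2 frames")
        if not self.pixel_width_um > 0:
            raise ValueError("pixel_width_um must be positive")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(height, width)`` of one frame."""
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_s


def read_stack(path: str | os.PathLike,
               pixel_width_um: float,
               frame_interval_s: float) -> ImageStack:
    """Read a multi-page TIFF, or a directory of single-page TIFFs, as a stack.

    Files in a directory are taken in lexicographic order.  Frames are
    loaded as floating point; no rescaling is applied.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        frames = [tifffile.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        arr = np.stack(frames)
    elif path.exists():
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    else:
        raise FileNotFoundError(str(path))
    if arr.ndim != 3:
        raise ValueError(f"expected grayscale frames, got array of shape {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("fewer than 2 frames")
    return ImageStack(arr, pixel_width_um, frame_interval_s)


def write_stack(stack: ImageStack,
                path: str | os.PathLike,
                per_frame: bool = False) -> Path:
    """Write a stack as one multi-page TIFF or one TIFF per frame.

    Intensities are stored as 32-bit float without rescaling.  In
    per-frame mode ``path`` is a directory receiving files
    ``frame_000.tif``, ``frame_001.tif``, ... (zero-padded to at least
    three digits).
    """
    path = Path(path)
    data = stack.frames.astype(np.float32)
    if per_frame:
        path.mkdir(parents=True, exist_ok=True)
        width = max(3, len(str(stack.n_frames - 1)))
        for i, frame in enumerate(data):
            tifffile.imwrite(path / f"frame_{i:0{width}d}.tif", frame,
                             photometric="minisblack")
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
    return path
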