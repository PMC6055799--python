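"""Image containers and TIFF I/O.

The whole pipeline operates on :class:`ImageStack`: one or more 2D intensity
frames carrying their physical calibration (pixel size in micrometres, frame
interval in seconds). Single images are stacks with one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A (T, H, W) float intensity stack with physical calibration.

    Parameters
    ----------
    frames:
        Array of shape (T, H, W); a 2D array is promoted to a single frame.
    pixel_size_um:
        Lateral pixel size in micrometres per pixel.
    frame_interval_s:
        Time between consecutive frames in seconds.
    """

    frames: np.ndarray
    pixel_size_um: float = 0.05
    frame_interval_s: float = 2.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"frames must be 2D or 3D, got shape {arr.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        self.frames = arr

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    def frame(self, t: int) -> np.ndarray:
        return self.frames[t]

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval_s


def read_stack(path, pixel_size_um: float = 0.05,
               frame_interval_s: float = 2.0) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`."""
    arr = tifffile.imread(path)
    return ImageStack(np.asarray(arr, dtype=float), pixel_size_um, frame_interval_s)


def write_stack(path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as a multi-page float32 TIFF."""
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a uint8 0/255 single-page TIFF."""
    tifffile.imwrite(path, (np.asarray(mask, bool).astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    """Read a binary mask TIFF (any nonzero pixel is foreground)."""
    return np.asarray(tifffile.imread(path)) > 0
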