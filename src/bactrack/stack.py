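"""Frame-series container and PNG series I/O.

A recorded series is an ordered list of equally sized 8-bit intensity
matrices plus its acquisition metadata (frame rate, pixel size).  Series are
stored on disk as one PNG per frame with zero-padded, lexically sortable
names; reading never modifies the originals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights for colour -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameStack:
    """Ordered raw frames with acquisition metadata.

    frames : list of (h, w) uint8 arrays, all the same shape.
    fps : acquisition frame rate (frames/s).
    pixel_size_nm : physical pixel edge length (nm/px).
    """

    frames: list[np.ndarray] = field(default_factory=list)
    fps: float = 30.0
    pixel_size_nm: float = 94.2

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("fps and pixel_size_nm must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mismatched shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        if not self.frames:
            raise ValueError("empty stack has no shape")
        return self.frames[0].shape

    def as_array(self) -> np.ndarray:
        """All frames as one (n, h, w) array."""
        return np.stack(self.frames)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit frame to single-channel 8-bit intensity.

    Colour frames use fixed BT.601 luma weighting
    (0.299 R + 0.587 G + 0.114 B), rounded to the nearest integer; a frame
    that is already single-channel is returned unchanged.
    """
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    if frame.ndim == 3 and frame.shape[2] == 3:
        gray = frame.astype(np.float64) @ _LUMA
        return np.rint(gray).clip(0, 255).astype(np.uint8)
    if frame.ndim == 3 and frame.shape[2] == 1:
        return frame[:, :, 0].astype(np.uint8, copy=False)
    raise ValueError(f"unsupported channel layout: shape {frame.shape}")


def write_series(stack: FrameStack, directory: str | Path) -> list[Path]:
    """Write one 8-bit PNG per frame; returns the written paths.

    Names are zero-padded (``frame_0000.png`` ...) so a lexical sort
    restores acquisition order; round-trips losslessly with
    :func:`read_series`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(stack.frames) - 1)))
    paths = []
    for i, frame in enumerate(stack.frames):
        path = directory / f"frame_{i:0{width}d}.png"
        iio.imwrite(path, np.ascontiguousarray(frame, dtype=np.uint8))
        paths.append(path)
    return paths


def read_series(directory: str | Path, fps: float = 30.0,
                pixel_size_nm: float = 94.2) -> FrameStack:
    """Load a PNG series in name order into a :class:`FrameStack`.

    Colour frames are converted to grayscale; files that are not readable
    images are skipped with a logged warning.  At least two frames are
    required (differencing needs a pair) and all frames must share
    dimensions.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    frames = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            img = iio.imread(path)
        except Exception:
            logger.warning("skipping unreadable file %s", path)
            continue
        frames.append(to_grayscale(img))
    if len(frames) < 2:
        raise ValueError(f"need at least 2 readable frames in {directory}, "
                         f"found {len(frames)}")
    return FrameStack(frames=frames, fps=fps, pixel_size_nm=pixel_size_nm)
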