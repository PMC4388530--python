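"""Optical acquisition geometry.

The canonical setup is a 40x phase-contrast objective with a GigE camera at
1280 x 960 px and 30 fps, where one pixel images a square of 94.2 nm edge
length; a 30-frame series therefore spans one second and a field of view of
120.6 x 90.4 um.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OpticalConfig:
    """Camera and magnification parameters of a frame series.

    Parameters
    ----------
    pixel_size_nm : float
        Edge length of the square imaged by one pixel, in nanometres.
    fps : float
        Acquisition frame rate, frames per second.
    frames_per_series : int
        Number of frames in one recorded series.
    image_width_px, image_height_px : int
        Sensor resolution in pixels.
    """

    pixel_size_nm: float = 94.2
    fps: float = 30.0
    frames_per_series: int = 30
    image_width_px: int = 1280
    image_height_px: int = 960

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "fps", "frames_per_series",
                     "image_width_px", "image_height_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0


def field_of_view(optics: OpticalConfig) -> tuple[float, float]:
    """Imaged region (width, height) in micrometres, rounded to 1 decimal.

    With the canonical 1280 x 960 px sensor at 94.2 nm/px this is
    (120.6, 90.4) um.
    """
    width = optics.image_width_px * optics.pixel_size_um
    height = optics.image_height_px * optics.pixel_size_um
    return round(width, 1), round(height, 1)
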