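"""Synthetic microscopy scenes with known ground-truth kinematics.

Generates PNG-compatible frame series that emulate what the flow-cell
camera sees once the confining layer has settled: a handful of bright
rod-shaped bacteria swimming in the focal plane over a noisy background,
plus static debris from turbid production media.  Every bacterium follows
a constant-speed random-heading walk (heading perturbed by a Gaussian turn
each step); debris never moves, which is exactly the property the
sum-difference stage exploits to ignore it.  The generator returns the
rendered stack together with per-frame ground-truth centroids and
per-step speeds, so tracking accuracy can be scored without a microscope.

Rendering keeps positions in floating point and rasterizes ellipses with
coverage-weighted anti-aliasing (supersampling), so detected centroids can
legitimately be compared to ground truth at sub-pixel accuracy.  Bodies
leaving the field of view are clipped at the border and their ground truth
ends at the last frame whose true centre is still inside the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import FrameStack

#: supersampling factor per axis for anti-aliased rasterization
_SS = 4


@dataclass
class BacteriumSpec:
    """One swimming rod: start position (px), speed (um/s), initial heading
    (degrees, 0 = +x, 90 = +y i.e. downward on screen), Gaussian per-step
    turn magnitude (degrees), body length/width (um) and peak intensity."""

    start_xy: tuple[float, float]
    speed: float = 50.0
    heading: float = 0.0
    heading_sd_per_step: float = 10.0
    length: float = 2.0
    width: float = 0.7
    intensity: float = 200.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if not self.length >= self.width > 0:
            raise ValueError("need length >= width > 0")


@dataclass
class DebrisSpec:
    """A static undissolved particle: centre (px), radius (um), intensity."""

    center_xy: tuple[float, float]
    radius: float = 0.5
    intensity: float = 150.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class SceneSpec:
    """Full description of a synthetic frame series."""

    width_px: int = 1280
    height_px: int = 960
    n_frames: int = 30
    fps: float = 30.0
    pixel_size_nm: float = 94.2
    background_level: float = 30.0
    noise_sd: float = 5.0
    bacteria: list[BacteriumSpec] = field(default_factory=list)
    debris: list[DebrisSpec] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_frames) < 1:
            raise ValueError("width_px, height_px, n_frames must be >= 1")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fps <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("fps and pixel_size_nm must be positive")


@dataclass
class GroundTruth:
    """True per-frame centroids and per-step speeds.

    ``table`` columns: frame, bacterium_id, x_px, y_px, speed_um_s — one
    row per frame per bacterium while its centre is inside the image;
    ``speed_um_s`` is the speed of the step leaving that frame (NaN on a
    bacterium's last visible frame).
    """

    table: pd.DataFrame

    def mean_speed(self) -> float:
        return float(self.table["speed_um_s"].dropna().mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _paint_ellipse(img: np.ndarray, cx: float, cy: float, a: float, b: float,
                   theta: float, intensity: float) -> None:
    """Alpha-composite an anti-aliased filled ellipse onto ``img``.

    (cx, cy) in px, semi-axes a >= b in px, theta in radians CCW from +x
    in the y-down pixel frame.  Coverage is estimated on an _SS x _SS
    subgrid per pixel.
    """
    h, w = img.shape
    pad = a + 1.5
    x0, x1 = int(np.floor(cx - pad)), int(np.ceil(cx + pad))
    y0, y1 = int(np.floor(cy - pad)), int(np.ceil(cy + pad))
    x0, x1 = max(x0, 0), min(x1, w - 1)
    y0, y1 = max(y0, 0), min(y1, h - 1)
    if x0 > x1 or y0 > y1:
        return
    sub = (np.arange(_SS) + 0.5) / _SS
    xs = x0 + np.add.outer(np.arange(x1 - x0 + 1), sub).ravel()
    ys = y0 + np.add.outer(np.arange(y1 - y0 + 1), sub).ravel()
    dx = xs - cx
    dy = ys[:, None] - cy
    c, s = np.cos(theta), np.sin(theta)
    u = dx[None, :] * c + dy * s
    v = -dx[None, :] * s + dy * c
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cov = inside.reshape(y1 - y0 + 1, _SS, x1 - x0 + 1, _SS).mean(axis=(1, 3))
    region = img[y0:y1 + 1, x0:x1 + 1]
    region[:] = region * (1.0 - cov) + intensity * cov


def render_scene(spec: SceneSpec) -> tuple[FrameStack, GroundTruth]:
    """Render a scene to a frame stack plus its ground truth.

    Bacteria advance ``speed / fps`` micrometres per frame along a heading
    perturbed by N(0, heading_sd_per_step) degrees each step; debris is
    rendered identically in every frame; i.i.d. Gaussian noise of the
    specified sd is added and the result clipped to [0, 255].  Identical
    spec and seed give bit-identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    px_um = spec.pixel_size_nm / 1000.0
    h, w = spec.height_px, spec.width_px

    for i, b in enumerate(spec.bacteria):
        x, y = b.start_xy
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"bacterium {i} starts outside the image: "
                             f"{b.start_xy}")

    # simulate kinematics first so rendering cannot perturb the RNG stream
    paths = []  # per bacterium: list of (x, y, heading_rad)
    for b in spec.bacteria:
        step_px = b.speed / spec.fps / px_um
        x, y = b.start_xy
        heading = np.radians(b.heading)
        pts = [(x, y, heading)]
        for _ in range(spec.n_frames - 1):
            heading += np.radians(rng.normal(0.0, b.heading_sd_per_step)) \
                if b.heading_sd_per_step > 0 else 0.0
            x += step_px * np.cos(heading)
            y += step_px * np.sin(heading)
            pts.append((x, y, heading))
        paths.append(pts)

    base = np.full((h, w), float(spec.background_level))
    for d in spec.debris:
        r_px = d.radius / px_um
        _paint_ellipse(base, d.center_xy[0], d.center_xy[1], r_px, r_px,
                       0.0, d.intensity)

    frames = []
    gt_rows = []
    for f in range(spec.n_frames):
        img = base.copy()
        for bid, (b, pts) in enumerate(zip(spec.bacteria, paths)):
            x, y, heading = pts[f]
            a_px = (b.length / 2.0) / px_um
            b_px = (b.width / 2.0) / px_um
            _paint_ellipse(img, x, y, a_px, b_px, heading, b.intensity)
            if 0 <= x < w and 0 <= y < h:
                if f + 1 < spec.n_frames:
                    x1, y1, _ = pts[f + 1]
                    step = np.hypot(x1 - x, y1 - y)
                    speed = step * px_um * spec.fps
                else:
                    speed = np.nan
                gt_rows.append({"frame": f, "bacterium_id": bid,
                                "x_px": x, "y_px": y, "speed_um_s": speed})
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames.append(np.rint(img).clip(0, 255).astype(np.uint8))

    gt = pd.DataFrame(gt_rows, columns=["frame", "bacterium_id", "x_px",
                                        "y_px", "speed_um_s"])
    stack = FrameStack(frames=frames, fps=spec.fps,
                       pixel_size_nm=spec.pixel_size_nm)
    return stack, GroundTruth(table=gt)


def random_scene(n_bacteria: int | None = None, seed: int = 0,
                 speed_range: tuple[float, float] = (40.0, 60.0),
                 noise_sd: float = 5.0, width_px: int = 1280,
                 height_px: int = 960, n_frames: int = 30,
                 heading_sd_per_step: float = 10.0,
                 margin_px: int = 120) -> SceneSpec:
    """A randomized scene at canonical optics.

    Draws ``n_bacteria`` (default uniform in the 5-10 optimum range) with
    speeds uniform in ``speed_range``, random headings and start positions
    kept ``margin_px`` away from the border so most bodies stay in view
    for the whole second.
    """
    rng = np.random.default_rng(seed)
    if n_bacteria is None:
        n_bacteria = int(rng.integers(5, 11))
    bacteria = []
    for _ in range(n_bacteria):
        x = rng.uniform(margin_px, width_px - margin_px)
        y = rng.uniform(margin_px, height_px - margin_px)
        bacteria.append(BacteriumSpec(
            start_xy=(float(x), float(y)),
            speed=float(rng.uniform(*speed_range)),
            heading=float(rng.uniform(0.0, 360.0)),
            heading_sd_per_step=heading_sd_per_step))
    return SceneSpec(width_px=width_px, height_px=height_px,
                     n_frames=n_frames, noise_sd=noise_sd,
                     bacteria=bacteria, rng_seed=int(rng.integers(2 ** 31)))
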