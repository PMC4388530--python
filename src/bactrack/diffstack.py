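"""Sum-difference imaging: isolate moving objects in a frame series.

For each frame A_k of a series the indexed serial subtraction accumulates
the component-wise absolute differences against every other frame,

    B_k = sum_{j != k} abs(A_k - A_j),

so pixels whose intensity never changes (background, static debris in
turbid media) cancel exactly, while a swimming bacterium lights up strongly
at its frame-k position (it differs from ~all other frames there) and only
faintly at the positions it occupies in other frames.  Denoising subtracts
twice the global pixel mean, clips negatives to zero, and rescales the
contrast to the full 0-255 range.

Accumulation runs in 32-bit integers: a sum of 29 absolute 8-bit
differences can reach 29 * 255, far beyond the 8-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import FrameStack


@dataclass
class SumDiffImage:
    """Per-frame accumulated absolute-difference image.

    values : (h, w) non-negative array; int32 while un-normalized, uint8
        after :func:`denoise_normalize`.
    source_index : index k of the frame the image was accumulated for.
    normalized : whether denoise/contrast normalization has been applied.
    """

    values: np.ndarray
    source_index: int
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("sum-difference image must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("sum-difference values must be non-negative")


def sum_difference(stack: FrameStack, k: int) -> SumDiffImage:
    """Indexed serial subtraction for frame ``k``.

    Returns the un-normalized B_k = sum over j != k of |A_k - A_j|,
    computed component-wise in int32.  The result is invariant to the
    ordering of the non-current frames.
    """
    n = len(stack)
    if n < 2:
        raise ValueError("need at least 2 frames for differencing")
    if not 0 <= k < n:
        raise IndexError(f"frame index {k} out of range for {n} frames")
    arr = stack.as_array().astype(np.int32)
    diffs = np.abs(arr - arr[k])
    return SumDiffImage(values=diffs.sum(axis=0), source_index=k,
                        normalized=False)


def sum_difference_stack(stack: FrameStack) -> list[SumDiffImage]:
    """B_k for every frame of the series (one pass, shared int32 cast)."""
    n = len(stack)
    if n < 2:
        raise ValueError("need at least 2 frames for differencing")
    arr = stack.as_array().astype(np.int32)
    out = []
    for k in range(n):
        values = np.abs(arr - arr[k]).sum(axis=0)
        out.append(SumDiffImage(values=values, source_index=k,
                                normalized=False))
    return out


def denoise_normalize(b: SumDiffImage) -> SumDiffImage:
    """Remove accumulated noise and normalize contrast to 0-255.

    Twice the global pixel mean is subtracted (negative values are set to
    zero), then the survivors are linearly rescaled so the maximum is 255.
    An image with nothing left after subtraction (e.g. a static scene)
    comes back all-zero rather than raising; downstream detection then
    reports zero particles.
    """
    if b.normalized:
        raise ValueError("input is already normalized")
    values = b.values.astype(np.float64)
    values = np.clip(values - 2.0 * values.mean(), 0.0, None)
    peak = values.max()
    if peak > 0:
        values = values * (255.0 / peak)
    out = np.rint(values).clip(0, 255).astype(np.uint8)
    return SumDiffImage(values=out, source_index=b.source_index,
                        normalized=True)
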