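"""Image pipeline: corral video stack -> "percent area covered per worm".

The locomotion score for one trial is computed from a ~2-minute, 1 Hz
grayscale recording of a group of worms confined in a corral:

1. per-pixel **median** across frames estimates the static background
   (agar, corral wall, uneven illumination);
2. the absolute difference of each frame from that background isolates
   moving worm bodies regardless of whether worms image darker or
   brighter than the agar;
3. a **maximum-intensity projection** across time collapses the stack to
   the union of everywhere a worm body went;
4. the projection is binarised with the **IsoData** (Ridler-Calvard
   iterative-intermeans) automatic threshold, which is robust to uneven
   lighting;
5. the fraction of the corral region above threshold, divided by the
   number of worms in the group, is the **area covered per worm**.

Sluggish, narrowly bending (intoxicated) worms visit less area, so the
score drops with intoxication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import tifffile

logger = logging.getLogger("wormloco")

__all__ = [
    "ImageStack",
    "CorralROI",
    "AreaScore",
    "NoForegroundError",
    "median_background",
    "subtract_background",
    "max_projection",
    "isodata_threshold",
    "area_score",
    "score_trial",
]


class NoForegroundError(ValueError):
    """Raised when an image has no contrast to threshold (constant in the ROI)."""


@dataclass
class ImageStack:
    """A T x H x W grayscale time-lapse recording of one corral.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative intensities, one page per time point.
    bit_depth : {8, 16}
        Intensity scale of the source data.
    frame_rate : float
        Frames per second (the assay records at 1 Hz).
    """

    frames: np.ndarray
    bit_depth: int = 8
    frame_rate: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("an image stack needs at least 2 frames")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if np.any(np.asarray(self.frames[0], dtype=float) < 0):
            raise ValueError("frame intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @classmethod
    def from_tiff(cls, path, frame_rate: float = 1.0) -> "ImageStack":
        """Load a multi-page grayscale TIFF as a stack."""
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        bit_depth = 16 if frames.dtype.itemsize > 1 else 8
        return cls(frames=frames, bit_depth=bit_depth, frame_rate=frame_rate)

    def to_tiff(self, path) -> None:
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        tifffile.imwrite(path, np.asarray(self.frames, dtype=dtype))


@dataclass
class CorralROI:
    """Analysis region (the cropped corral) as a boolean mask over a frame.

    Pixel coordinates are 0-based; rectangles use half-open bounds
    [y0, y1) x [x0, x1).
    """

    mask: np.ndarray
    shape_kind: str = "rectangle"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def rectangle(cls, frame_shape, y0: int, y1: int, x0: int, x1: int) -> "CorralROI":
        h, w = frame_shape
        if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
            raise ValueError("rectangle bounds outside frame")
        mask = np.zeros((h, w), dtype=bool)
        mask[y0:y1, x0:x1] = True
        return cls(mask=mask, shape_kind="rectangle")

    @classmethod
    def circle(cls, frame_shape, center, radius: float) -> "CorralROI":
        h, w = frame_shape
        cy, cx = center
        yy, xx = np.ogrid[:h, :w]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        if not mask.any():
            raise ValueError("circular ROI does not cover any pixel")
        return cls(mask=mask, shape_kind="circle")

    @classmethod
    def full(cls, frame_shape) -> "CorralROI":
        return cls(mask=np.ones(frame_shape, dtype=bool), shape_kind="rectangle")


@dataclass
class AreaScore:
    """Foreground statistics and the per-worm locomotion score for one trial."""

    foreground_pixels: int
    total_pixels: int
    n_worms: int
    threshold_used: Optional[float] = None
    no_foreground: bool = False

    @property
    def area_fraction(self) -> float:
        return self.foreground_pixels / self.total_pixels

    @property
    def area_per_worm(self) -> float:
        return self.area_fraction / self.n_worms

    def __post_init__(self) -> None:
        if self.n_worms < 1:
            raise ValueError("n_worms must be >= 1")
        if not 0 <= self.foreground_pixels <= self.total_pixels:
            raise ValueError("foreground count outside [0, ROI area]")


def median_background(stack: ImageStack) -> np.ndarray:
    """Per-pixel median across all frames.

    A pixel occupied by a moving worm in fewer than half of the frames
    takes its background value, so the median image is worm-free for
    sufficiently mobile animals.  Even frame counts use the mean of the
    two central order statistics.
    """
    return np.median(np.asarray(stack.frames, dtype=float), axis=0)


def subtract_background(stack: ImageStack, background: np.ndarray) -> np.ndarray:
    """Per-pixel absolute difference |frame - background|.

    The absolute value makes the pipeline polarity-agnostic: worms that
    image darker than the agar and worms that image brighter both yield
    positive responses.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != stack.frame_shape:
        raise ValueError(
            f"background shape {background.shape} does not match frames {stack.frame_shape}"
        )
    return np.abs(np.asarray(stack.frames, dtype=float) - background)


def max_projection(diff_stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection across time (union of worm responses)."""
    diff_stack = np.asarray(diff_stack, dtype=float)
    if diff_stack.ndim != 3 or diff_stack.shape[0] < 1:
        raise ValueError("diff stack must be T x H x W with T >= 1")
    return diff_stack.max(axis=0)


N_BINS = 256


def isodata_threshold(image: np.ndarray, roi: CorralROI) -> float:
    """Ridler-Calvard iterative-intermeans (IsoData) threshold of ROI pixels.

    ROI intensities are linearly rescaled onto a 256-bin histogram
    (min-max rescaling).  Starting from the histogram midpoint the
    threshold bin is iterated as t <- (mean below-or-at t + mean above
    t) / 2 until the bin index is stable, then mapped back to the
    original intensity scale.  Foreground is defined downstream as
    strictly greater than the returned threshold.

    Raises
    ------
    NoForegroundError
        If the ROI is constant (no contrast to split).
    """
    vals = np.asarray(image, dtype=float)[roi.mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax == vmin:
        raise NoForegroundError("image is constant within the ROI; nothing to threshold")

    counts, _ = np.histogram(vals, bins=N_BINS, range=(vmin, vmax))
    idx = np.arange(N_BINS)
    csum = np.cumsum(counts)
    cmom = np.cumsum(counts * idx)
    total_n, total_m = csum[-1], cmom[-1]

    t = N_BINS // 2 - 1  # histogram midpoint
    for _ in range(N_BINS):
        n_low = csum[t]
        if n_low == 0:  # nothing at or below t: move up
            t += 1
            continue
        if n_low == total_n:  # everything at or below t: move down
            t -= 1
            continue
        m_low = cmom[t] / n_low
        m_high = (total_m - cmom[t]) / (total_n - n_low)
        t_new = int(round((m_low + m_high) / 2.0))
        if t_new == t:
            break
        t = t_new

    # map the stable bin index back to the intensity scale (bin centre)
    threshold = vmin + (t + 0.5) * (vmax - vmin) / N_BINS
    logger.debug("isodata threshold: bin %d -> intensity %.4f", t, threshold)
    return threshold


def area_score(binary: np.ndarray, roi: CorralROI, n_worms: int,
               threshold_used: Optional[float] = None) -> AreaScore:
    """Count foreground pixels within the ROI and form the per-worm score."""
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != roi.mask.shape:
        raise ValueError("binary image and ROI mask shapes differ")
    fg = int(np.count_nonzero(binary & roi.mask))
    return AreaScore(
        foreground_pixels=fg,
        total_pixels=roi.area,
        n_worms=int(n_worms),
        threshold_used=threshold_used,
    )


def score_trial(stack: ImageStack, roi: CorralROI, n_worms: int) -> AreaScore:
    """Full pipeline for one trial: stack -> AreaScore.

    Composition of median background, absolute-difference subtraction,
    maximum projection, IsoData threshold and foreground counting.  A
    stack with no contrast (e.g. no worms, no noise) yields a zero score
    flagged ``no_foreground`` rather than an error.
    """
    if roi.mask.shape != stack.frame_shape:
        raise ValueError("ROI mask does not match frame shape")
    background = median_background(stack)
    diff = subtract_background(stack, background)
    projection = max_projection(diff)
    try:
        threshold = isodata_threshold(projection, roi)
    except NoForegroundError:
        logger.info("no foreground detected (constant projection); score set to 0")
        return AreaScore(
            foreground_pixels=0,
            total_pixels=roi.area,
            n_worms=int(n_worms),
            threshold_used=None,
            no_foreground=True,
        )
    binary = projection > threshold
    score = area_score(binary, roi, n_worms, threshold_used=threshold)
    logger.debug(
        "trial scored: threshold=%.4f fg=%d/%d area/worm=%.6f",
        threshold, score.foreground_pixels, score.total_pixels, score.area_per_worm,
    )
    return score
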