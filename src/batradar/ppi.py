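"""Quantized PPI (plan position indicator) radar image handling.

The radar display quantizes echo strength into 32 intensity levels
(0-31) on a north-up pixel grid with the radar at a fixed origin pixel
(3.027 m/pixel at the 1.5 km range setting, pixel area 9.16 m2).
This module provides pixel geometry (center-to-center distances and
clockwise-from-north bearings), clutter-threshold visibility masks over
angular sectors, and the echo-visibility procedure applied to stacks of
consecutive scans: an echo sample passes in one scan when the 3x3 pixel
matrix around its brightest pixel has a mean intensity at or above 25,
and the sample point is "visible" when more than 5 of 11 scans pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Tuple, Union

import numpy as np

__all__ = [
    "PpiImage",
    "SectorSpec",
    "VisibilityMask",
    "EchoStack",
    "visibility_mask",
    "echo_matrix_mean",
    "stack_visibility",
    "max_visible_distance",
]

N_LEVELS = 32
DEFAULT_METERS_PER_PIXEL = 3.027
#: Echo-visibility thresholds of the analysis procedure.
MEAN_INTENSITY_THRESHOLD = 25
VISIBLE_COUNT_THRESHOLD = 5
STACK_FRAMES = 11


@dataclass(frozen=True)
class PpiImage:
    """A level-quantized radar image with its pixel geometry.

    ``levels`` holds integers 0..31, row 0 at the top (north); bearings
    are measured clockwise from north.  ``radar_origin`` is the (row,
    col) pixel of the antenna.
    """

    levels: np.ndarray
    meters_per_pixel: float = DEFAULT_METERS_PER_PIXEL
    radar_origin: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.ndim != 2:
            raise ValueError("levels must be a 2-D grid")
        if lv.min() < 0 or lv.max() >= N_LEVELS:
            raise ValueError(f"levels must lie in [0, {N_LEVELS - 1}]")
        r, c = self.radar_origin
        if not (0 <= r < lv.shape[0] and 0 <= c < lv.shape[1]):
            raise ValueError("radar origin must lie inside the image")
        object.__setattr__(self, "levels", lv.astype(np.int16))

    @property
    def pixel_area_m2(self) -> float:
        return self.meters_per_pixel**2

    def pixel_distances_m(self) -> np.ndarray:
        """Center-to-center distance of every pixel from the radar origin."""
        r0, c0 = self.radar_origin
        rows = np.arange(self.levels.shape[0])[:, None]
        cols = np.arange(self.levels.shape[1])[None, :]
        return self.meters_per_pixel * np.hypot(rows - r0, cols - c0)

    def pixel_bearings_deg(self) -> np.ndarray:
        """Bearing of every pixel, degrees clockwise from north (up)."""
        r0, c0 = self.radar_origin
        rows = np.arange(self.levels.shape[0])[:, None]
        cols = np.arange(self.levels.shape[1])[None, :]
        east = cols - c0
        north = r0 - rows
        return np.degrees(np.arctan2(east, north)) % 360.0

    def same_geometry(self, other: "PpiImage") -> bool:
        return (
            self.levels.shape == other.levels.shape
            and self.radar_origin == other.radar_origin
            and np.isclose(self.meters_per_pixel, other.meters_per_pixel)
        )

    # --- I/O -----------------------------------------------------------

    def to_text(self, path: Union[str, Path]) -> None:
        """Portable text matrix of levels (whitespace-separated ints)."""
        np.savetxt(path, self.levels, fmt="%d")

    @classmethod
    def from_text(
        cls,
        path: Union[str, Path],
        meters_per_pixel: float = DEFAULT_METERS_PER_PIXEL,
        radar_origin: Tuple[int, int] = (0, 0),
    ) -> "PpiImage":
        lv = np.loadtxt(path, dtype=int, ndmin=2)
        return cls(levels=lv, meters_per_pixel=meters_per_pixel, radar_origin=radar_origin)

    def to_png(self, path: Union[str, Path]) -> None:
        """8-bit grayscale PNG with gray = level * 8."""
        from PIL import Image

        Image.fromarray((self.levels * 8).astype(np.uint8), mode="L").save(path)

    @classmethod
    def from_png(
        cls,
        path: Union[str, Path],
        meters_per_pixel: float = DEFAULT_METERS_PER_PIXEL,
        radar_origin: Tuple[int, int] = (0, 0),
    ) -> "PpiImage":
        """8-bit grayscale ingestion: level = floor(gray / 8)."""
        from PIL import Image

        gray = np.asarray(Image.open(path).convert("L"))
        return cls(
            levels=(gray // 8).astype(np.int16),
            meters_per_pixel=meters_per_pixel,
            radar_origin=radar_origin,
        )


@dataclass(frozen=True)
class SectorSpec:
    """An angular image sector: bearings clockwise from ``start`` to
    ``end`` (degrees from north, [start, end) half-open), out to
    ``max_range_m``.  start == end denotes the full circle."""

    start_bearing_deg: float
    end_bearing_deg: float
    max_range_m: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_bearing_deg < 360 and 0 <= self.end_bearing_deg < 360):
            raise ValueError("bearings must lie in [0, 360)")
        if self.max_range_m <= 0:
            raise ValueError("max_range must be strictly positive")

    @property
    def angle_deg(self) -> float:
        if self.start_bearing_deg == self.end_bearing_deg:
            return 360.0
        return (self.end_bearing_deg - self.start_bearing_deg) % 360.0

    def contains(self, bearings_deg: np.ndarray) -> np.ndarray:
        b = np.asarray(bearings_deg)
        s, e = self.start_bearing_deg, self.end_bearing_deg
        if s == e:
            return np.ones_like(b, dtype=bool)
        if s < e:
            return (b >= s) & (b < e)
        return (b >= s) | (b < e)

    def complement(self) -> "SectorSpec":
        return SectorSpec(self.end_bearing_deg, self.start_bearing_deg, self.max_range_m)


@dataclass(frozen=True)
class VisibilityMask:
    """Boolean clutter-free mask aligned to a PpiImage, with the pixel
    distances cached for the volume integration."""

    mask: np.ndarray
    distances_m: np.ndarray
    meters_per_pixel: float

    @property
    def visible_count(self) -> int:
        return int(self.mask.sum())

    def to_png(self, path: Union[str, Path]) -> None:
        from PIL import Image

        Image.fromarray(np.where(self.mask, 255, 0).astype(np.uint8), mode="L").save(path)


def visibility_mask(
    image: PpiImage,
    sector: SectorSpec,
    clutter_threshold: int,
) -> VisibilityMask:
    """Clutter-free pixels: inside the sector, within range (0 < distance
    <= max_range, center-to-center) and at level <= clutter_threshold.
    The radar-origin pixel is never visible."""
    if not 0 <= clutter_threshold < N_LEVELS:
        raise ValueError(f"clutter threshold must lie in [0, {N_LEVELS - 1}]")
    dist = image.pixel_distances_m()
    bear = image.pixel_bearings_deg()
    mask = (
        (dist > 0)
        & (dist <= sector.max_range_m)
        & sector.contains(bear)
        & (image.levels <= clutter_threshold)
    )
    return VisibilityMask(mask=mask, distances_m=dist, meters_per_pixel=image.meters_per_pixel)


def echo_matrix_mean(
    image: PpiImage,
    sample_point: Tuple[int, int],
    search_window: int = 11,
) -> Tuple[float, Tuple[int, int]]:
    """Mean intensity of the 3x3 pixel matrix around the brightest pixel
    near a sample point.

    The brightest pixel is searched in a ``search_window`` x
    ``search_window`` box centered on ``sample_point`` (clipped to the
    image).  Ties between equally bright pixels go to the one nearest
    the sample point (then row-major), so a uniform echo block centered
    on the sample point is analysed at its center.  The mean is over the
    3x3 block centered on that peak, excluding cells outside the image.
    Returns (mean_level, peak_pixel).
    """
    if search_window < 1:
        raise ValueError("search window must be at least 1")
    r, c = sample_point
    half = search_window // 2
    r0, r1 = max(0, r - half), min(image.levels.shape[0], r + half + 1)
    c0, c1 = max(0, c - half), min(image.levels.shape[1], c + half + 1)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("search window lies outside the image")
    window = image.levels[r0:r1, c0:c1]
    peak_rows, peak_cols = np.nonzero(window == window.max())
    d2 = (peak_rows + r0 - r) ** 2 + (peak_cols + c0 - c) ** 2
    best = int(np.argmin(d2))  # argmin keeps row-major order on distance ties
    pr, pc = r0 + int(peak_rows[best]), c0 + int(peak_cols[best])
    b0, b1 = max(0, pr - 1), min(image.levels.shape[0], pr + 2)
    d0, d1 = max(0, pc - 1), min(image.levels.shape[1], pc + 2)
    block = image.levels[b0:b1, d0:d1]
    return float(block.mean()), (pr, pc)


@dataclass(frozen=True)
class EchoStack:
    """Consecutive PPI scans of one sample point (default 11 frames)."""

    frames: Tuple[PpiImage, ...]
    sample_point: Tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("stack must contain at least one frame")
        if len(self.frames) % 2 == 0:
            raise ValueError("frame count must be odd")
        first = self.frames[0]
        for f in self.frames[1:]:
            if not first.same_geometry(f):
                raise ValueError("all frames must share the same geometry")


def stack_visibility(
    stack: EchoStack,
    mean_threshold: float = MEAN_INTENSITY_THRESHOLD,
    count_threshold: int = VISIBLE_COUNT_THRESHOLD,
    search_window: int = 11,
) -> Tuple[bool, int]:
    """Apply the echo-visibility rule to an image stack.

    A frame passes when its 3x3 matrix mean is >= ``mean_threshold``;
    the sample point is visible when the pass count v strictly exceeds
    ``count_threshold`` (v > 5 of 11, i.e. more than half the scans).
    Returns (visible, v).
    """
    v = 0
    for frame in stack.frames:
        mean, _ = echo_matrix_mean(frame, stack.sample_point, search_window)
        if mean >= mean_threshold:
            v += 1
    return v > count_threshold, v


def max_visible_distance(
    per_distance_counts: Mapping[float, int],
    total_frames: int = STACK_FRAMES,
    count_threshold: int = VISIBLE_COUNT_THRESHOLD,
) -> Optional[float]:
    """Largest distance whose pass count satisfies the stack rule
    (count > total_frames * count_threshold / 11), or None when no
    distance qualifies."""
    if not per_distance_counts:
        raise ValueError("per-distance counts must be non-empty")
    needed = total_frames * count_threshold / STACK_FRAMES
    visible = []
    for dist, count in per_distance_counts.items():
        if not 0 <= count <= total_frames:
            raise ValueError("counts must lie in [0, total_frames]")
        if count > needed:
            visible.append(dist)
    return max(visible) if visible else None
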