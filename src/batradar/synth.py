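"""Seeded synthetic PPI scenes: clutter blobs, fluctuating point echoes,
echo stacks and paired with/without-fence images.

Real radar imagery of the study site is not distributable, so every
pipeline stage is exercised on synthetic level-quantized scenes that
emulate its structure: extended clutter regions rendered as filled discs
whose per-pixel intensity fluctuates between scans, and point targets
rendered as 3x3 pixel blocks at a polar position.  All randomness comes
from a single integer seed; identical specs render byte-identical
images.

The with/without-fence pair couples the image to the diffraction model:
each clutter pixel of the "with" image is attenuated by the fence's
two-way knife-edge suppression at that pixel's ground position,
converted to display levels through a documented level step (default
3 dB per level — the 32 levels spanning roughly 96 dB of displayed
dynamic range; nothing in the display standard fixes this mapping, so it
is an explicit fixture constant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .diffraction import CsfGeometry, one_way_suppression_db
from .ppi import DEFAULT_METERS_PER_PIXEL, EchoStack, N_LEVELS, PpiImage
from .radar_link import RadarSystem

__all__ = [
    "ClutterBlob",
    "PointEcho",
    "SceneSpec",
    "render_scene",
    "render_stack",
    "render_csf_pair",
]

#: Display levels per dB of echo power (fixture constant, see module doc).
LEVEL_STEP_DB = 3.0

#: Exemplar echo levels: a clearly visible echo (3x3 mean 31) and a
#: too-dim one (mean 18), the two printed reference signatures.
PASS_LEVEL = 31
FAIL_LEVEL = 18


@dataclass(frozen=True)
class ClutterBlob:
    """A filled clutter disc: center pixel, radius in pixels, base
    intensity level and a per-pixel fluctuation amplitude (levels)."""

    center: Tuple[int, int]
    radius_px: float
    base_level: int
    fluctuation: int = 0


@dataclass(frozen=True)
class PointEcho:
    """A point target at a polar position (bearing clockwise from north,
    range in meters), rendered as a 3x3 block of ``mean_level``."""

    bearing_deg: float
    range_m: float
    mean_level: int
    fluctuation: int = 0


@dataclass(frozen=True)
class SceneSpec:
    """Deterministic recipe for a synthetic PPI scene."""

    shape: Tuple[int, int] = (200, 200)
    meters_per_pixel: float = DEFAULT_METERS_PER_PIXEL
    radar_origin: Optional[Tuple[int, int]] = None
    blobs: Tuple[ClutterBlob, ...] = ()
    echoes: Tuple[PointEcho, ...] = ()
    seed: int = 0

    @property
    def origin(self) -> Tuple[int, int]:
        if self.radar_origin is not None:
            return self.radar_origin
        return (self.shape[0] // 2, self.shape[1] // 2)


def _echo_pixel(spec: SceneSpec, echo: PointEcho) -> Tuple[int, int]:
    r0, c0 = spec.origin
    rng_px = echo.range_m / spec.meters_per_pixel
    b = math.radians(echo.bearing_deg)
    row = int(round(r0 - rng_px * math.cos(b)))
    col = int(round(c0 + rng_px * math.sin(b)))
    if not (0 <= row < spec.shape[0] and 0 <= col < spec.shape[1]):
        raise ValueError(f"echo at bearing {echo.bearing_deg}, range {echo.range_m} "
                         "falls outside the image")
    return row, col


def _clutter_mask(spec: SceneSpec) -> np.ndarray:
    mask = np.zeros(spec.shape, dtype=bool)
    rows = np.arange(spec.shape[0])[:, None]
    cols = np.arange(spec.shape[1])[None, :]
    for blob in spec.blobs:
        br, bc = blob.center
        mask |= (rows - br) ** 2 + (cols - bc) ** 2 <= blob.radius_px**2
    return mask


def _render_levels(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    levels = np.zeros(spec.shape, dtype=np.int32)
    rows = np.arange(spec.shape[0])[:, None]
    cols = np.arange(spec.shape[1])[None, :]
    for blob in spec.blobs:
        br, bc = blob.center
        inside = (rows - br) ** 2 + (cols - bc) ** 2 <= blob.radius_px**2
        vals = np.full(spec.shape, blob.base_level, dtype=np.int32)
        if blob.fluctuation > 0:
            vals += rng.integers(-blob.fluctuation, blob.fluctuation + 1, size=spec.shape)
        levels = np.where(inside, np.maximum(levels, vals), levels)
    for echo in spec.echoes:
        er, ec = _echo_pixel(spec, echo)
        val = echo.mean_level
        if echo.fluctuation > 0:
            val = val + int(rng.integers(-echo.fluctuation, echo.fluctuation + 1))
        r0, r1 = max(0, er - 1), min(spec.shape[0], er + 2)
        c0, c1 = max(0, ec - 1), min(spec.shape[1], ec + 2)
        levels[r0:r1, c0:c1] = np.maximum(levels[r0:r1, c0:c1], val)
    return np.clip(levels, 0, N_LEVELS - 1)


def render_scene(spec: SceneSpec) -> PpiImage:
    """Render a scene to a level-quantized PPI image (seeded)."""
    rng = np.random.default_rng(spec.seed)
    return PpiImage(
        levels=_render_levels(spec, rng),
        meters_per_pixel=spec.meters_per_pixel,
        radar_origin=spec.origin,
    )


def render_stack(
    spec: SceneSpec,
    pass_pattern: Sequence[bool],
    frames: int = 11,
) -> EchoStack:
    """Render a stack of consecutive frames of one fluctuating echo.

    The spec must contain exactly one point echo; frame i renders it at
    the pass exemplar level (3x3 mean 31) when ``pass_pattern[i]`` is
    true and the fail exemplar level (mean 18) otherwise, so the planted
    pattern is exactly recoverable by the visibility procedure.
    """
    if len(pass_pattern) != frames:
        raise ValueError("pass_pattern length must equal the frame count")
    if len(spec.echoes) != 1:
        raise ValueError("render_stack requires a spec with exactly one echo")
    echo = spec.echoes[0]
    sample_point = _echo_pixel(spec, echo)
    imgs = []
    for i, passes in enumerate(pass_pattern):
        level = PASS_LEVEL if passes else FAIL_LEVEL
        frame_spec = SceneSpec(
            shape=spec.shape,
            meters_per_pixel=spec.meters_per_pixel,
            radar_origin=spec.radar_origin,
            blobs=spec.blobs,
            echoes=(PointEcho(echo.bearing_deg, echo.range_m, level, 0),),
            seed=spec.seed + i,
        )
        imgs.append(render_scene(frame_spec))
    return EchoStack(frames=tuple(imgs), sample_point=sample_point)


def render_csf_pair(
    spec: SceneSpec,
    geom: CsfGeometry,
    system: RadarSystem,
    level_step_db: float = LEVEL_STEP_DB,
) -> Tuple[PpiImage, PpiImage]:
    """Render a (without-fence, with-fence) image pair.

    The "with" image equals the "without" image except that every
    clutter pixel beyond the fence radius has its level reduced by
    round(two_way_suppression_dB / level_step_db), floored at 0, using
    the knife-edge suppression of ``geom`` at ground level (height 0) and
    the pixel's distance.  Point echoes (airborne targets) are untouched.
    """
    without = render_scene(spec)
    clutter = _clutter_mask(spec)
    dist = without.pixel_distances_m()
    beyond = dist > geom.fence_radius_m
    affected = clutter & beyond
    levels_with = without.levels.astype(np.int32).copy()
    if np.any(affected):
        d = dist[affected]
        one_way = one_way_suppression_db(geom, [0.0], d, system.wavelength_m)[0]
        drop = np.round(2.0 * one_way / level_step_db).astype(int)
        levels_with[affected] = np.maximum(levels_with[affected] - drop, 0)
    with_img = PpiImage(
        levels=np.clip(levels_with, 0, N_LEVELS - 1),
        meters_per_pixel=spec.meters_per_pixel,
        radar_origin=spec.origin,
    )
    return without, with_img
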