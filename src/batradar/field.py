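"""2D received-power field over (distance, height) and detection boundaries.

The vertical cross section of the detection volume is simulated on a
regular grid: for every (distance d, height h) cell the slant range and
elevation angle from the antenna phase center at (0, h_R) determine the
echo power through the radar equation and the vertical gain pattern.
With a clutter shielding fence present ("advanced" mode) the power is
further scaled by the squared normalized knife-edge intensity for that
cell.  Cells at or above the minimum detectable signal power form the
detection region; its upper (and, behind a fence, lower) envelope is the
detection boundary from which per-distance detection heights are read.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .antenna import AntennaPattern, gain_at_clipped
from .diffraction import CsfGeometry, edge_fresnel_v, knife_edge_intensity
from .radar_link import PowerLevel, RadarSystem

__all__ = [
    "FieldMode",
    "PowerField",
    "DetectionBoundary",
    "simulate_field",
    "extract_boundary",
    "detection_height_at",
]


class FieldMode(str, enum.Enum):
    SIMPLE = "simple"
    ADVANCED = "advanced"


@dataclass(frozen=True)
class PowerField:
    """Echo power P_r (or P_rm) in watts on a (height x distance) grid."""

    distances_m: np.ndarray
    heights_m: np.ndarray
    power_w: np.ndarray  # shape (len(heights), len(distances))
    mode: FieldMode

    def __post_init__(self) -> None:
        if self.power_w.shape != (len(self.heights_m), len(self.distances_m)):
            raise ValueError("power grid shape inconsistent with axes")

    def power_dbm(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.power_w / 1e-3)

    def export_dbm(self, path: Union[str, Path]) -> None:
        """Write the field as a dBm matrix with axis headers (TSV)."""
        with open(path, "w") as fh:
            fh.write("height_m\\distance_m\t" + "\t".join(f"{d:g}" for d in self.distances_m) + "\n")
            dbm = self.power_dbm()
            for h, row in zip(self.heights_m, dbm):
                fh.write(f"{h:g}\t" + "\t".join(f"{p:.3f}" for p in row) + "\n")


@dataclass(frozen=True)
class DetectionBoundary:
    """Per-distance detectable height intervals and the maximum range.

    ``intervals[j]`` lists the (low, high) height intervals (meters,
    disjoint, ordered) that are detectable at ``distances_m[j]``.  In
    simple mode there is at most one interval per distance starting at
    the bottom of the height grid.
    """

    distances_m: np.ndarray
    intervals: Tuple[Tuple[Tuple[float, float], ...], ...]
    max_range_m: float

    def export(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("distance_m\tinterval_low_m\tinterval_high_m\n")
            for d, ivs in zip(self.distances_m, self.intervals):
                for lo, hi in ivs:
                    fh.write(f"{d:g}\t{lo:g}\t{hi:g}\n")


def simulate_field(
    system: RadarSystem,
    pattern: AntennaPattern,
    sigma_m2: float,
    geom: Optional[CsfGeometry] = None,
    distances_m: Optional[Sequence[float]] = None,
    heights_m: Optional[Sequence[float]] = None,
) -> PowerField:
    """Simulate the 2D echo-power field for a target of cross section
    ``sigma_m2``.

    Default grid: distances 5..1200 m in 5 m steps, heights 0..300 m in
    1 m steps.  With ``geom`` given, the squared knife-edge factor of the
    fence edge is applied to every cell (advanced mode).
    """
    if sigma_m2 <= 0:
        raise ValueError("sigma must be strictly positive")
    if distances_m is None:
        # default grid starts beyond the fence radius in advanced mode
        start = 5.0
        if geom is not None:
            start = 5.0 * math.floor(geom.fence_radius_m / 5.0 + 1.0)
        d = np.arange(start, 1200.0 + 2.5, 5.0)
    else:
        d = np.asarray(distances_m, dtype=float)
    h = (
        np.arange(0.0, 300.0 + 0.5, 1.0)
        if heights_m is None
        else np.asarray(heights_m, dtype=float)
    )
    if d.size == 0 or h.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(d <= 0):
        raise ValueError("distances must be strictly positive")
    if geom is not None and d.min() <= geom.fence_radius_m:
        raise ValueError("distance grid must start beyond the fence radius")

    hr = system.antenna_height_m
    dz = h[:, None] - hr
    dd = d[None, :]
    slant = np.hypot(dd, dz)
    elev = np.degrees(np.arctan2(dz, dd))
    gain = gain_at_clipped(pattern, elev)

    lam = system.wavelength_m
    const = system.transmit_power_w * lam**2 * sigma_m2 / ((4.0 * np.pi) ** 3)
    power = const * gain**2 / slant**4

    mode = FieldMode.SIMPLE
    if geom is not None:
        v1 = edge_fresnel_v(geom, dd, h[:, None], lam)
        intensity = knife_edge_intensity(v1)
        power = power * intensity**2
        mode = FieldMode.ADVANCED
    return PowerField(distances_m=d, heights_m=h, power_w=power, mode=mode)


def extract_boundary(field: PowerField, pmin: PowerLevel) -> DetectionBoundary:
    """Detection boundary: per distance, the maximal contiguous height
    intervals with power >= pmin; max_range is the largest distance with
    any detectable cell (0 when nowhere detectable)."""
    detectable = field.power_w >= pmin.watts
    h = field.heights_m
    intervals: List[Tuple[Tuple[float, float], ...]] = []
    max_range = 0.0
    for j, d in enumerate(field.distances_m):
        col = detectable[:, j]
        ivs = []
        # run-length extraction over the height column
        edges = np.flatnonzero(np.diff(np.concatenate(([0], col.view(np.int8), [0]))))
        for lo_i, hi_i in zip(edges[::2], edges[1::2]):
            ivs.append((float(h[lo_i]), float(h[hi_i - 1])))
        intervals.append(tuple(ivs))
        if ivs:
            max_range = float(d)
    return DetectionBoundary(
        distances_m=field.distances_m,
        intervals=tuple(intervals),
        max_range_m=max_range,
    )


def detection_height_at(boundary: DetectionBoundary, distance_m: float) -> float:
    """Total detectable height extent (sum of interval extents, meters) at
    the nearest grid distance; 0 beyond the maximum range."""
    if distance_m > boundary.max_range_m:
        return 0.0
    j = int(np.argmin(np.abs(boundary.distances_m - distance_m)))
    return float(sum(hi - lo for lo, hi in boundary.intervals[j]))


def detection_heights(boundary: DetectionBoundary, distances_m: np.ndarray) -> np.ndarray:
    """Vectorized :func:`detection_height_at` for many query distances."""
    extents = np.array(
        [sum(hi - lo for lo, hi in ivs) for ivs in boundary.intervals]
    )
    grid = np.asarray(boundary.distances_m, dtype=float)
    q = np.asarray(distances_m, dtype=float)
    idx = np.clip(np.searchsorted(grid, q), 0, len(grid) - 1)
    # searchsorted gives the right neighbor; pick the nearer of the two
    left = np.clip(idx - 1, 0, len(grid) - 1)
    idx = np.where(np.abs(grid[left] - q) <= np.abs(grid[idx] - q), left, idx)
    out = extents[idx]
    out = np.where(q > boundary.max_range_m, 0.0, out)
    return out
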