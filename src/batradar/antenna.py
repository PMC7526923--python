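"""Vertical antenna gain pattern G(phi) for the detection-field simulation.

The manufacturer's measured vertical diagram of the slotted waveguide
antenna is not available, so the default is a parametric Gaussian main
lobe: quadratic in dB, -3 dB at the half-power half-width (about +/-10
degrees for a marine slot antenna), peak at the data-sheet gain.
Tabulated patterns (two-column text: elevation_deg, gain_dBi) can be
loaded instead, e.g. to include sidelobes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .units import db_to_linear


@dataclass(frozen=True)
class AntennaPattern:
    """Sampled vertical gain pattern, interpolated linearly in dB."""

    elevations_deg: np.ndarray
    gains_linear: np.ndarray
    peak_gain: float

    def __post_init__(self) -> None:
        el = np.asarray(self.elevations_deg, dtype=float)
        g = np.asarray(self.gains_linear, dtype=float)
        if el.ndim != 1 or el.shape != g.shape:
            raise ValueError("elevations and gains must be 1-D and equal length")
        if not np.all(np.diff(el) > 0):
            raise ValueError("elevations must be strictly increasing")
        if el[0] > -30.0 or el[-1] < 30.0:
            raise ValueError("pattern must span at least [-30, +30] degrees")
        if not np.isclose(g.max(), self.peak_gain, rtol=1e-9):
            raise ValueError("max sampled gain must equal peak_gain")
        object.__setattr__(self, "elevations_deg", el)
        object.__setattr__(self, "gains_linear", g)

    @property
    def span_deg(self) -> tuple[float, float]:
        return float(self.elevations_deg[0]), float(self.elevations_deg[-1])


def gaussian_pattern(
    peak_gain_dbi: float = 31.6,
    half_power_half_width_deg: float = 10.0,
    span_deg: float = 90.0,
    step_deg: float = 0.1,
) -> AntennaPattern:
    """Parametric Gaussian main lobe: G_dB(phi) = peak - 3*(phi/width)^2.

    Sampled on a ``step_deg`` grid over +/- ``span_deg``.  Exactly -3 dB
    at phi = +/- half_power_half_width_deg.
    """
    if half_power_half_width_deg <= 0:
        raise ValueError("half-power half-width must be strictly positive")
    el = np.arange(-span_deg, span_deg + step_deg / 2, step_deg)
    g_db = peak_gain_dbi - 3.0 * (el / half_power_half_width_deg) ** 2
    return AntennaPattern(
        elevations_deg=el,
        gains_linear=db_to_linear(g_db),
        peak_gain=db_to_linear(peak_gain_dbi),
    )


def gain_at(pattern: AntennaPattern, elevation_deg) -> Union[float, np.ndarray]:
    """Linear gain at the given elevation(s), interpolated linearly in dB.

    Raises for queries outside the sampled span (use
    :func:`gain_at_clipped` in field simulations where out-of-span
    elevations are treated as unilluminated).
    """
    el = np.asarray(elevation_deg, dtype=float)
    lo, hi = pattern.span_deg
    if np.any(el < lo) or np.any(el > hi):
        raise ValueError(f"elevation outside sampled span [{lo}, {hi}] deg")
    g = _interp_db(pattern, el)
    return float(g) if np.isscalar(elevation_deg) else g


def gain_at_clipped(pattern: AntennaPattern, elevation_deg) -> np.ndarray:
    """Like :func:`gain_at` but returns zero gain outside the span."""
    el = np.asarray(elevation_deg, dtype=float)
    lo, hi = pattern.span_deg
    inside = (el >= lo) & (el <= hi)
    g = np.zeros_like(el)
    if np.any(inside):
        g[inside] = _interp_db(pattern, el[inside])
    return g


def _interp_db(pattern: AntennaPattern, el: np.ndarray) -> np.ndarray:
    g_db = 10.0 * np.log10(pattern.gains_linear)
    return 10.0 ** (np.interp(el, pattern.elevations_deg, g_db) / 10.0)


def save_pattern(pattern: AntennaPattern, path: Union[str, Path]) -> None:
    """Write a two-column table (elevation_deg, gain_dBi) with header."""
    g_dbi = 10.0 * np.log10(pattern.gains_linear)
    with open(path, "w") as fh:
        fh.write("elevation_deg\tgain_dbi\n")
        for e, g in zip(pattern.elevations_deg, g_dbi):
            fh.write(f"{e:.6g}\t{g:.10g}\n")


def load_pattern(path: Union[str, Path]) -> AntennaPattern:
    """Read a pattern written by :func:`save_pattern` (header required)."""
    data = np.loadtxt(path, skiprows=1)
    el, g_dbi = data[:, 0], data[:, 1]
    g = db_to_linear(g_dbi)
    return AntennaPattern(elevations_deg=el, gains_linear=g, peak_gain=float(g.max()))
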