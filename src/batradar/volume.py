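"""3D detection-volume integration and fence/threshold optimization.

The detection volume combines the vertical detection boundary with the
horizontally visible (clutter-free) image pixels:

    V = sum over visible pixels p of  A_px * h(d_p)

where ``A_px`` is the pixel footprint area and ``h(d_p)`` the detectable
height extent at the pixel's distance, read from the detection boundary.
A sector volume extrapolates linearly in angle to full-circle operation,
and compares against the hemispherical detection volume of an acoustic
bat detector.  The optimization sweep evaluates the volume over a grid
of fence-to-antenna height differences and clutter thresholds, with and
without the fence, coupling the two fence effects: the modified vertical
boundary (knife-edge diffraction) and the reduced ground clutter on the
image.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

from .antenna import AntennaPattern
from .diffraction import CsfGeometry
from .field import DetectionBoundary, detection_heights, extract_boundary, simulate_field
from .ppi import PpiImage, SectorSpec, VisibilityMask, visibility_mask
from .radar_link import PowerLevel, RadarSystem

__all__ = [
    "VolumeResult",
    "integrate_volume",
    "sector_extrapolate",
    "acoustic_hemisphere_volume",
    "volume_ratio_vs_acoustic",
    "optimization_sweep",
]

M3_PER_KM3 = 1e9


@dataclass(frozen=True)
class VolumeResult:
    """An integrated detection volume and its provenance."""

    total_volume_m3: float
    visible_pixel_count: int
    sector: SectorSpec

    @property
    def total_volume_km3(self) -> float:
        return self.total_volume_m3 / M3_PER_KM3


def integrate_volume(
    mask: VisibilityMask,
    boundary: DetectionBoundary,
    sector: SectorSpec,
) -> VolumeResult:
    """Sum A_px * h(d_p) over the visible pixels.

    Pixels beyond the boundary's maximum range contribute zero height
    and hence zero volume.
    """
    a_px = mask.meters_per_pixel**2
    d = mask.distances_m[mask.mask]
    h = detection_heights(boundary, d)
    return VolumeResult(
        total_volume_m3=float(a_px * h.sum()),
        visible_pixel_count=int(mask.visible_count),
        sector=sector,
    )


def sector_extrapolate(result_or_volume, target_angle_deg: float, sector_angle_deg: Optional[float] = None) -> float:
    """Scale a sector volume linearly in angle (e.g. to 360 degrees)."""
    if isinstance(result_or_volume, VolumeResult):
        volume = result_or_volume.total_volume_m3
        angle = result_or_volume.sector.angle_deg
    else:
        volume = float(result_or_volume)
        if sector_angle_deg is None:
            raise ValueError("sector_angle_deg required when passing a bare volume")
        angle = sector_angle_deg
    if angle <= 0:
        raise ValueError("sector angle must be strictly positive")
    return volume * target_angle_deg / angle


def acoustic_hemisphere_volume(radius_m: float) -> float:
    """Detection volume of an acoustic bat detector modelled as a
    hemisphere of the given microphone range: (2/3) pi r^3."""
    if radius_m <= 0:
        raise ValueError("radius must be strictly positive")
    return (2.0 / 3.0) * math.pi * radius_m**3


def volume_ratio_vs_acoustic(
    sector_volume_m3: float,
    sector_angle_deg: float,
    mic_radius_m: float = 40.0,
) -> Tuple[float, int]:
    """Full-circle radar volume over the acoustic hemisphere volume.

    Returns the raw ratio and the ratio rounded to the nearest ten.
    """
    full = sector_extrapolate(sector_volume_m3, 360.0, sector_angle_deg)
    ratio = full / acoustic_hemisphere_volume(mic_radius_m)
    return ratio, int(round(ratio / 10.0) * 10)


def optimization_sweep(
    system: RadarSystem,
    pattern: AntennaPattern,
    sigma_m2: float,
    pmin: PowerLevel,
    sector: SectorSpec,
    fence_template: CsfGeometry,
    h_cfr_values_m: Sequence[float],
    thresholds: Sequence[int],
    image_pair_fn: Callable[[CsfGeometry], Tuple[PpiImage, PpiImage]],
    distances_m: Optional[Sequence[float]] = None,
    heights_m: Optional[Sequence[float]] = None,
) -> List[Dict[str, float]]:
    """Sweep fence height difference x clutter threshold.

    For each fence-to-antenna height difference h_CFR the antenna height
    is set to fence_height - h_CFR (fence fixed, antenna adjustable, as
    in the field setup).  ``image_pair_fn(geom)`` must return a
    (without-fence, with-fence) image pair for that geometry — see
    :func:`batradar.synth.render_csf_pair` for the synthetic contract.
    Returns one row per combination with the volumes (m^3) with and
    without the fence and their ratio.
    """
    if not h_cfr_values_m or not thresholds:
        raise ValueError("sweep value sets must be non-empty")
    rows: List[Dict[str, float]] = []
    for h_cfr in h_cfr_values_m:
        geom = CsfGeometry(
            fence_height_m=fence_template.fence_height_m,
            fence_radius_m=fence_template.fence_radius_m,
            antenna_height_m=fence_template.fence_height_m - h_cfr,
        )
        sys_h = RadarSystem(
            transmit_power_w=system.transmit_power_w,
            frequency_hz=system.frequency_hz,
            peak_gain=system.peak_gain,
            pulse_length_s=system.pulse_length_s,
            antenna_height_m=geom.antenna_height_m,
            pulse_repetition_frequency_hz=system.pulse_repetition_frequency_hz,
            min_detectable_power_w=system.min_detectable_power_w,
            wavelength_override_m=system.wavelength_override_m,
        )
        img_without, img_with = image_pair_fn(geom)
        if not img_without.same_geometry(img_with):
            raise ValueError("image pair geometries do not match")
        simple = extract_boundary(
            simulate_field(sys_h, pattern, sigma_m2, None, distances_m, heights_m), pmin
        )
        advanced = extract_boundary(
            simulate_field(sys_h, pattern, sigma_m2, geom, distances_m, heights_m), pmin
        )
        for thr in thresholds:
            v_no = integrate_volume(visibility_mask(img_without, sector, thr), simple, sector)
            v_csf = integrate_volume(visibility_mask(img_with, sector, thr), advanced, sector)
            ratio = (
                v_csf.total_volume_m3 / v_no.total_volume_m3
                if v_no.total_volume_m3 > 0
                else float("inf")
            )
            rows.append(
                {
                    "h_cfr_m": float(h_cfr),
                    "threshold": int(thr),
                    "volume_no_csf_m3": v_no.total_volume_m3,
                    "volume_csf_m3": v_csf.total_volume_m3,
                    "ratio": ratio,
                }
            )
    return rows


def write_sweep_table(rows: Sequence[Dict[str, float]], path: Union[str, Path]) -> None:
    """Write sweep rows as a TSV table with header."""
    fields = ["h_cfr_m", "threshold", "volume_no_csf_m3", "volume_csf_m3", "ratio"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in fields})
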