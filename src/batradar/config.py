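"""YAML/JSON config serialization for the core domain objects.

Flat key-value dialect; unknown keys are rejected so that a typo in a
config file fails loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Union

import yaml

from .diffraction import CsfGeometry
from .radar_link import RadarSystem
from .synth import ClutterBlob, PointEcho, SceneSpec
from .units import dbm_to_watts, watts_to_dbm

__all__ = [
    "radar_to_dict",
    "radar_from_dict",
    "csf_to_dict",
    "csf_from_dict",
    "scene_to_dict",
    "scene_from_dict",
    "load_config",
    "save_config",
]

_RADAR_KEYS = {
    "pulse_power_w",
    "frequency_hz",
    "antenna_gain_dbi",
    "pulse_length_s",
    "pulse_repetition_frequency_hz",
    "antenna_height_m",
    "min_detectable_power_dbm",
    "wavelength_override_m",
}

_CSF_KEYS = {"fence_height_m", "fence_radius_m", "antenna_height_m"}


def _check_keys(data: Dict[str, Any], allowed: set, required: set, what: str) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {what} config keys: {sorted(unknown)}")
    missing = required - set(data)
    if missing:
        raise ValueError(f"missing {what} config keys: {sorted(missing)}")


def radar_to_dict(system: RadarSystem) -> Dict[str, Any]:
    d: Dict[str, Any] = {
        "pulse_power_w": system.transmit_power_w,
        "frequency_hz": system.frequency_hz,
        "antenna_gain_dbi": system.peak_gain_dbi,
        "pulse_length_s": system.pulse_length_s,
        "antenna_height_m": system.antenna_height_m,
    }
    if system.pulse_repetition_frequency_hz is not None:
        d["pulse_repetition_frequency_hz"] = system.pulse_repetition_frequency_hz
    if system.min_detectable_power_w is not None:
        d["min_detectable_power_dbm"] = watts_to_dbm(system.min_detectable_power_w)
    if system.wavelength_override_m is not None:
        d["wavelength_override_m"] = system.wavelength_override_m
    return d


def radar_from_dict(data: Dict[str, Any]) -> RadarSystem:
    _check_keys(
        data,
        _RADAR_KEYS,
        {"pulse_power_w", "frequency_hz", "antenna_gain_dbi", "pulse_length_s"},
        "radar",
    )
    pmin = data.get("min_detectable_power_dbm")
    return RadarSystem.from_dbi(
        transmit_power_w=float(data["pulse_power_w"]),
        frequency_hz=float(data["frequency_hz"]),
        peak_gain_dbi=float(data["antenna_gain_dbi"]),
        pulse_length_s=float(data["pulse_length_s"]),
        antenna_height_m=float(data.get("antenna_height_m", 2.0)),
        pulse_repetition_frequency_hz=data.get("pulse_repetition_frequency_hz"),
        min_detectable_power_w=None if pmin is None else dbm_to_watts(float(pmin)),
        wavelength_override_m=data.get("wavelength_override_m"),
    )


def csf_to_dict(geom: CsfGeometry) -> Dict[str, Any]:
    return {
        "fence_height_m": geom.fence_height_m,
        "fence_radius_m": geom.fence_radius_m,
        "antenna_height_m": geom.antenna_height_m,
    }


def csf_from_dict(data: Dict[str, Any]) -> CsfGeometry:
    _check_keys(data, _CSF_KEYS, _CSF_KEYS, "CSF")
    return CsfGeometry(**{k: float(data[k]) for k in _CSF_KEYS})


def scene_to_dict(spec: SceneSpec) -> Dict[str, Any]:
    return {
        "shape": list(spec.shape),
        "meters_per_pixel": spec.meters_per_pixel,
        "radar_origin": None if spec.radar_origin is None else list(spec.radar_origin),
        "seed": spec.seed,
        "blobs": [
            {
                "center": list(b.center),
                "radius_px": b.radius_px,
                "base_level": b.base_level,
                "fluctuation": b.fluctuation,
            }
            for b in spec.blobs
        ],
        "echoes": [
            {
                "bearing_deg": e.bearing_deg,
                "range_m": e.range_m,
                "mean_level": e.mean_level,
                "fluctuation": e.fluctuation,
            }
            for e in spec.echoes
        ],
    }


def scene_from_dict(data: Dict[str, Any]) -> SceneSpec:
    allowed = {"shape", "meters_per_pixel", "radar_origin", "seed", "blobs", "echoes"}
    _check_keys(data, allowed, {"shape"}, "scene")
    origin = data.get("radar_origin")
    return SceneSpec(
        shape=tuple(data["shape"]),
        meters_per_pixel=float(data.get("meters_per_pixel", 3.027)),
        radar_origin=None if origin is None else tuple(origin),
        seed=int(data.get("seed", 0)),
        blobs=tuple(
            ClutterBlob(
                center=tuple(b["center"]),
                radius_px=float(b["radius_px"]),
                base_level=int(b["base_level"]),
                fluctuation=int(b.get("fluctuation", 0)),
            )
            for b in data.get("blobs", [])
        ),
        echoes=tuple(
            PointEcho(
                bearing_deg=float(e["bearing_deg"]),
                range_m=float(e["range_m"]),
                mean_level=int(e["mean_level"]),
                fluctuation=int(e.get("fluctuation", 0)),
            )
            for e in data.get("echoes", [])
        ),
    )


def load_config(path: Union[str, Path]) -> Dict[str, Any]:
    """Load a YAML (or JSON — YAML is a superset) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def save_config(data: Dict[str, Any], path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(data, fh, sort_keys=True)
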