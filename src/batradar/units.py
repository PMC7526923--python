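"""Unit conversions and physical constants shared across the package."""

import math

#: Speed of light in vacuum, m/s (value used throughout the link budget).
C_LIGHT = 2.998e8


def watts_to_dbm(watts: float) -> float:
    """Convert power in watts to dBm (dB referenced to 1 mW)."""
    if watts <= 0:
        raise ValueError(f"power must be positive to express in dBm, got {watts}")
    return 10.0 * math.log10(watts / 1e-3)


def dbm_to_watts(dbm: float) -> float:
    """Convert power in dBm to watts."""
    return 1e-3 * 10.0 ** (dbm / 10.0)


def db_to_linear(db: float) -> float:
    """Convert a power ratio in dB to a linear factor."""
    return 10.0 ** (db / 10.0)


def linear_to_db(ratio: float) -> float:
    """Convert a linear power ratio to dB."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive to express in dB, got {ratio}")
    return 10.0 * math.log10(ratio)


def cm2_to_m2(sigma_cm2: float) -> float:
    return sigma_cm2 * 1e-4


def m2_to_cm2(sigma_m2: float) -> float:
    return sigma_m2 * 1e4
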