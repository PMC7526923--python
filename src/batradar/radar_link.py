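"""Radar-equation link budget for a marine X-band pulse radar.

The monostatic radar equation relates transmitted power ``P_t``, antenna
gain ``g`` (linear), wavelength ``lambda``, target radar cross section
``sigma`` and range ``R`` to the received echo power::

    P_r = P_t * g**2 * lambda**2 * sigma / (R**4 * (4*pi)**3)

Setting ``P_r`` equal to the minimum detectable signal power ``P_min``
and solving for ``R`` gives the maximum detection range; solving for
``sigma`` gives the cross section of a target whose maximum range was
measured in the field.  ``P_min`` absorbs every loss of the real system
(receiver noise, processing, display quantization) and is recovered by
calibration against a sphere of known cross section rather than from a
noise-figure budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .units import C_LIGHT, db_to_linear, dbm_to_watts, linear_to_db, watts_to_dbm

_FOUR_PI_CUBED = (4.0 * math.pi) ** 3


@dataclass(frozen=True)
class PowerLevel:
    """A signal power, stored in watts, convertible to and from dBm."""

    watts: float

    @property
    def dbm(self) -> float:
        return watts_to_dbm(self.watts)

    @classmethod
    def from_dbm(cls, dbm: float) -> "PowerLevel":
        return cls(dbm_to_watts(dbm))

    def __mul__(self, factor: float) -> "PowerLevel":
        return PowerLevel(self.watts * factor)

    __rmul__ = __mul__


@dataclass(frozen=True)
class RadarSystem:
    """Pulse-radar parameters entering the link budget.

    ``peak_gain`` is stored linear; use :meth:`from_dbi` to build from a
    data-sheet gain in dBi.  ``pulse_repetition_frequency_hz`` is metadata
    only — no equation in this package uses it.  ``min_detectable_power_w``
    stays ``None`` until the system is calibrated (see
    :func:`pmin_from_range`).
    """

    transmit_power_w: float
    frequency_hz: float
    peak_gain: float
    pulse_length_s: float
    antenna_height_m: float = 2.0
    pulse_repetition_frequency_hz: Optional[float] = None
    min_detectable_power_w: Optional[float] = None
    wavelength_override_m: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("transmit_power_w", "frequency_hz", "peak_gain", "pulse_length_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.min_detectable_power_w is not None:
            if not 0 < self.min_detectable_power_w < self.transmit_power_w:
                raise ValueError("min_detectable_power_w must be in (0, transmit_power)")

    @classmethod
    def from_dbi(
        cls,
        transmit_power_w: float,
        frequency_hz: float,
        peak_gain_dbi: float,
        pulse_length_s: float,
        **kwargs,
    ) -> "RadarSystem":
        return cls(
            transmit_power_w=transmit_power_w,
            frequency_hz=frequency_hz,
            peak_gain=db_to_linear(peak_gain_dbi),
            pulse_length_s=pulse_length_s,
            **kwargs,
        )

    @property
    def peak_gain_dbi(self) -> float:
        return linear_to_db(self.peak_gain)

    @property
    def wavelength_m(self) -> float:
        if self.wavelength_override_m is not None:
            return self.wavelength_override_m
        return C_LIGHT / self.frequency_hz

    def calibrated(self, pmin: PowerLevel) -> "RadarSystem":
        """Return a copy with the minimum detectable signal power set."""
        return replace(self, min_detectable_power_w=pmin.watts)

    @property
    def min_detectable_power(self) -> PowerLevel:
        if self.min_detectable_power_w is None:
            raise ValueError(
                "radar system is not calibrated: min_detectable_power is unset "
                "(derive it with pmin_from_range)"
            )
        return PowerLevel(self.min_detectable_power_w)


def furuno_far2117(**overrides) -> RadarSystem:
    """The study radar: 12 kW magnetron, 9410 MHz, 31.6 dBi slotted
    waveguide antenna, 0.07 us pulse at 3000 Hz PRF, 2 m antenna height."""
    params = dict(
        transmit_power_w=12e3,
        frequency_hz=9410e6,
        peak_gain_dbi=31.6,
        pulse_length_s=0.07e-6,
        pulse_repetition_frequency_hz=3000.0,
        antenna_height_m=2.0,
    )
    params.update(overrides)
    return RadarSystem.from_dbi(**params)


def wavelength(system: RadarSystem) -> float:
    """Wavelength c/f in meters (9410 MHz -> 3.186 cm)."""
    return system.wavelength_m


def range_resolution(system: RadarSystem) -> float:
    """Theoretical pulse-limited range resolution c*tau/2 in meters."""
    return C_LIGHT * system.pulse_length_s / 2.0


def received_power(
    system: RadarSystem,
    sigma_m2: float,
    range_m: float,
    gain: Optional[float] = None,
) -> PowerLevel:
    """Echo power for a target of cross section ``sigma_m2`` at ``range_m``.

    ``gain`` is the linear antenna gain toward the target; defaults to the
    peak (boresight) gain.
    """
    if range_m <= 0:
        raise ValueError("range must be strictly positive")
    if sigma_m2 < 0:
        raise ValueError("sigma must be non-negative")
    g = system.peak_gain if gain is None else gain
    lam = system.wavelength_m
    pr = (
        system.transmit_power_w * g**2 * lam**2 * sigma_m2
        / (range_m**4 * _FOUR_PI_CUBED)
    )
    return PowerLevel(pr)


def max_detection_range(system: RadarSystem, sigma_m2: float) -> float:
    """Maximum detection range for cross section ``sigma_m2`` (boresight)."""
    if sigma_m2 <= 0:
        raise ValueError("sigma must be strictly positive")
    pmin = system.min_detectable_power.watts
    lam = system.wavelength_m
    return (
        system.transmit_power_w * system.peak_gain**2 * lam**2 * sigma_m2
        / (_FOUR_PI_CUBED * pmin)
    ) ** 0.25


def rcs_from_range(system: RadarSystem, r_max_m: float) -> float:
    """Cross section (m^2) of a target whose maximum range is ``r_max_m``."""
    if r_max_m <= 0:
        raise ValueError("r_max must be strictly positive")
    pmin = system.min_detectable_power.watts
    lam = system.wavelength_m
    return (
        r_max_m**4 * _FOUR_PI_CUBED * pmin
        / (system.transmit_power_w * system.peak_gain**2 * lam**2)
    )


def pmin_from_range(system: RadarSystem, r_max_m: float, sigma_m2: float) -> PowerLevel:
    """Minimum detectable signal power implied by a measured maximum range
    of a target of known cross section (the sphere-calibration step)."""
    if r_max_m <= 0:
        raise ValueError("r_max must be strictly positive")
    if sigma_m2 < 0:
        raise ValueError("sigma must be non-negative")
    lam = system.wavelength_m
    pmin = (
        system.transmit_power_w * system.peak_gain**2 * lam**2 * sigma_m2
        / (_FOUR_PI_CUBED * r_max_m**4)
    )
    return PowerLevel(pmin)
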