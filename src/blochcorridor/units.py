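"""Unit conventions and conversion constants.

Internally every energy is measured in units of the tunnelling amplitude
Delta and time in 1/Delta, with hbar = kB = 1.  Spectroscopic inputs
(wavenumbers, Kelvin) are converted on load and back on export.
"""

from __future__ import annotations

#: angular frequency per wavenumber: omega [rad/ps] = 0.188365 * nu [cm^-1]
CM1_TO_RAD_PS = 0.188365

#: Boltzmann constant in spectroscopic units
KB_CM1_PER_K = 0.695035


def wavenumber_to_delta_units(value_cm1: float, delta_cm1: float) -> float:
    """Express an energy given in cm^-1 in units of Delta."""
    return value_cm1 / delta_cm1


def delta_units_to_wavenumber(value: float, delta_cm1: float) -> float:
    return value * delta_cm1


def kelvin_to_delta_units(t_kelvin: float, delta_cm1: float) -> float:
    """kB*T expressed in units of Delta (kB = 0.695035 cm^-1/K)."""
    return KB_CM1_PER_K * t_kelvin / delta_cm1


def delta_units_to_kelvin(t_delta: float, delta_cm1: float) -> float:
    return t_delta * delta_cm1 / KB_CM1_PER_K


def time_unit_ps(delta_cm1: float) -> float:
    """Duration of one internal time unit (1/Delta) in picoseconds."""
    return 1.0 / (CM1_TO_RAD_PS * delta_cm1)
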