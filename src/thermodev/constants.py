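"""Physical constants and organism-level configuration defaults.

All unit conversions in the package go through this module: activation
energies are stored in kJ/mol, pre-exponential factors in min^-1, and
temperatures are supplied in degrees Celsius and converted to Kelvin by
adding exactly 273.15.
"""

from __future__ import annotations

#: Gas constant, J mol^-1 K^-1.
R_J_PER_MOL_K = 8.314

#: Exact offset between Celsius and Kelvin scales.
KELVIN_OFFSET = 273.15

#: Core temperature range (deg C) over which the Arrhenius plot is treated
#: as linear, per organism.
CORE_RANGE_C = {
    "fly": (14.3, 27.0),
    "frog": (12.2, 25.7),
}

#: Temperature span (deg C) over which embryos reach the last scored event.
VIABLE_RANGE_C = {
    "fly": (14.3, 30.1),
    "frog": (12.2, 28.5),
}

#: Time-origin score per organism (fly: 14th syncytial cleavage;
#: frog: 3rd cleavage).
ORIGIN_SCORE = {"fly": "A", "frog": "A"}

MINUTES_PER_SECOND = 1.0 / 60.0
MINUTES_PER_DAY = 24.0 * 60.0


def celsius_to_kelvin(temperature_c):
    """Convert a temperature in degrees Celsius to Kelvin."""
    return temperature_c + KELVIN_OFFSET


def kelvin_to_celsius(temperature_k):
    """Convert a temperature in Kelvin to degrees Celsius."""
    return temperature_k - KELVIN_OFFSET
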