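"""Physical constants shared across the solvers.

Free-space permittivity is kept at the conventional 8.854e-12 F/m; all other
electromagnetic constants are derived from it so that the dispersion relation
k0 = omega * sqrt(mu0 * eps0) is internally consistent.
"""

import math

#: Free-space permittivity (F/m).
EPSILON_0 = 8.854e-12

#: Free-space permeability (H/m).
MU_0 = 4.0e-7 * math.pi

#: Free-space wave impedance (ohm).
ETA_0 = math.sqrt(MU_0 / EPSILON_0)

#: Universal gas constant (J/(K*mol)), used by the Arrhenius damage kinetics.
R_GAS = 8.314

#: Offset between Celsius and Kelvin scales.
KELVIN_OFFSET = 273.15

#: Baseline body temperature (degC); initial and arterial blood temperature.
BODY_TEMPERATURE_C = 37.0

#: Baseline body temperature (K).
BODY_TEMPERATURE_K = BODY_TEMPERATURE_C + KELVIN_OFFSET


def celsius(t_kelvin):
    """Kelvin -> Celsius (works on scalars and arrays)."""
    return t_kelvin - KELVIN_OFFSET


def kelvin(t_celsius):
    """Celsius -> Kelvin (works on scalars and arrays)."""
    return t_celsius + KELVIN_OFFSET
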