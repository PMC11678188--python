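"""Physical constants in the calorie-based units used throughout.

All enthalpies are kcal/mol, entropies and heat capacities cal/(mol K),
temperatures kelvin internally (Celsius only at user-facing boundaries).
"""

#: Gas constant, cal / (mol K)
R_CAL = 1.987204

#: Gas constant, kcal / (mol K)
R_KCAL = 1.987204e-3

#: Celsius -> kelvin offset
T0_CELSIUS = 273.15


def celsius_to_kelvin(t_c):
    return t_c + T0_CELSIUS


def kelvin_to_celsius(t_k):
    return t_k - T0_CELSIUS
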