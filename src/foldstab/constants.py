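"""Physical constants shared by every analysis module.

All thermodynamic quantities in this package are expressed in kcal/mol,
temperatures in kelvin internally (user-facing interfaces use °C), and
denaturant concentrations in mol/L.
"""

#: Gas constant, kcal/(mol K). Single authoritative definition.
R_GAS: float = 1.987e-3

#: Celsius offset used for every °C ↔ K conversion.
KELVIN_OFFSET: float = 273.15

#: Viscosity of pure water at 20 °C, centipoise (reference solvent for s20,w).
WATER_VISCOSITY_20C_CP: float = 1.002

#: Density of pure water at 20 °C, g/mL (reference solvent for s20,w).
WATER_DENSITY_20C_G_ML: float = 0.99823


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + KELVIN_OFFSET


def kelvin_to_celsius(temp_k: float) -> float:
    return temp_k - KELVIN_OFFSET
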