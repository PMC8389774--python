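"""Physical constants and shared defaults.

All energies in this package are in kJ/mol and all temperatures in K.
"""

#: Gas constant in kJ/mol/K.
R_KJ_MOL_K: float = 8.31446e-3

#: Default absolute temperature (K) when a series does not specify one.
DEFAULT_TEMPERATURE: float = 300.0

#: Conversion factor from kcal/mol to kJ/mol (thermochemical calorie).
KCAL_TO_KJ: float = 4.184


def rt(temperature: float) -> float:
    """Thermal energy RT in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return R_KJ_MOL_K * temperature
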