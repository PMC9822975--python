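"""Physical constants used throughout the package.

Values follow CODATA; currents are microampere, voltages millivolt,
bench concentrations millimolar unless a function states otherwise.
"""

FARADAY_C_PER_MOL: float = 96485.332
GAS_CONSTANT_J_PER_MOL_K: float = 8.314462
DEFAULT_TEMPERATURE_K: float = 293.15  # room temperature, 20 degC


def thermal_voltage_mV(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT/F in millivolts (~25.26 mV at 293.15 K)."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K} K")
    return 1e3 * GAS_CONSTANT_J_PER_MOL_K * temperature_K / FARADAY_C_PER_MOL
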