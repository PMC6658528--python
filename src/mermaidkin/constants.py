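"""Physical constants and small thermodynamic helpers."""

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol
ZERO_CELSIUS = 273.15  # K


def kelvin(temperature_c: float) -> float:
    """Absolute temperature from Celsius."""
    return temperature_c + ZERO_CELSIUS


def rt_over_f_mv(temperature_c: float) -> float:
    """Thermal voltage RT/F in millivolts (25.61 mV at 24 degC)."""
    return GAS_CONSTANT * kelvin(temperature_c) / FARADAY * 1000.0
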