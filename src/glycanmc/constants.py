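"""Physical constants shared across the package."""

#: Boltzmann constant in kJ mol^-1 K^-1 (molar gas constant).
K_B = 0.0083145

#: Default simulation temperature in kelvin.
DEFAULT_TEMPERATURE = 298.0
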