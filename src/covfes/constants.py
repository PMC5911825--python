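"""Physical constants and shared defaults (kcal/mol, Å, K conventions)."""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 300.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL * temperature
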