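"""Unit conventions used throughout the package.

Internally everything is carried in a single unit system: lengths in Å,
times in ps, energies in kcal/mol, temperatures in K.  Quantities stated
in kJ/mol at input boundaries (e.g. the initial hill height) are converted
once, on entry.
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

#: kJ per kcal (thermochemical calorie)
KJ_PER_KCAL = 4.184


def kj_to_kcal(x: float) -> float:
    """Convert an energy from kJ/mol to kcal/mol."""
    return x / KJ_PER_KCAL


def kcal_to_kj(x: float) -> float:
    return x * KJ_PER_KCAL


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol for a temperature in K."""
    return KB_KCAL * temperature
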