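"""Physical constants and unit conversions used throughout the package.

Energies are carried in kJ/mol, lengths in nm, forces (line tensions) in pN.
The molar scale is convenient because free-energy profiles from simulation
are conventionally reported in kJ/mol; converting a molar energy density to
a mechanical line tension requires dividing by Avogadro's number, which is
folded into the single constant ``PN_PER_KJ_MOL_NM``.
"""

from __future__ import annotations

#: Boltzmann constant (gas constant per mole) in kJ mol^-1 K^-1.
KB = 0.00831446

#: Conversion factor: 1 kJ mol^-1 nm^-1 = 1.66054 pN.
PN_PER_KJ_MOL_NM = 1.66054

#: Conversion factor: 1 pN nm = 0.602214 kJ mol^-1 (inverse of the above).
KJ_MOL_PER_PN_NM = 1.0 / PN_PER_KJ_MOL_NM

#: Default physiological temperature in K.
DEFAULT_TEMPERATURE = 310.0


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature in K."""
    return KB * temperature
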