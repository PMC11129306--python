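"""Unit conventions shared across the package.

Lengths are nanometres, times nanoseconds, energies kJ/mol unless a
function documents otherwise.  Free energies handed to users are in
units of the thermal energy kBT.
"""

#: Boltzmann constant times Avogadro's number, kJ mol^-1 K^-1.
KB_KJ_PER_MOL_K = 0.00831446261815324

#: Default temperature (K) for thermal-energy conversions.
DEFAULT_TEMPERATURE_K = 300.0


def kbt_kj_per_mol(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kBT in kJ/mol at the given temperature."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_KJ_PER_MOL_K * temperature_k


#: kBT at 300 K in kJ/mol, the package-wide default.
KBT_300K = kbt_kj_per_mol(300.0)
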