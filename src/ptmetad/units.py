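"""Unit conventions.

Internal units throughout the package: energies in kJ/mol, lengths in
Angstrom, times in ps, temperatures in K, angles in radians.  Reporting
helpers convert to kcal/mol (1 kcal = 4.184 kJ).
"""

KB = 0.0083144621  # Boltzmann constant, kJ/mol/K
KJ_PER_KCAL = 4.184


def kj_to_kcal(x):
    return x / KJ_PER_KCAL


def kcal_to_kj(x):
    return x * KJ_PER_KCAL


def beta(temperature: float) -> float:
    """Inverse temperature 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)
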