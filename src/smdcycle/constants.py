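"""Physical constants and unit conventions.

Units are fixed package-wide: energy in kcal mol^-1, length in angstrom (A),
time in ps, mass in amu, temperature in K.  With these units one
kcal mol^-1 equals 418.4 amu A^2 ps^-2, which is the factor converting a
force in kcal mol^-1 A^-1 acting on a mass in amu into an acceleration in
A ps^-2.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 0.0019872

#: kcal mol^-1 expressed in amu A^2 ps^-2 (4184 J / 10.0 J per amu A^2 ps^-2).
KCAL_PER_MOL_IN_AMU_A2_PS2 = 418.4

#: Standard-state volume per molecule at 1 M, A^3.
V0_STANDARD = 1661.0


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal mol^-1."""
    return KB * temperature


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B*T) in mol kcal^-1."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (KB * temperature)


#: Bondi van-der-Waals radii (A) used by the SASA engine, keyed by element
#: symbol.  Only elements occurring in standard amino acids plus a few common
#: hetero elements are listed; anything else is an explicit error.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "ZN": 1.39,
}
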