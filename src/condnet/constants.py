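"""Physical constants and unit conversions.

Internal unit system (the "real" convention of bead-spring MD engines):
length Å, energy kcal/mol, mass amu, time fs, charge in elementary charges.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 0.0019872041

#: Coulomb constant e^2/(4 pi eps0), kcal Å mol^-1 e^-2.
COULOMB = 332.06371

#: Acceleration conversion: (kcal/mol/Å)/amu -> Å/fs^2.
FORCE_TO_ACC = 4.184e-4

#: Kinetic energy conversion: amu (Å/fs)^2 -> kcal/mol.
VSQ_TO_KCAL = 1.0 / FORCE_TO_ACC

#: Mass density conversion: amu/Å^3 -> g/cm^3.
AMU_PER_A3_TO_G_PER_CM3 = 1.66053906892

#: Stress-integral conversion: kcal mol^-1 Å^-2 -> mN/m.
KCAL_PER_MOL_A2_TO_MN_PER_M = 694.7694


def thermal_energy(temperature: float) -> float:
    """k_B*T in kcal/mol for a temperature in kelvin.

    Raises
    ------
    ValueError
        If ``temperature`` is not positive.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
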