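"""Physical constants and element tables used throughout the package.

Unit conventions: lengths in Å, time in ps, energies in kcal mol⁻¹,
temperatures in K.  The toy Langevin engine works in reduced mass units
(m = 1 kcal mol⁻¹ ps² Å⁻²) so forces in kcal mol⁻¹ Å⁻¹ act directly on
velocities in Å ps⁻¹.
"""

# Boltzmann constant, kcal mol⁻¹ K⁻¹
KB_KCAL_MOL_K = 0.0019872041

DEFAULT_TEMPERATURE_K = 300.0


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """kT in kcal mol⁻¹ at the given temperature in K."""
    return KB_KCAL_MOL_K * temperature


# 1 kcal (mol Å e)⁻¹ expressed as a field in V Å⁻¹:
# 4184 J mol⁻¹ / (N_A · elementary charge) per Å.
_NA = 6.02214076e23
_E_CHARGE = 1.602176634e-19
KCAL_MOL_ANG_E_TO_V_PER_ANG = 4184.0 / (_NA * _E_CHARGE)  # ≈ 0.043364
KCAL_MOL_ANG_E_TO_V_PER_NM = 10.0 * KCAL_MOL_ANG_E_TO_V_PER_ANG

# element -> (electron count, vdW radius Å, mass amu)
ELEMENT_TABLE = {
    "H": (1, 1.10, 1.008),
    "C": (6, 1.70, 12.011),
    "N": (7, 1.55, 14.007),
    "O": (8, 1.52, 15.999),
    "P": (15, 1.80, 30.974),
    "S": (16, 1.80, 32.06),
}
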