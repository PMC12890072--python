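"""Physical constants and unit conversions used across the package.

All coordinates and distances are in angstrom (Å), concentrations in
mol/L, and Kirkwood-Buff integrals in L/mol.  The single conversion
between number density (molecules/Å^3) and molarity lives here so that
every module agrees on it.
"""

#: Avogadro constant, 1/mol (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: 1 mol/L expressed in molecules per cubic angstrom.
#: 1 mol/L = N_A / 1e27 molecules/Å^3.
MOLAR_PER_A3 = AVOGADRO / 1e27  # 6.02214076e-4

#: Boltzmann constant in kJ/(mol K) — used by the replica-exchange
#: acceptance arithmetic, where energies are in kJ/mol.
KB_KJ_PER_MOL_K = 8.31446261815324e-3


def number_density_to_molar(rho_per_a3: float) -> float:
    """Convert a number density in molecules/Å^3 to mol/L."""
    return rho_per_a3 / MOLAR_PER_A3


def molar_to_number_density(molar: float) -> float:
    """Convert a concentration in mol/L to molecules/Å^3."""
    return molar * MOLAR_PER_A3


def a3_to_l_per_mol(volume_a3: float) -> float:
    """Convert a volume in Å^3 to L/mol (the unit of a KBI per molecule)."""
    return volume_a3 * MOLAR_PER_A3
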