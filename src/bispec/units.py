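"""Unit conversions between the molar-areal (dm, mol, s) system the ODE
model is written in and the per-molecule (um, molecule, s) system the
particle simulator uses.

Surface concentrations: 1 molecule/um^2 = 1e10 molecules/dm^2
                                        = 1e10 / N_A mol/dm^2.
Surface rate constants: 1 um^2/(molecule s) = 1e-10 N_A dm^2/(mol s).
"""

import math

N_A = 6.02214076e23  # 1/mol

CM2_PER_UM2 = 1e-8
UM2_PER_CM2 = 1e8
DM2_PER_UM2 = 1e-10
UM3_PER_DM3 = 1e15  # 1 dm^3 = 1 L = 1e15 um^3


def per_molecule_to_molar_areal(k_um2_per_molecule_s: float) -> float:
    """um^2/(molecule s) -> dm^2/(mol s)."""
    return k_um2_per_molecule_s * DM2_PER_UM2 * N_A


def molar_areal_to_per_molecule(k_dm2_per_mol_s: float) -> float:
    """dm^2/(mol s) -> um^2/(molecule s)."""
    return k_dm2_per_mol_s / (DM2_PER_UM2 * N_A)


def molecules_per_um2_to_mol_per_dm2(density: float) -> float:
    return density * 1e10 / N_A


def mol_per_dm2_to_molecules_per_um2(density: float) -> float:
    return density * N_A * 1e-10


def sphere_area_um2(diameter_um: float) -> float:
    """Surface area pi*d^2 of a sphere of diameter d."""
    return math.pi * diameter_um ** 2
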